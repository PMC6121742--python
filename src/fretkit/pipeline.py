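"""Pipeline drivers, run configuration and the dye-pair self-consistency ratio.

``run_confocal`` and ``run_tirf`` execute the full ordered workflow --
ingest, background, burst search / bleach detection, apparent E-S,
(alpha, delta), (gamma, beta), final E-S, <E>, distances, uncertainty
budget, and the R_rel self-consistency check when at least two datasets are
supplied.  Every fitted factor is reported with its provenance; when an
output directory is given, each intermediate is serialized (per-event
tables as TSV, the summary as JSON).
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import correction
from .av import sphere_av, build_lookup_table
from .burst import PhotonStream, bursts_to_table, estimate_background_confocal, find_bursts
from .correction import (
    IllConditionedFitError,
    PopulationError,
    apparent_es,
    finalize_es_and_mean,
    fit_gamma_beta_global,
    fit_leakage_direct,
    intermediate_es,
    subtract_background,
)
from .factors import CorrectionFactors
from .forster import distance_from_efficiency
from .io import dump_json
from .traces import (
    GammaNotComputable,
    InsufficientPostBleachError,
    Trace,
    detect_bleaching,
    estimate_background_trace,
    individual_gamma,
    profile_normalize,
    traces_to_table,
)
from .uncertainty import UncertaintyInputs, total_distance_uncertainty


class ConfigError(ValueError):
    """Run configuration contains unknown or invalid keys."""


#: full default run configuration; user configs are validated against these keys
DEFAULT_CONFIG: dict = {
    "mode": "confocal",  # or "tirf"
    "bin_ms": 1.0,
    "burst_threshold": 50,
    "burst_criterion": "all",  # "dex" restricts to donor-excitation photons
    "bg_threshold": None,  # default: burst_threshold
    "min_population_events": 50,
    "s_window": [0.3, 0.7],
    "da_window": [0.3, 0.8],  # stage-iii S range treated as the FRET species
    "factor_overrides": {},  # e.g. {"alpha": 0.05} to skip a fit
    "gamma_mode": "global",  # "global", "single-species" or "individual"
    "r0": 62.6,  # Å
    "kappa2_ok": True,  # set False to refuse the distance stage
    "av_radius": None,  # Å; sphere-AV radius enabling the R_MP stage
    "frame_period": 0.4,  # s (TIRF)
    "trace_bg_method": "post-bleach-offset",
    "uncertainty": {
        "rel_dgamma": 0.10,
        "rel_dbg": 0.02,
        "rel_dalpha": 0.10,
        "rel_ddelta": 0.10,
        "rel_dR0": 0.07,
        "mean_burst": 100.0,
    },
    "seed": 0,
}


_FACTOR_NAMES = {"alpha", "beta", "gamma", "delta"}


def make_config(overrides: Optional[dict] = None) -> dict:
    """Merge user overrides into the defaults, rejecting unknown keys."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in (overrides or {}).items():
        if key not in cfg:
            raise ConfigError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict) and isinstance(value, dict):
            allowed = _FACTOR_NAMES if key == "factor_overrides" else set(cfg[key])
            unknown = set(value) - allowed
            if unknown:
                raise ConfigError(f"unknown config keys {sorted(unknown)} under {key!r}")
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def r_rel(e_lo: float, e_mid: float, f: float = 1.0) -> float:
    """Self-consistency ratio of two apparent distances from one dye pair.

    R_rel = f * ((1/E_lo - 1)/(1/E_mid - 1))^(1/6), the ratio
    R_<E>,lo / R_<E>,mid; ``f`` collects the spectroscopic prefactors
    (ratios of kappa^2, quantum yields, overlaps and refractive indices) and
    is ~1 when donor positions and environments match across constructs.
    Quasi-independent of R0, so it cross-validates the dye model between
    dye pairs.
    """
    if not (0.0 < e_lo < 1.0 and 0.0 < e_mid < 1.0):
        raise ValueError("efficiencies must be strictly inside (0, 1)")
    if f <= 0:
        raise ValueError("f must be > 0")
    return f * ((1.0 / e_lo - 1.0) / (1.0 / e_mid - 1.0)) ** (1.0 / 6.0)


def rrel_report(
    pairs: dict[str, tuple[float, float]],
    f: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Compare R_rel across dye pairs: per-pair ratio, mean, deviation.

    ``pairs`` maps a dye-pair name to its (E_lo, E_mid) efficiencies.
    Similar ratios across pairs support the freely rotating/diffusing dye
    model; the deviation column is the percent departure from the mean.
    """
    rows = []
    for name, (e_lo, e_mid) in pairs.items():
        ratio = r_rel(e_lo, e_mid, (f or {}).get(name, 1.0))
        rows.append({"pair": name, "E_lo": e_lo, "E_mid": e_mid, "R_rel": ratio})
    df = pd.DataFrame(rows)
    mean = df["R_rel"].mean()
    df["deviation_pct"] = 100.0 * (df["R_rel"] - mean) / mean
    df.attrs["mean_R_rel"] = float(mean)
    df.attrs["max_deviation_pct"] = float(df["deviation_pct"].abs().max())
    return df


def _da_population_mean(df_iii: pd.DataFrame, da_window) -> tuple[float, float]:
    """Population (E, S) point from summed stage-iii intensities.

    Ratio-of-means rather than mean-of-ratios: per-event E and S are count
    ratios whose nonlinearity biases a plain mean at finite burst size,
    while sums over the population are bias-free.  Membership is
    sigma-clipped on the per-event E to reject chance coincidences.
    """
    mask = (
        (df_iii["S_app"] > da_window[0])
        & (df_iii["S_app"] < da_window[1])
        & np.isfinite(df_iii["E_app"])
    )
    if "flag_negative" in df_iii:
        mask &= ~df_iii["flag_negative"]
    if mask.sum() == 0:
        raise PopulationError("no events in the DA window")
    sub = df_iii.loc[mask]
    e = sub["E_app"].to_numpy()
    keep = np.ones(len(sub), dtype=bool)
    for _ in range(5):
        mu, sd = e[keep].mean(), e[keep].std()
        if sd == 0:
            break
        new = keep & (np.abs(e - mu) <= 3.0 * sd)
        if (new == keep).all():
            break
        keep = new
    f_sum = sub["F_AD"].to_numpy()[keep].sum()
    d_sum = sub["I_DemDex"].to_numpy()[keep].sum()
    x_sum = sub["I_AemAex"].to_numpy()[keep].sum()
    dex = f_sum + d_sum
    return float(f_sum / dex), float(dex / (dex + x_sum))


def _distance_block(mean_e: float, cfg: dict) -> dict:
    """<E> -> R_<E> (-> R_MP) -> uncertainty budget for one dataset."""
    block: dict = {}
    if not cfg["kappa2_ok"]:
        block["distance_refused"] = (
            "kappa2 check not passed; supply an explicit kappa2 or set "
            "kappa2_ok once anisotropies justify 2/3"
        )
        return block
    r0 = cfg["r0"]
    r_e = distance_from_efficiency(mean_e, r0)
    block["R_E"] = r_e
    if cfg["av_radius"]:
        av = sphere_av((0.0, 0.0, 0.0), cfg["av_radius"], grid=cfg["av_radius"] / 6)
        table = build_lookup_table(av, av, r0)
        block["R_MP"] = table.rmp(r_e)
    unc = cfg["uncertainty"]
    inputs = UncertaintyInputs(
        rel_dgamma=unc["rel_dgamma"],
        rel_dbg=unc["rel_dbg"],
        rel_dalpha=unc["rel_dalpha"],
        rel_ddelta=unc["rel_ddelta"],
        rel_dR0=unc["rel_dR0"],
        r0=r0,
        mean_burst=unc["mean_burst"],
    )
    budget = total_distance_uncertainty(np.array([r_e]), inputs)
    block["dR_setup"] = float(budget["dR_setup_total"].iloc[0])
    block["dR_total"] = float(budget["dR_total"].iloc[0])
    return block


def _fit_factors(
    tables_ii: list[pd.DataFrame], cfg: dict
) -> tuple[CorrectionFactors, str]:
    """(alpha, delta) then (gamma, beta) over the pooled stage-ii events."""
    overrides = cfg["factor_overrides"]
    pooled = pd.concat(tables_ii, ignore_index=True)
    pooled.attrs["stage"] = "ii"
    if "alpha" in overrides and "delta" in overrides:
        alpha, delta = overrides["alpha"], overrides["delta"]
    else:
        try:
            alpha, delta = fit_leakage_direct(
                pooled, min_events=cfg["min_population_events"]
            )
        except PopulationError as err:
            raise PopulationError(
                f"{err}; alternatively set factor_overrides alpha/delta"
            ) from None
        alpha = overrides.get("alpha", alpha)
        delta = overrides.get("delta", delta)

    if "gamma" in overrides and "beta" in overrides:
        gamma, beta = overrides["gamma"], overrides["beta"]
        provenance = "ground-truth"
    elif cfg["gamma_mode"] == "single-species":
        df_iii = intermediate_es(pooled, alpha, delta)
        gamma, beta = correction.fit_gamma_beta_single(df_iii)
        provenance = "fitted-single-species"
    else:
        points = []
        for tab in tables_ii:
            df_iii = intermediate_es(tab, alpha, delta)
            points.append(_da_population_mean(df_iii, cfg["da_window"]))
        if len(points) < 2:
            raise IllConditionedFitError(
                "global gamma/beta needs >= 2 datasets with distinct E; "
                "use gamma_mode='single-species' or factor_overrides"
            )
        gamma, beta = fit_gamma_beta_global(points)
        provenance = "fitted-global"
    return (
        CorrectionFactors(
            alpha=alpha, beta=beta, gamma=gamma, delta=delta, provenance=provenance
        ),
        provenance,
    )


def _finalize_datasets(
    tables_ii: list[pd.DataFrame],
    names: list[str],
    factors: CorrectionFactors,
    cfg: dict,
    outdir: Optional[Path],
) -> dict:
    report: dict = {"factors": factors.as_dict(), "datasets": {}}
    means = {}
    for name, tab in zip(names, tables_ii):
        events, res = finalize_es_and_mean(tab, factors, tuple(cfg["s_window"]))
        entry = {
            "mean_E": res.mean_E,
            "sigma_E": res.sigma_E,
            "n_events": res.n_events,
            "fit_converged": res.fit_converged,
            "in_gaussian_range": res.in_gaussian_range,
            "low_statistics": res.low_statistics,
        }
        entry.update(_distance_block(res.mean_E, cfg))
        report["datasets"][name] = entry
        means[name] = res.mean_E
        if outdir is not None:
            events.to_csv(outdir / f"{name}_events.tsv", sep="\t", index=False)
    if len(means) >= 2 and cfg["kappa2_ok"]:
        # ratio of the two lowest-efficiency datasets: R_<E>(lo)/R_<E>(mid)
        ordered = sorted(means.items(), key=lambda kv: kv[1])
        (n_lo, e_lo), (n_mid, e_mid) = ordered[0], ordered[1]
        report["r_rel"] = {
            "lo": n_lo, "mid": n_mid, "value": r_rel(e_lo, e_mid)
        }
    if outdir is not None:
        dump_json(report, outdir / "summary.json")
    return report


def run_confocal(
    streams: Sequence[PhotonStream],
    config: Optional[dict] = None,
    names: Optional[Sequence[str]] = None,
    outdir: Optional[str] = None,
) -> dict:
    """Full confocal workflow over one or more photon streams.

    Order: background estimate -> burst search -> stage-i tables ->
    background subtraction -> (alpha, delta) from the pooled DO/AO windows
    -> (gamma, beta) globally across datasets -> final E-S and <E> per
    dataset -> distances and uncertainty budget -> R_rel when >= 2 datasets.
    """
    cfg = make_config(config)
    names = list(names or (f"dataset{i}" for i in range(len(streams))))
    out = Path(outdir) if outdir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    tables_ii = []
    backgrounds = {}
    for name, stream in zip(names, streams):
        bg = estimate_background_confocal(
            stream,
            bin_ms=cfg["bin_ms"],
            burst_threshold=cfg["bg_threshold"] or cfg["burst_threshold"],
        )
        bursts = find_bursts(
            stream,
            bin_ms=cfg["bin_ms"],
            threshold=cfg["burst_threshold"],
            criterion=cfg["burst_criterion"],
        )
        table = bursts_to_table(bursts)
        table_ii = subtract_background(table, bg)
        backgrounds[name] = list(bg)
        tables_ii.append(table_ii)
        if out is not None:
            apparent_es(table).to_csv(out / f"{name}_stage_i.tsv", sep="\t", index=False)

    factors, _ = _fit_factors(tables_ii, cfg)
    factors = factors.with_background(
        tuple(np.mean([backgrounds[n] for n in names], axis=0))
    )
    report = _finalize_datasets(tables_ii, names, factors, cfg, out)
    report["mode"] = "confocal"
    report["backgrounds_per_ms"] = backgrounds
    report["n_bursts"] = {n: int(len(t)) for n, t in zip(names, tables_ii)}
    if out is not None:
        dump_json(report, out / "summary.json")
    return report


def run_tirf(
    trace_sets: Sequence[Sequence[Trace]],
    config: Optional[dict] = None,
    names: Optional[Sequence[str]] = None,
    profile=None,
    outdir: Optional[str] = None,
) -> dict:
    """Full TIRF workflow over one or more trace sets.

    Order: bleach-step detection and single-pair selection -> per-trace
    background (post-bleach offset, falling back to the median offset of the
    other traces) -> optional position-specific excitation normalization ->
    per-molecule stage-i events over the pre-bleach range -> the same
    correction cascade as confocal.  ``gamma_mode='individual'`` replaces
    the global fit with the mean molecule-wise gamma from acceptor-bleach
    jumps.
    """
    cfg = make_config(config)
    names = list(names or (f"dataset{i}" for i in range(len(trace_sets))))
    out = Path(outdir) if outdir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    tables_ii = []
    gammas_individual = []
    n_valid = {}
    for name, traces in zip(names, trace_sets):
        annotations = [detect_bleaching(tr) for tr in traces]
        bgs = []
        for tr, ann in zip(traces, annotations):
            try:
                bgs.append(
                    estimate_background_trace(tr, ann, method=cfg["trace_bg_method"])
                )
            except (InsufficientPostBleachError, ValueError):
                bgs.append(None)
        known = [b for b in bgs if b is not None]
        fallback = tuple(np.median(known, axis=0)) if known else (0.0, 0.0, 0.0)
        bgs = [b if b is not None else fallback for b in bgs]

        corrected = []
        kept_ann = []
        kept_bg = []
        for tr, ann, bg in zip(traces, annotations, bgs):
            if not ann.valid:
                continue
            rng = ann.analysis_range(tr)
            if (rng.stop - rng.start) < 3:
                continue
            if profile is not None:
                tr = profile_normalize(tr, profile)
            corrected.append(tr)
            kept_ann.append(ann)
            kept_bg.append(bg)
            try:
                gammas_individual.append(individual_gamma(tr, ann, bg=bg))
            except GammaNotComputable:
                pass
        table = traces_to_table(corrected, kept_ann)
        n_valid[name] = int(len(table))
        bg_arrays = tuple(
            np.array([b[k] for b in kept_bg]) for k in range(3)
        )
        tables_ii.append(subtract_background(table, bg_arrays))

    if cfg["gamma_mode"] == "individual" and gammas_individual:
        overrides = dict(cfg["factor_overrides"])
        overrides["gamma"] = float(np.mean(gammas_individual))
        overrides.setdefault("beta", 1.0)
        cfg = {**cfg, "factor_overrides": overrides, "gamma_mode": "global"}
        factors, _ = _fit_factors(tables_ii, cfg)
        factors = CorrectionFactors(
            alpha=factors.alpha, beta=factors.beta, gamma=factors.gamma,
            delta=factors.delta, provenance="individual",
        )
    else:
        factors, _ = _fit_factors(tables_ii, cfg)

    report = _finalize_datasets(tables_ii, names, factors, cfg, out)
    report["mode"] = "tirf"
    report["n_valid_traces"] = n_valid
    if gammas_individual:
        report["gamma_individual_mean"] = float(np.mean(gammas_individual))
        report["gamma_individual_n"] = len(gammas_individual)
    if out is not None:
        dump_json(report, out / "summary.json")
    return report
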