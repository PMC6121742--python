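"""The ordered ALEX correction cascade.

Raw intensity triples (stage i) become background-corrected triples
(stage ii), then leakage/direct-excitation-corrected apparent values
(stage iii), and finally fully corrected FRET efficiencies E and
stoichiometries S.  The order of the steps is fixed -- background first,
then (alpha, delta), then (gamma, beta) -- and enforced through a stage tag
carried on each event table; applying a step out of order raises
:class:`StageOrderError`.

Event tables are pandas DataFrames with columns ``I_DemDex``, ``I_AemDex``,
``I_AemAex`` and ``exposure`` (bins or frames integrated per event), plus
``df.attrs["stage"]`` in {"i", "ii", "final"}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .factors import CorrectionFactors

#: default selection windows after stage ii (the paper shows but does not
#: quantify them)
DO_WINDOW = {"s_min": 0.8, "e_max": 0.5}
AO_WINDOW = {"s_max": 0.2}
S_WINDOW = (0.3, 0.7)


class StageOrderError(RuntimeError):
    """A correction step was applied to a table at the wrong stage."""


class PopulationError(RuntimeError):
    """A required donor-only/acceptor-only population is missing or too small."""


class IllConditionedFitError(RuntimeError):
    """gamma/beta fit input populations have indistinguishable efficiencies."""


@dataclass
class EfficiencyResult:
    """Population-mean efficiency from a Gaussian fit to the E histogram."""

    mean_E: float
    sigma_E: float
    n_events: int
    s_window: tuple[float, float] = S_WINDOW
    fit_converged: bool = True
    in_gaussian_range: bool = True  # Gaussian approximation holds for ~0.1..0.9
    low_statistics: bool = False


def _require_stage(df: pd.DataFrame, stage: str, step: str) -> None:
    got = df.attrs.get("stage")
    if got != stage:
        raise StageOrderError(
            f"{step} requires a stage-{stage!r} table, got stage {got!r}; "
            "the cascade order is BG -> (alpha, delta) -> (gamma, beta)"
        )


def _triple(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return (
        df["I_DemDex"].to_numpy(float),
        df["I_AemDex"].to_numpy(float),
        df["I_AemAex"].to_numpy(float),
    )


def apparent_es(df: pd.DataFrame) -> pd.DataFrame:
    """Apparent (uncorrected) E and S per event.

    E_app = I_Aem|Dex / (I_Aem|Dex + I_Dem|Dex) and
    S_app = (I_Aem|Dex + I_Dem|Dex) / (I_Aem|Dex + I_Dem|Dex + I_Aem|Aex).
    Events with zero total signal are flagged undefined and get NaN.
    """
    dd, ad, aa = _triple(df)
    dex = dd + ad
    total = dex + aa
    out = df.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["E_app"] = np.where(dex != 0, ad / dex, 0.0)
        out["S_app"] = np.where(total != 0, dex / total, np.nan)
    out["undefined"] = total == 0
    out.attrs["stage"] = df.attrs.get("stage", "i")
    return out


def subtract_background(
    df: pd.DataFrame, bg: tuple[float, float, float]
) -> pd.DataFrame:
    """Stage i -> ii: remove per-channel background.

    ``bg`` is in photons per unit exposure; each channel is reduced by
    bg * exposure.  Negative results are retained but flagged
    (``flag_negative``) -- such events are excluded from factor fits but
    kept in histograms.
    """
    _require_stage(df, "i", "subtract_background")
    bg = [np.asarray(b, dtype=float) for b in bg]
    if any(np.any(b < 0) for b in bg):
        raise ValueError("bg must be nonnegative")
    exposure = df["exposure"].to_numpy(float) if "exposure" in df else 1.0
    out = df.copy()
    for col, b in zip(("I_DemDex", "I_AemDex", "I_AemAex"), bg):
        out[col] = df[col].to_numpy(float) - b * exposure
    out["flag_negative"] = (
        (out["I_DemDex"] < 0) | (out["I_AemDex"] < 0) | (out["I_AemAex"] < 0)
    )
    out.attrs["stage"] = "ii"
    return out


def _population_masks(es: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    # the flag_negative exclusion is deliberately NOT applied here: a
    # channel with ~zero expected signal (Aem|Aex for donor-only, Dem|Dex
    # for acceptor-only) goes negative after background subtraction half
    # the time, and discarding those events truncates the noise and biases
    # the window means (and hence alpha/delta) upward
    do = (
        (es["S_app"] > DO_WINDOW["s_min"])
        & (es["E_app"] < DO_WINDOW["e_max"])
    ).to_numpy()
    ao = (es["S_app"] < AO_WINDOW["s_max"]).to_numpy()
    return do, ao


def clipped_mean(values: np.ndarray, n_sigma: float = 3.0, n_iter: int = 5) -> float:
    """Iteratively sigma-clipped mean.

    Robust population center for the selection-window means: events from
    other species that leak into a window (e.g. chance coincidences of a
    donor-only and a FRET molecule in one burst) sit many sigma from the
    window population and would bias a plain mean, while the clipped mean
    preserves the (slightly skewed) shot-noise distribution of the
    population itself.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    for _ in range(n_iter):
        mu, sd = v.mean(), v.std()
        if sd == 0:
            break
        keep = np.abs(v - mu) <= n_sigma * sd
        if keep.all():
            break
        v = v[keep]
    return float(v.mean())


def leakage_from_do_mean(e_do: float) -> float:
    """alpha = <E_app(DO)> / (1 - <E_app(DO)>)."""
    if not 0.0 <= e_do < 1.0:
        raise ValueError("donor-only mean efficiency must be in [0, 1)")
    return e_do / (1.0 - e_do)


def direct_excitation_from_ao_mean(s_ao: float) -> float:
    """delta = <S_app(AO)> / (1 - <S_app(AO)>)."""
    if not 0.0 <= s_ao < 1.0:
        raise ValueError("acceptor-only mean stoichiometry must be in [0, 1)")
    return s_ao / (1.0 - s_ao)


def fit_leakage_direct(
    df_ii: pd.DataFrame, min_events: int = 50
) -> tuple[float, float]:
    """Leakage alpha and direct excitation delta from DO/AO populations.

    alpha = <E_app(DO)> / (1 - <E_app(DO)>) from the donor-only window
    (S > 0.8, E < 0.5 at stage ii) and
    delta = <S_app(AO)> / (1 - <S_app(AO)>) from the acceptor-only window
    (S < 0.2); the window means are sigma-clipped against events leaking in
    from other populations.  After applying the factors the DO population
    centers at E = 0 and the AO population at S = 0.
    """
    _require_stage(df_ii, "ii", "fit_leakage_direct")
    es = apparent_es(df_ii)
    do, ao = _population_masks(es)
    if do.sum() < min_events or ao.sum() < min_events:
        raise PopulationError(
            f"need >= {min_events} donor-only and acceptor-only events "
            f"(got {int(do.sum())} DO, {int(ao.sum())} AO); supply alpha/delta "
            "externally or lower the burst threshold / use criterion='all'"
        )
    e_do = clipped_mean(es.loc[do, "E_app"])
    s_ao = clipped_mean(es.loc[ao, "S_app"])
    return leakage_from_do_mean(e_do), direct_excitation_from_ao_mean(s_ao)


def intermediate_es(
    df_ii: pd.DataFrame, alpha: float, delta: float
) -> pd.DataFrame:
    """Stage ii -> iii apparent values.

    F_A|D = I_Aem|Dex - alpha*I_Dem|Dex - delta*I_Aem|Aex (sensitized
    acceptor emission); E and S are recomputed with F_A|D in place of the
    raw acceptor signal.  alpha = delta = 0 reduces to the stage-ii values.
    """
    _require_stage(df_ii, "ii", "intermediate_es")
    if alpha < 0 or delta < 0:
        raise ValueError("alpha and delta must be >= 0")
    dd, ad, aa = _triple(df_ii)
    f_ad = ad - alpha * dd - delta * aa
    out = df_ii.copy()
    out["F_AD"] = f_ad
    dex = f_ad + dd
    total = dex + aa
    with np.errstate(divide="ignore", invalid="ignore"):
        out["E_app"] = np.where(dex != 0, f_ad / dex, 0.0)
        out["S_app"] = np.where(total != 0, dex / total, np.nan)
    out.attrs["stage"] = "iii"
    return out


def gamma_beta_from_line(a: float, b: float) -> tuple[float, float]:
    """Closed-form (gamma, beta) from the 1/S = a + b*E regression line."""
    beta = a + b - 1.0
    if beta <= 0:
        raise IllConditionedFitError(f"fit implies beta = {beta:.4g} <= 0")
    gamma = (a - 1.0) / beta
    if gamma <= 0:
        raise IllConditionedFitError(f"fit implies gamma = {gamma:.4g} <= 0")
    return gamma, beta


def fit_gamma_beta_global(
    populations: Sequence[tuple[float, float]],
    weights: Optional[Sequence[float]] = None,
    min_delta_e: float = 0.05,
) -> tuple[float, float]:
    """Global gamma/beta from >= 2 population means at stage iii.

    The stage-iii DA populations obey
    S = (1 + gamma*beta + (1 - gamma)*beta*E)^-1, so a linear fit of 1/S
    versus E with intercept a and slope b gives beta = a + b - 1 and
    gamma = (a - 1)/(a + b - 1).  ``weights`` (e.g. inverse variances of the
    population means) are optional; with exactly two populations the line is
    exact.
    """
    pts = np.asarray(populations, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 (mean E, mean S) populations")
    e, s = pts[:, 0], pts[:, 1]
    if np.ptp(e) < min_delta_e:
        raise IllConditionedFitError(
            f"population efficiencies span {np.ptp(e):.3g} < {min_delta_e}"
        )
    if np.any(s <= 0):
        raise ValueError("population stoichiometries must be > 0")
    w = None if weights is None else np.asarray(weights, dtype=float)
    b, a = np.polyfit(e, 1.0 / s, 1, w=w)
    return gamma_beta_from_line(float(a), float(b))


def fit_gamma_beta_single(
    df_iii: pd.DataFrame, min_iqr: float = 0.1
) -> tuple[float, float]:
    """Single-species gamma/beta from burstwise scatter within one population.

    Same 1/S-versus-E regression, on per-event stage-iii points of one
    species whose efficiency broadening is dominated by genuine distance
    fluctuations.  Refuses when the E interquartile range is below
    ``min_iqr`` (shot-noise-only spread makes the regression meaningless).
    """
    _require_stage(df_iii, "iii", "fit_gamma_beta_single")
    mask = np.isfinite(df_iii["E_app"]) & np.isfinite(df_iii["S_app"])
    mask &= df_iii["S_app"] > 0
    if "flag_negative" in df_iii:
        mask &= ~df_iii["flag_negative"]
    e = df_iii.loc[mask, "E_app"].to_numpy()
    s = df_iii.loc[mask, "S_app"].to_numpy()
    q75, q25 = np.percentile(e, [75, 25])
    if q75 - q25 < min_iqr:
        raise IllConditionedFitError(
            f"E IQR {q75 - q25:.3g} < {min_iqr}; single-species mode needs "
            "broad genuine distance fluctuations"
        )
    b, a = np.polyfit(e, 1.0 / s, 1)
    return gamma_beta_from_line(float(a), float(b))


def corrected_es(
    df_ii: pd.DataFrame, factors: CorrectionFactors
) -> pd.DataFrame:
    """Fully corrected E and S per event from stage-ii intensities.

    E = F_A|D / (gamma*I_Dem|Dex + F_A|D) and
    S = (gamma*I_Dem|Dex + F_A|D) /
        (gamma*I_Dem|Dex + F_A|D + I_Aem|Aex/beta).
    """
    _require_stage(df_ii, "ii", "corrected_es")
    dd, ad, aa = _triple(df_ii)
    f_ad = ad - factors.alpha * dd - factors.delta * aa
    f_dd = factors.gamma * dd
    f_aa = aa / factors.beta
    out = df_ii.copy()
    denom = f_dd + f_ad
    total = denom + f_aa
    with np.errstate(divide="ignore", invalid="ignore"):
        out["E"] = np.where(denom != 0, f_ad / denom, np.nan)
        out["S"] = np.where(total != 0, denom / total, np.nan)
    out.attrs["stage"] = "final"
    return out


def _gaussian(x: np.ndarray, amp: float, mu: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _freedman_diaconis_edges(values: np.ndarray) -> np.ndarray:
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    width = 2.0 * iqr / len(values) ** (1.0 / 3.0) if iqr > 0 else 0.0
    lo, hi = values.min(), values.max()
    if width <= 0 or hi - lo <= width:
        return np.linspace(lo - 0.01, hi + 0.01, 11)
    n = max(5, int(np.ceil((hi - lo) / width)))
    return np.linspace(lo, hi, n + 1)


def fit_gaussian_mean(values: np.ndarray) -> tuple[float, float, bool]:
    """(center, width, converged) of a Gaussian fit to a 1-D histogram.

    Unweighted least squares on Freedman-Diaconis-binned counts; on
    non-convergence falls back to the robust (median) center with the flag
    cleared.
    """
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    edges = _freedman_diaconis_edges(values)
    counts, _ = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (float(counts.max()), float(values.mean()), float(values.std() or 0.05))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(_gaussian, centers, counts, p0=p0, maxfev=5000)
        mu, sigma = float(popt[1]), abs(float(popt[2]))
        if not np.isfinite(mu):
            raise RuntimeError
        return mu, sigma, True
    except (RuntimeError, ValueError):
        return float(np.median(values)), float(values.std()), False


def finalize_es_and_mean(
    df_ii: pd.DataFrame,
    factors: CorrectionFactors,
    s_window: tuple[float, float] = S_WINDOW,
) -> tuple[pd.DataFrame, EfficiencyResult]:
    """Fully corrected event table plus the population mean <E>.

    The corrected efficiency histogram is built from events with
    stoichiometry inside ``s_window`` (0.3 < S < 0.7 default) and <E> is the
    center of a Gaussian fit to it -- a good approximation for
    0.1 <~ E <~ 0.9 (flagged outside).  Fewer than 100 events in the window
    sets the low-statistics flag.
    """
    out = corrected_es(df_ii, factors)
    sel = (out["S"] > s_window[0]) & (out["S"] < s_window[1])
    sel &= np.isfinite(out["E"])
    e_values = out.loc[sel, "E"].to_numpy()
    if e_values.size == 0:
        raise PopulationError("no events inside the stoichiometry window")
    mu, sigma, converged = fit_gaussian_mean(e_values)
    result = EfficiencyResult(
        mean_E=mu,
        sigma_E=sigma,
        n_events=int(e_values.size),
        s_window=s_window,
        fit_converged=converged,
        in_gaussian_range=0.1 <= mu <= 0.9,
        low_statistics=e_values.size < 100,
    )
    return out, result


def iterate_alpha_delta_gamma_beta(
    df_ii: pd.DataFrame,
    populations_of: "callable",
    min_events: int = 50,
    tol: float = 1e-6,
    max_iter: int = 10,
) -> CorrectionFactors:
    """Optional iteration of the (alpha, delta) and (gamma, beta) fits.

    ``populations_of(df_iii)`` must return the list of (mean E, mean S)
    DA-population points used by the global fit.  Iterates until successive
    factor changes fall below ``tol`` (typically 2-3 rounds); the cascade
    order within each round is preserved.
    """
    alpha, delta = fit_leakage_direct(df_ii, min_events=min_events)
    gamma = beta = None
    for _ in range(max_iter):
        df_iii = intermediate_es(df_ii, alpha, delta)
        gamma_new, beta_new = fit_gamma_beta_global(populations_of(df_iii))
        alpha_new, delta_new = fit_leakage_direct(df_ii, min_events=min_events)
        deltas = [abs(alpha_new - alpha), abs(delta_new - delta)]
        if gamma is not None:
            deltas += [abs(gamma_new - gamma), abs(beta_new - beta)]
        alpha, delta, gamma, beta = alpha_new, delta_new, gamma_new, beta_new
        if max(deltas) < tol:
            break
    return CorrectionFactors(
        alpha=alpha, beta=beta, gamma=gamma, delta=delta,
        provenance="fitted-global",
    )
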