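"""Per-molecule TIRF trace processing.

Surface-tethered molecules are recorded as frame-indexed intensity triples
(I_Dem|Dex, I_Aem|Dex, I_Aem|Aex) under alternating excitation.  This module
detects single-step photobleaching (which certifies a single donor and a
single acceptor), selects the analysis range prior to the earliest bleach,
estimates per-trace backgrounds, normalizes for position-dependent
excitation across the field of view, and determines the molecule-wise
detection factor gamma from the acceptor-bleach intensity jump.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class GammaNotComputable(RuntimeError):
    """Individual gamma needs the acceptor to bleach before the donor."""


class InsufficientPostBleachError(RuntimeError):
    """Fewer than the minimum post-bleach frames; fall back to a global method."""


class InvalidProfileError(ValueError):
    """Excitation profile is zero/negative at the requested position."""


@dataclass
class Trace:
    """Frame-indexed intensity triple of one surface-tethered molecule."""

    I_DemDex: np.ndarray
    I_AemDex: np.ndarray
    I_AemAex: np.ndarray
    position: tuple[float, float] = (0.0, 0.0)
    frame_period: float = 0.4  # s

    def __post_init__(self) -> None:
        self.I_DemDex = np.asarray(self.I_DemDex, dtype=float)
        self.I_AemDex = np.asarray(self.I_AemDex, dtype=float)
        self.I_AemAex = np.asarray(self.I_AemAex, dtype=float)
        n = len(self.I_DemDex)
        if not (len(self.I_AemDex) == len(self.I_AemAex) == n):
            raise ValueError("channels must have equal length")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be > 0")

    def __len__(self) -> int:
        return len(self.I_DemDex)


@dataclass
class BleachAnnotation:
    """Bleach frames per dye (first dark frame) and the single-pair flag."""

    donor_bleach_frame: Optional[int]
    acceptor_bleach_frame: Optional[int]
    valid: bool

    @property
    def earliest_bleach(self) -> Optional[int]:
        frames = [
            f
            for f in (self.donor_bleach_frame, self.acceptor_bleach_frame)
            if f is not None
        ]
        return min(frames) if frames else None

    def analysis_range(self, trace: Trace) -> slice:
        """Frames strictly before the earliest detected bleach."""
        stop = self.earliest_bleach
        return slice(0, len(trace) if stop is None else stop)


@dataclass
class ExcitationProfile:
    """2-D excitation intensity maps of the donor and acceptor lasers.

    Maps are indexed as ``map[iy, ix]`` with pixel coordinates; both must be
    strictly positive wherever molecules are evaluated.  Typically obtained
    as the mean image of a stack recorded over a chamber with dense dye
    coverage.
    """

    I_D: np.ndarray
    I_A: np.ndarray

    def __post_init__(self) -> None:
        self.I_D = np.asarray(self.I_D, dtype=float)
        self.I_A = np.asarray(self.I_A, dtype=float)
        if self.I_D.shape != self.I_A.shape:
            raise ValueError("donor and acceptor maps must share a shape")

    def ratio_at(self, position: tuple[float, float]) -> float:
        """I_D/I_A at the (x, y) pixel position (nearest pixel)."""
        x, y = position
        iy = int(round(y))
        ix = int(round(x))
        ny, nx = self.I_D.shape
        if not (0 <= iy < ny and 0 <= ix < nx):
            raise InvalidProfileError(f"position {position} outside profile map")
        d, a = self.I_D[iy, ix], self.I_A[iy, ix]
        if d <= 0 or a <= 0:
            raise InvalidProfileError(f"non-positive profile value at {position}")
        return float(d / a)


def _noise_sigma(y: np.ndarray) -> float:
    """Robust frame-to-frame noise estimate (median absolute difference)."""
    if len(y) < 2:
        return 0.0
    mad = np.median(np.abs(np.diff(y)))
    return float(mad / (0.6745 * np.sqrt(2.0))) or 1e-12


def _best_split(y: np.ndarray) -> tuple[int, float, float]:
    """Two-segment least-squares split maximizing variance reduction.

    Returns (split index t in [1, n-1], mean before, mean after) for the
    split minimizing the pooled SSE.
    """
    n = len(y)
    c1 = np.cumsum(y)
    c2 = np.cumsum(y * y)
    t = np.arange(1, n)
    sse_left = c2[t - 1] - c1[t - 1] ** 2 / t
    sr1 = c1[-1] - c1[t - 1]
    sr2 = c2[-1] - c2[t - 1]
    sse_right = sr2 - sr1**2 / (n - t)
    best = int(np.argmin(sse_left + sse_right))
    tb = int(t[best])
    return tb, float(c1[tb - 1] / tb), float(sr1[best] / (n - tb))


def _detect_steps(
    y: np.ndarray, sigma: float, snr_min: float, min_seg: int = 2
) -> list[int]:
    """Recursively locate all significant downward/upward steps."""
    if len(y) < 2 * min_seg:
        return []
    t, m1, m2 = _best_split(y)
    if t < min_seg or len(y) - t < min_seg:
        return []
    if abs(m1 - m2) < snr_min * sigma:
        return []
    left = _detect_steps(y[:t], sigma, snr_min, min_seg)
    right = [t + s for s in _detect_steps(y[t:], sigma, snr_min, min_seg)]
    return left + [t] + right


def _single_bleach_step(
    y: np.ndarray, snr_min: float, drop_frac: float
) -> tuple[Optional[int], int]:
    """(bleach frame or None, number of significant steps) for one channel.

    Detection runs on the variance-stabilized (Anscombe square-root)
    signal, since shot noise scales with the intensity level and a global
    noise estimate on the raw trace would be dominated by the quiet
    post-bleach segment.  A bleach step must additionally be a drop whose
    post-step mean falls below ``drop_frac`` of the pre-step mean (on the
    raw scale), distinguishing true loss of the dye from partial intensity
    changes (e.g. the donor de-quenching jump upon acceptor bleaching,
    which only partially changes the donor-excited sum).
    """
    yt = np.sqrt(np.maximum(y, 0.0) + 0.375)
    sigma = _noise_sigma(yt)
    steps = _detect_steps(yt, sigma, snr_min)
    if not steps:
        return None, 0
    bleach = None
    for t in steps:
        m1 = float(np.mean(y[:t]))
        m2 = float(np.mean(y[t:]))
        if m2 < m1 and m2 < drop_frac * m1:
            bleach = t
            break
    return bleach, len(steps)


def detect_bleaching(
    trace: Trace, snr_min: float = 3.0, drop_frac: float = 0.5
) -> BleachAnnotation:
    """Single-change-point bleach detection per dye.

    The donor is probed with the total donor-excited signal
    (I_Dem|Dex + I_Aem|Dex), which collapses when the donor bleaches but is
    largely insensitive to acceptor loss; the acceptor is probed with
    I_Aem|Aex.  Traces whose probe shows more than one significant step
    (multiple fluorophores) or no step in either channel are flagged
    ``valid=False`` rather than raised.
    """
    if len(trace) < 4:
        raise ValueError("trace must have at least 4 frames")
    donor_probe = trace.I_DemDex + trace.I_AemDex
    d_frame, d_steps = _single_bleach_step(donor_probe, snr_min, drop_frac)
    a_frame, a_steps = _single_bleach_step(trace.I_AemAex, snr_min, drop_frac)
    valid = d_steps <= 1 and a_steps <= 1 and (d_frame is not None or a_frame is not None)
    return BleachAnnotation(
        donor_bleach_frame=d_frame, acceptor_bleach_frame=a_frame, valid=valid
    )


def estimate_background_trace(
    trace: Trace,
    annotation: BleachAnnotation,
    method: str = "post-bleach-offset",
    dark: Optional[tuple[float, float, float]] = None,
    local_bg: Optional[np.ndarray] = None,
    margin: int = 1,
    min_frames: int = 3,
) -> tuple[float, float, float]:
    """Per-channel background in counts/frame.

    ``post-bleach-offset`` (default): individual offset (time average) after
    photobleaching of both dyes.  ``global-dark``: per-channel offsets
    supplied from dark regions or dark traces.  ``local-mask``: time-average
    of a per-frame local background trace (e.g. an annulus mask around the
    particle) over the analysis range; follows slow background drifts.
    """
    channels = (trace.I_DemDex, trace.I_AemDex, trace.I_AemAex)
    if method == "post-bleach-offset":
        if annotation.donor_bleach_frame is None or annotation.acceptor_bleach_frame is None:
            raise InsufficientPostBleachError("both bleach frames are required")
        start = max(annotation.donor_bleach_frame, annotation.acceptor_bleach_frame) + margin
        if len(trace) - start < min_frames:
            raise InsufficientPostBleachError(
                f"only {len(trace) - start} post-bleach frames (< {min_frames})"
            )
        return tuple(max(0.0, float(np.mean(ch[start:]))) for ch in channels)
    if method == "global-dark":
        if dark is None:
            raise ValueError("global-dark requires per-channel dark offsets")
        return tuple(max(0.0, float(d)) for d in dark)
    if method == "local-mask":
        if local_bg is None:
            raise ValueError("local-mask requires a per-frame background trace")
        local_bg = np.atleast_2d(np.asarray(local_bg, dtype=float))
        if local_bg.shape[0] == 1:
            local_bg = np.repeat(local_bg, 3, axis=0)
        rng = annotation.analysis_range(trace)
        return tuple(max(0.0, float(np.mean(row[rng]))) for row in local_bg)
    raise ValueError(f"unknown background method {method!r}")


def profile_normalize(trace: Trace, profile: ExcitationProfile) -> Trace:
    """Position-specific excitation normalization of the Aem|Aex channel.

    Multiplies I_Aem|Aex by I_D(x', y')/I_A(x, y) evaluated at the molecule
    position, making the stoichiometry independent of where in the field of
    view the molecule sits.  Apply after background subtraction: the
    rescaling belongs to signal, not to the camera offset.
    """
    ratio = profile.ratio_at(trace.position)
    return Trace(
        I_DemDex=trace.I_DemDex.copy(),
        I_AemDex=trace.I_AemDex.copy(),
        I_AemAex=trace.I_AemAex * ratio,
        position=trace.position,
        frame_period=trace.frame_period,
    )


def individual_gamma(
    trace: Trace,
    annotation: BleachAnnotation,
    bg: tuple[float, float, float] = (0.0, 0.0, 0.0),
    guard: int = 1,
    min_frames: int = 3,
) -> float:
    """Molecule-wise detection factor from the acceptor-bleach jump.

    gamma = (decrease in I_Aem|Dex) / (increase in I_Dem|Dex) across the
    acceptor bleach, both on background-corrected intensities.  ``guard``
    frames on each side of the bleach frame are excluded to avoid
    partial-frame artifacts.  Requires the acceptor to bleach first with at
    least ``min_frames`` usable frames on each side.
    """
    a = annotation.acceptor_bleach_frame
    d = annotation.donor_bleach_frame
    if a is None:
        raise GammaNotComputable("no acceptor bleach detected")
    if d is not None and d <= a:
        raise GammaNotComputable("donor bleached first; fall back to global gamma")
    end = d if d is not None else len(trace)
    pre = slice(0, a - guard)
    post = slice(a + guard, end - guard if d is not None else end)
    n_pre = pre.stop - pre.start
    n_post = (post.stop or len(trace)) - post.start
    if n_pre < min_frames or n_post < min_frames:
        raise GammaNotComputable("fewer than min_frames frames on one side of the bleach")
    ad = trace.I_AemDex - bg[1]
    dd = trace.I_DemDex - bg[0]
    dA = float(np.mean(ad[pre]) - np.mean(ad[post]))
    dD = float(np.mean(dd[post]) - np.mean(dd[pre]))
    # the donor de-quenching jump must be resolvable above noise, otherwise
    # the ratio is dominated by noise (e.g. acceptor-only traces)
    sem = float(
        np.sqrt(np.var(dd[pre]) / max(n_pre, 1) + np.var(dd[post]) / max(n_post, 1))
    )
    if dD <= 0 or (sem > 0 and dD < 3.0 * sem):
        raise GammaNotComputable("donor intensity increase not resolvable")
    return dA / dD


def traces_to_table(
    traces: Sequence[Trace],
    annotations: Sequence[BleachAnnotation],
    min_frames: int = 3,
) -> pd.DataFrame:
    """Stage-i event table (one row per valid molecule) for the correction engine.

    Intensities are per-frame means over the analysis range (frames before
    the earliest bleach), so ``exposure`` is 1 frame and per-frame
    background rates subtract directly.
    """
    rows = []
    for trace, ann in zip(traces, annotations):
        if not ann.valid:
            continue
        rng = ann.analysis_range(trace)
        if (rng.stop - rng.start) < min_frames:
            continue
        rows.append(
            {
                "I_DemDex": float(np.mean(trace.I_DemDex[rng])),
                "I_AemDex": float(np.mean(trace.I_AemDex[rng])),
                "I_AemAex": float(np.mean(trace.I_AemAex[rng])),
                "exposure": 1.0,
                "x": trace.position[0],
                "y": trace.position[1],
            }
        )
    df = pd.DataFrame(
        rows, columns=["I_DemDex", "I_AemDex", "I_AemAex", "exposure", "x", "y"]
    )
    df.attrs["stage"] = "i"
    return df
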