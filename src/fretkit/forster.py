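"""Förster theory: overlap integral, Förster radius, efficiency <-> distance.

The Förster radius R0 (in Å) follows from the donor quantum yield Phi_F,D,
the dipole orientation factor kappa^2, the refractive index of the
intervening medium n_im, and the spectral overlap integral J (M^-1 cm^-1
nm^4):

    R0/Å = 0.2108 * (Phi_F,D * kappa^2 * n_im^-4 * J)^(1/6)

The transfer efficiency for a single donor-acceptor distance R_DA is
E = 1/(1 + R_DA^6/R0^6); for a cloud of sampled dye positions the measured
quantity is the efficiency average over all position pairs, and inverting
it yields the apparent (FRET-averaged) distance R_<E>, not the physical
mean-position distance.

kappa^2 = 2/3 presumes rotational averaging much faster than transfer
(k_rot >> k_FRET); the anisotropy checks quantify when that assumption is
safe (combined residual anisotropy r_C < 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.spatial.distance import cdist

#: prefactor of the R0 formula for J in M^-1 cm^-1 nm^4, R0 in Å
R0_PREFACTOR = 0.2108
#: isotropic dynamic average of the dipole orientation factor
KAPPA2_ISOTROPIC = 2.0 / 3.0
#: recommended refractive index of the donor-acceptor intervening medium
N_IM_DEFAULT = 1.40


class ZeroOverlapError(ValueError):
    """Donor emission and acceptor extinction spectra do not overlap."""


@dataclass
class ForsterInputs:
    """Spectroscopic inputs of the R0 formula."""

    phi_F_D: float
    J: float  # M^-1 cm^-1 nm^4
    kappa2: float = KAPPA2_ISOTROPIC
    n_im: float = N_IM_DEFAULT

    def __post_init__(self) -> None:
        if not 0.0 < self.phi_F_D <= 1.0:
            raise ValueError("phi_F_D must be in (0, 1]")
        if not 0.0 <= self.kappa2 <= 4.0:
            raise ValueError("kappa2 must be in [0, 4]")
        if self.n_im < 1.0:
            raise ValueError("n_im must be >= 1")
        if self.J <= 0:
            raise ValueError("J must be > 0")


@dataclass
class AnisotropyData:
    """Steady-state/time-resolved anisotropy observables of the dye pair."""

    r0: float = 0.4  # intrinsic (fundamental) anisotropy
    tau: float = 3.0  # fluorescence lifetime, ns
    phi_rot: float = 1.0  # rotational correlation time, ns
    r_inf_D: float = 0.05  # residual donor anisotropy
    r_inf_A: float = 0.05  # residual acceptor anisotropy

    def __post_init__(self) -> None:
        for name in ("r0", "r_inf_D", "r_inf_A"):
            if not 0.0 <= getattr(self, name) <= 0.4:
                raise ValueError(f"{name} must be in [0, 0.4]")
        if self.tau <= 0 or self.phi_rot <= 0:
            raise ValueError("tau and phi_rot must be > 0")


@dataclass
class RegimeRates:
    """Rate ordering underlying the dynamic-averaging dye model (ns^-1)."""

    k_rot: float
    k_FRET: float
    k_diff: float
    k_int: float

    def __post_init__(self) -> None:
        if min(self.k_rot, self.k_FRET, self.k_diff, self.k_int) <= 0:
            raise ValueError("all rates must be > 0")


@dataclass
class AnisotropyReport:
    r_C: float
    perrin_r: float
    kappa2_ok: bool
    regime_ok: bool
    #: fractional R0 uncertainty warranted when kappa2 = 2/3 is adopted
    kappa2_rel_dR0: float = 0.05


def _as_spectrum(spec) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(spec, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("spectrum must be an (n, 2) array of (wavelength_nm, value)")
    wl, val = arr[:, 0], arr[:, 1]
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    return wl, val


def overlap_integral(
    donor_emission, acceptor_extinction, epsilon_max: Optional[float] = None
) -> float:
    """Spectral overlap integral J = int F_D(l) eps_A(l) l^4 dl.

    The donor emission spectrum is normalized to unit area over its full
    wavelength grid (so rescaling the input changes nothing); the acceptor
    extinction is rescaled so its maximum equals ``epsilon_max`` in
    M^-1 cm^-1 (or used as-is when absolute).  Both spectra are linearly
    interpolated onto the union grid of the overlap range and integrated by
    the trapezoid rule.  Result in M^-1 cm^-1 nm^4.
    """
    wl_d, f_d = _as_spectrum(donor_emission)
    wl_a, eps = _as_spectrum(acceptor_extinction)
    area = np.trapezoid(f_d, wl_d)
    if area <= 0:
        raise ValueError("donor spectrum must have positive area")
    f_d = f_d / area
    if epsilon_max is not None:
        if epsilon_max <= 0:
            raise ValueError("epsilon_max must be > 0")
        eps = eps * (epsilon_max / eps.max())
    lo, hi = max(wl_d[0], wl_a[0]), min(wl_d[-1], wl_a[-1])
    if hi <= lo:
        raise ZeroOverlapError("donor and acceptor spectra have no common range")
    grid = np.union1d(wl_d, wl_a)
    grid = grid[(grid >= lo) & (grid <= hi)]
    fd_i = np.interp(grid, wl_d, f_d)
    eps_i = np.interp(grid, wl_a, eps)
    return float(np.trapezoid(fd_i * eps_i * grid**4, grid))


def forster_radius(inputs: ForsterInputs) -> float:
    """R0 in Å; monotone in each input (1/6-power scaling in J)."""
    return R0_PREFACTOR * (
        inputs.phi_F_D * inputs.kappa2 * inputs.n_im ** -4 * inputs.J
    ) ** (1.0 / 6.0)


def kappa_squared(theta_AD: float, theta_D: float, theta_A: float) -> float:
    """Orientation factor (cos th_AD - 3 cos th_D cos th_A)^2; angles in degrees."""
    rad = np.deg2rad
    k2 = (np.cos(rad(theta_AD)) - 3.0 * np.cos(rad(theta_D)) * np.cos(rad(theta_A))) ** 2
    return float(k2)


def anisotropy_checks(data: AnisotropyData, rates: RegimeRates) -> AnisotropyReport:
    """Combined anisotropy, Perrin estimate and averaging-regime report.

    r_C = sqrt(r_A,inf) * sqrt(r_D,inf); the Perrin steady-state anisotropy
    is r(tau) = r0/(1 + tau/phi_rot).  kappa2 = 2/3 (with ~5% R0
    uncertainty) is warranted when both are below 0.2; the dynamic-averaging
    model additionally needs the strict rate ordering
    k_rot > k_FRET > k_diff > k_int.
    """
    r_c = float(np.sqrt(data.r_inf_A) * np.sqrt(data.r_inf_D))
    perrin = data.r0 / (1.0 + data.tau / data.phi_rot)
    kappa2_ok = r_c < 0.2 and perrin < 0.2
    regime_ok = rates.k_rot > rates.k_FRET > rates.k_diff > rates.k_int
    return AnisotropyReport(
        r_C=r_c, perrin_r=float(perrin), kappa2_ok=kappa2_ok, regime_ok=regime_ok
    )


def efficiency_from_distance(
    r_da: Union[float, np.ndarray], r0: float
) -> Union[float, np.ndarray]:
    """E = 1/(1 + R_DA^6/R0^6)."""
    if r0 <= 0:
        raise ValueError("R0 must be > 0")
    r_da = np.asarray(r_da, dtype=float)
    out = 1.0 / (1.0 + (r_da / r0) ** 6)
    return float(out) if out.ndim == 0 else out


def distance_from_efficiency(
    e: Union[float, np.ndarray], r0: float
) -> Union[float, np.ndarray]:
    """Apparent distance R_<E> = R0 * (1/E - 1)^(1/6); inverse of the above."""
    if r0 <= 0:
        raise ValueError("R0 must be > 0")
    e_arr = np.asarray(e, dtype=float)
    if np.any(e_arr <= 0.0) or np.any(e_arr >= 1.0):
        raise ValueError("E must be strictly inside (0, 1) for inversion")
    out = r0 * (1.0 / e_arr - 1.0) ** (1.0 / 6.0)
    return float(out) if out.ndim == 0 else out


def mean_efficiency_positions(
    donor_cloud: np.ndarray,
    acceptor_cloud: np.ndarray,
    r0: float,
    donor_weights: Optional[np.ndarray] = None,
    acceptor_weights: Optional[np.ndarray] = None,
) -> float:
    """Efficiency averaged over all donor x acceptor position pairs (Å).

    <E> = (1/nm) sum_i sum_j 1/(1 + |R_A(j) - R_D(i)|^6 / R0^6), the
    dynamic positional average measured when dyes sample their accessible
    volumes slowly compared with transfer but quickly compared with the
    integration time.  Optional weights generalize to non-uniform clouds;
    single-point clouds reduce to the single-distance expression.
    """
    d = np.atleast_2d(np.asarray(donor_cloud, dtype=float))
    a = np.atleast_2d(np.asarray(acceptor_cloud, dtype=float))
    if d.size == 0 or a.size == 0:
        raise ValueError("clouds must be nonempty")
    e = 1.0 / (1.0 + (cdist(d, a) / r0) ** 6)
    if donor_weights is None and acceptor_weights is None:
        return float(e.mean())
    wd = np.ones(len(d)) if donor_weights is None else np.asarray(donor_weights, float)
    wa = np.ones(len(a)) if acceptor_weights is None else np.asarray(acceptor_weights, float)
    wd = wd / wd.sum()
    wa = wa / wa.sum()
    return float(wd @ e @ wa)
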