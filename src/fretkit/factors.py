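"""Correction-factor container shared across the package.

The four ALEX correction factors are

* ``alpha`` -- leakage of donor fluorescence into the acceptor channel,
* ``beta``  -- normalization of donor vs. acceptor excitation rates,
* ``gamma`` -- normalization of detection efficiencies and effective
  fluorescence quantum yields of acceptor vs. donor,
* ``delta`` -- direct excitation of the acceptor by the donor laser,

together with the per-channel background rates at the stage where the
factors were determined.  ``provenance`` records how the set was obtained.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


_PROVENANCES = ("fitted-global", "fitted-single-species", "individual", "ground-truth")


class InvalidFactorsError(ValueError):
    """Raised when a correction-factor set violates its invariants."""


@dataclass
class CorrectionFactors:
    """A full correction-factor set plus per-channel backgrounds.

    Backgrounds ``bg`` are ordered as the intensity triple
    (Dem|Dex, Aem|Dex, Aem|Aex), in photons per unit exposure
    (per ms bin for confocal bursts, per frame for TIRF traces).
    """

    alpha: float = 0.0
    beta: float = 1.0
    gamma: float = 1.0
    delta: float = 0.0
    bg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: str = "ground-truth"

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.delta < 0:
            raise InvalidFactorsError("alpha and delta must be >= 0")
        if self.beta <= 0 or self.gamma <= 0:
            raise InvalidFactorsError("beta and gamma must be > 0")
        if len(self.bg) != 3 or any(b < 0 for b in self.bg):
            raise InvalidFactorsError("bg must be three nonnegative rates")
        if self.provenance not in _PROVENANCES:
            raise InvalidFactorsError(
                f"provenance must be one of {_PROVENANCES}, got {self.provenance!r}"
            )

    def with_background(self, bg: tuple[float, float, float]) -> "CorrectionFactors":
        return replace(self, bg=tuple(float(b) for b in bg))

    def as_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma": self.gamma,
            "delta": self.delta,
            "bg_DemDex": self.bg[0],
            "bg_AemDex": self.bg[1],
            "bg_AemAex": self.bg[2],
            "provenance": self.provenance,
        }
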