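import numpy as np
import pandas as pd
import pytest

from fretkit import CorrectionFactors, GroundTruth, SpeciesSpec


@pytest.fixture
def lab_factors() -> CorrectionFactors:
    """Reference-lab-like confocal factor set."""
    return CorrectionFactors(alpha=0.05, beta=1.0, gamma=0.8, delta=0.1)


@pytest.fixture
def mixture_truth(lab_factors) -> GroundTruth:
    """FRET + donor-only + acceptor-only mixture, typical fractions."""
    return GroundTruth(
        species=[
            SpeciesSpec("DA", E_true=0.5, fraction=0.7),
            SpeciesSpec("DO", fraction=0.2),
            SpeciesSpec("AO", fraction=0.1),
        ],
        factors=lab_factors,
        seed=1234,
    )


def stage_ii_table(triples) -> pd.DataFrame:
    """Event table at stage ii from raw (D, A, X) triples."""
    arr = np.atleast_2d(np.asarray(triples, dtype=float))
    df = pd.DataFrame(
        {
            "I_DemDex": arr[:, 0],
            "I_AemDex": arr[:, 1],
            "I_AemAex": arr[:, 2],
            "exposure": 1.0,
        }
    )
    df.attrs["stage"] = "ii"
    return df


def stage_i_table(triples, exposure=1.0) -> pd.DataFrame:
    arr = np.atleast_2d(np.asarray(triples, dtype=float))
    df = pd.DataFrame(
        {
            "I_DemDex": arr[:, 0],
            "I_AemDex": arr[:, 1],
            "I_AemAex": arr[:, 2],
            "exposure": exposure,
        }
    )
    df.attrs["stage"] = "i"
    return df
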