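# fretkit

Intensity-based single-molecule FRET analysis: the alternating-excitation
(ALEX) correction cascade from raw photon data to absolute FRET
efficiencies, conversion to distances via Förster theory and an
accessible-volume dye model, and a complete distance-uncertainty budget —
all validated against a built-in photon-level simulator with known ground
truth.

## Who this is for

Labs measuring FRET efficiencies of dye-labeled biomolecules on confocal
(diffusing molecules) or TIRF (surface-tethered molecules) setups who want
*absolute* efficiencies and distances that are comparable across
instruments, not just relative changes.  Raw intensities depend on
detection efficiencies, quantum yields, spectral crosstalk and laser
powers; without a disciplined correction procedure, two labs measuring the
same sample report different numbers.

## The model

Each single-molecule event yields an intensity triple
(I<sub>Dem|Dex</sub>, I<sub>Aem|Dex</sub>, I<sub>Aem|Aex</sub>).  After
background subtraction, the sensitized acceptor emission is

F<sub>A|D</sub> = <sup>ii</sup>I<sub>Aem|Dex</sub> − α·<sup>ii</sup>I<sub>Dem|Dex</sub> − δ·<sup>ii</sup>I<sub>Aem|Aex</sub>

with leakage α fitted from the donor-only population and direct
excitation δ from the acceptor-only population, and the fully corrected
efficiency and stoichiometry are

E = F<sub>A|D</sub> / (γ·<sup>ii</sup>I<sub>Dem|Dex</sub> + F<sub>A|D</sub>),  S adds <sup>ii</sup>I<sub>Aem|Aex</sub>/β to the denominator,

with (γ, β) from the linear relation 1/S = a + b·E across FRET
populations (β = a + b − 1, γ = (a − 1)/(a + b − 1)).  The order —
background, then (α, δ), then (γ, β) — is enforced by stage tags.
⟨E⟩ is the Gaussian-fit center of the E histogram over events with
0.3 < S < 0.7, and distances follow from

R<sub>0</sub>/Å = 0.2108·(Φ<sub>F,D</sub>·κ²·n<sub>im</sub><sup>−4</sup>·J)<sup>1/6</sup>,  R<sub>⟨E⟩</sub> = R<sub>0</sub>(E<sup>−1</sup> − 1)<sup>1/6</sup>,

with an accessible-volume lookup table converting the efficiency-averaged
R<sub>⟨E⟩</sub> into the physical mean-position distance R<sub>MP</sub>,
and a first-order error budget propagating factor, background and
R<sub>0</sub> uncertainties into ΔR.  Details and all estimator choices:
[docs/methods.md](docs/methods.md); file formats:
[docs/formats.md](docs/formats.md).

## Worked example

`examples/01_confocal_correction.py` simulates two DNA-ruler-like samples
(true E = 0.2 and 0.6, with 20% donor-only and 10% acceptor-only
impurities) under known factors α = 0.05, δ = 0.10, γ = 0.80, β = 1.00,
then runs the full pipeline blind:

```
fitted factors (truth: alpha 0.05, delta 0.10, gamma 0.80, beta 1.00):
  alpha = 0.0509   delta = 0.0987
  gamma = 0.7997   beta  = 0.9942   [fitted-global]
lo: <E> = 0.199 (truth 0.2), R_<E> = 78.9 Å, R_MP = 79.6 Å, dR_total = 5.8 Å over 1688 events
mid: <E> = 0.606 (truth 0.6), R_<E> = 58.3 Å, R_MP = 57.5 Å, dR_total = 4.2 Å over 1683 events
R_rel (lo/mid apparent-distance ratio) = 1.355
```

Every factor comes back within ~2% of truth, the corrected ⟨E⟩ within
0.01 of the generating efficiency, and the two apparent distances land
within the quoted total uncertainty of the true separations; `R_rel` is
the R<sub>0</sub>-independent self-consistency ratio used to compare dye
pairs.  The other examples cover the Förster radius from spectra
(`02`), accessible volumes and the R<sub>⟨E⟩</sub>→R<sub>MP</sub> table
(`03`), the uncertainty budget (`04`), and the TIRF branch with
molecule-wise γ from acceptor-bleach jumps (`05`).

A thin CLI wraps the same library:

```sh
fretkit simulate --mode confocal --n 2000 --e-true 0.5 --out sim.csv
fretkit confocal sim.csv --outdir results/
fretkit uncertainty --r0 62.6 --out budget.tsv
fretkit rrel --e-lo 0.15 --e-mid 0.56
```

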