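# Methods

This note documents the models, estimators and numerical choices behind
fretkit: what each stage assumes, which knobs matter, and what the built-in
simulator does and does not emulate.

## The correction cascade

Intensity-based smFRET under alternating laser excitation (ALEX) records a
per-event intensity triple: donor emission under donor excitation
(I_Dem|Dex), acceptor emission under donor excitation (I_Aem|Dex), and
acceptor emission under acceptor excitation (I_Aem|Aex).  Four factors
separate the physics from the instrument:

* **alpha** — spectral leakage of donor fluorescence into the acceptor
  detection channel;
* **delta** — direct excitation of the acceptor by the donor laser;
* **gamma** — ratio of detection efficiencies times effective fluorescence
  quantum yields, acceptor vs. donor;
* **beta** — normalization of the donor vs. acceptor excitation rates.

The cascade order is fixed and enforced through stage tags on the event
tables: background subtraction (stage i → ii), then alpha/delta
(stage ii → iii apparent values), then gamma/beta (fully corrected E, S).
Applying a step out of order raises an error, because the later fits are
defined on the earlier stages' outputs: alpha comes from the donor-only
population's apparent efficiency, delta from the acceptor-only population's
apparent stoichiometry, and gamma/beta from the linear relation between
1/S and E across FRET populations (intercept a and slope b give
beta = a + b − 1, gamma = (a − 1)/(a + b − 1)).

The fully corrected efficiency is

    E = F_A|D / (gamma · II_Dem|Dex + F_A|D),
    F_A|D = II_Aem|Dex − alpha · II_Dem|Dex − delta · II_Aem|Aex,

with II denoting background-corrected intensities, and the corrected
stoichiometry adds II_Aem|Aex / beta to the denominator.  The population
mean ⟨E⟩ is the center of a Gaussian fit to the E histogram of events with
0.3 < S < 0.7, Freedman–Diaconis binning, unweighted least squares; the
Gaussian approximation is adequate for roughly 0.1 ≤ ⟨E⟩ ≤ 0.9 and the
result is flagged outside that range, as well as on non-convergence
(median fallback) or fewer than 100 window events.

### Estimator choices

* **Window means are sigma-clipped** (3 σ, ≤ 5 iterations).  The
  donor-only window (S > 0.8, E < 0.5 at stage ii) and acceptor-only
  window (S < 0.2) occasionally catch chance coincidences of two molecules
  in one burst; these sit many σ from the window population and would bias
  a plain mean, while clipping leaves the slightly skewed shot-noise
  distribution essentially intact.
* **Population points for the gamma/beta fit are ratios of summed
  intensities** (ratio-of-means), not means of per-event ratios.  Per-event
  E and S are count ratios whose nonlinearity biases a plain mean by
  O(1/N) at N photons per burst — enough to shift gamma by several percent
  at typical burst sizes — whereas sums over the population are bias-free.
* **Negative stage-ii channels** (background over-subtraction) are flagged
  and excluded from the gamma/beta population means, but *not* from the
  donor-only/acceptor-only window means: the expected-zero channel of
  those species goes negative half the time by construction, and excluding
  it truncates symmetric noise.
* **Leaked donor signal is not added back** to the donor channel; it would
  require spectral detection efficiencies that are otherwise unneeded and
  does not change the corrected efficiencies.
* The alpha/delta and gamma/beta fits can be **iterated**; on simulated
  data successive factor changes fall below 1e−6 within a few rounds.

## Confocal branch

Bursts are found by 1-ms binning (edges at integer multiples of the bin
width from the first timestamp) with a photon threshold, 50 by default, on
the donor-excitation sum; consecutive qualifying bins merge into one burst
so a molecule straddling a bin edge is not double-counted.  An optional
all-photon criterion exists because acceptor-only molecules emit almost
nothing in the donor-excitation slot and would otherwise never populate
the S ≈ 0 window that the delta fit needs; the pipeline default uses it.

Background rates are the mean count rate of sub-threshold bins, estimated
in two passes: the coarse burst threshold gives a first-pass rate, then the
average is repeated below the 99.99% Poisson quantile of that rate.  The
second pass rejects the sub-threshold edge fragments of bursts straddling
bin boundaries, which otherwise inflate the estimate severalfold at
percent-level burst occupancy — the practical analogue of thresholding at
the maximum of the frequency-versus-intensity histogram.

## TIRF branch

Single donor + single acceptor molecules are certified by single-step
photobleaching.  Change points are located per channel by the two-segment
least-squares split that maximizes variance reduction, applied recursively
to find all significant steps; detection runs on the Anscombe square-root
transform of the signal so that shot noise has uniform variance across the
bleached and unbleached segments (a raw-scale noise estimate would be
dominated by the quiet post-bleach tail and trigger on fluctuations of the
bright segment).  The donor is probed with the total donor-excited signal,
which collapses on donor bleaching but changes only partially on acceptor
bleaching; a step qualifies as a bleach only if the post-step mean falls
below half the pre-step mean, which separates true dye loss from the donor
de-quenching jump.  Traces with more than one significant step in a probe
(multiple fluorophores) or with no step at all are flagged invalid, not
raised.  Analysis uses only frames strictly before the earliest bleach.

Backgrounds per trace: the post-bleach offset (default; needs both dyes
bleached with ≥ 3 frames after), per-channel global dark offsets, or the
time-average of a user-supplied local-mask trace (an annulus around the
spot, as any spot extractor produces), which also follows slow drifts.
Background subtraction precedes the position-specific excitation
normalization (I_Aem|Aex × I_D(x, y)/I_A(x, y)) because the normalization
applies to signal, not to camera offset.

The molecule-wise (individual) gamma is the ratio of the acceptor-signal
decrease to the donor-signal increase across an acceptor-first bleach, on
background-corrected intensities with one guard frame on each side and at
least three frames per side; the donor jump must exceed 3× its standard
error, which excludes acceptor-only traces whose "jump" is pure noise.
Because the raw jump ratio still contains the leakage and direct-excitation
contributions, it carries a small bias of order delta·beta·gamma/E − alpha;
with typical alpha, delta ≈ 0.02 this is a few percent, and the global fit
is free of it.

## Distances

R0 follows from R0/Å = 0.2108 · (Phi_F,D · kappa² · n_im⁻⁴ · J)^(1/6) with
J = ∫ F̄_D(λ) ε_A(λ) λ⁴ dλ in M⁻¹ cm⁻¹ nm⁴.  The donor spectrum is
normalized to unit area over its full grid (so the input scale is
irrelevant), the acceptor extinction is pinned to its maximum value in
M⁻¹ cm⁻¹, and the integral is trapezoidal on the union grid of the overlap
range — spectra are smooth and densely sampled, so higher-order quadrature
buys nothing.  Defaults: n_im = 1.40 (between water and the biomolecule
interior, minimizing the worst-case refractive-index error) and
kappa² = 2/3, the isotropic dynamic average.  The 2/3 value is only
adopted when the anisotropy checks pass: combined residual anisotropy
r_C = √(r_A,∞ · r_D,∞) < 0.2 and Perrin steady-state estimate
r = r_0/(1 + τ/φ) < 0.2, plus the rate ordering
k_rot > k_FRET > k_diff > k_int of the dynamic-averaging regime.  The
pipeline refuses the distance stage (while still reporting efficiencies)
when the check is not vouched for.

Inverting ⟨E⟩ through the Förster relation yields the apparent distance
R_⟨E⟩ = R0 (1/E − 1)^(1/6).  For dyes on flexible linkers this is not a
physical distance: the measured efficiency is the average of E over all
sampled dye-position pairs, and efficiency averaging weights pairs
nonlinearly.  The physical quantity is R_MP, the distance between the mean
dye positions.  The accessible volume (AV) of each dye is computed with a
single-radius dye sphere on a regular grid: nodes within the linker length
of the attachment point, clash-free against obstacle spheres inflated by
the dye radius, and reachable by a flood-fill path with at least half the
linker width of clearance (defaults: linker width 4.5 Å, dye radius
3.5 Å, grid ≤ L/5).  Weights are uniform.  A spherical AV is provided as
the standard assumption when no structure is available, and externally
computed clouds can be imported for parity with dedicated AV software,
whose exact algorithms this package does not replicate.

R_⟨E⟩ → R_MP uses a lookup table: both clouds are centered, one is swept
in rigid-body separation (0.5-Å steps over 0.3–1.9 R0), and at each
separation the pairwise efficiency average gives R_⟨E⟩ while R_MP is the
separation itself; monotone cubic (PCHIP) interpolation inverts the sweep
and refuses extrapolation.  Clouds are thinned deterministically to ≤ 400
points for the pairwise average; the round-trip error of the table at
default resolution is below 0.1 Å.

## Uncertainty budget

Distance uncertainties are first-order propagations.  Writing the
corrected efficiency as E = F/T with T = gamma·D + F at representative
channel intensities (D, A, X) fixed by the forward model at a configured
mean burst size (default 100 detected photons) and factor magnitudes
(default alpha = 0.05, delta = 0.10, gamma = 0.8, beta = 1.0 — typical
published confocal values for the dye pairs this workflow targets):

* gamma: ΔE = E(1 − E) · Δgamma/gamma;
* alpha: ΔE = (gamma·D²/T²) · Δalpha;
* delta: ΔE = (gamma·D·X/T²) · Δdelta;
* backgrounds: per-channel relative intensity errors ΔI/I through the
  corresponding partials, the donor channel giving ΔR_bgD and the two
  acceptor channels combining in quadrature into ΔR_bgA.

Each ΔE maps to a distance error through |dR/dE| = R/(6·E·(1 − E)), and
independent sources combine in quadrature; the closed-form partials agree
with central differences to 1e−6 relative.  The Förster-radius term
ΔR = R·(ΔR0/R0) is added in quadrature to the efficiency-related total —
with the reference inputs (Δgamma/gamma = 10%, ΔI/I = 2%,
Δalpha/alpha = Δdelta/delta = 10%, ΔR0/R0 = 7% from the component
quadrature 0.04/0.01/0.025/0.05) this keeps the efficiency-related total
under 4 Å on 35–90 Å and the grand total under 6 Å on 35–80 Å at
R0 = 62.6 Å, which linear addition of the R0 term would not.

Two modeling notes.  Backgrounds enter as *relative* per-channel errors;
under this convention the background share of the budget peaks at the
long-distance end (where the acceptor channel starves) but the
short-distance end is gamma-dominated, because the shrinking donor channel
shrinks its background error with it.  An absolute-background convention
would make both ends background-dominated but requires a specific photon
budget; the relative form is the cleaner instrument-level statement.
Sensitivity diverges toward E → 0 and E → 1, so distances outside roughly
0.6–1.6 R0 are intrinsically poorly determined regardless of calibration.

The dye-pair self-consistency ratio
R_rel = f · ((1/E_lo − 1)/(1/E_mid − 1))^(1/6) compares two constructs
measured with the same dye pair; with matched donor positions and
environments the spectroscopic prefactor f ≈ 1 and R_rel is
quasi-independent of R0, so agreement of R_rel across dye pairs
cross-validates the mobile-dye model.  It is exposed as a report
(`rrel_report`) over user-supplied efficiency pairs.

## The simulator

The generator is the package's testbed: it emulates exactly the features
the corrections act on, with known ground truth.

Confocal: bursts are rectangular 1-ms windows at uniform random times over
a duration giving ~1% occupancy (≈ 10 bursts/s — typical of real
measurements with 10³–10⁴ bursts, and keeping chance coincidences rare);
burst photon totals are Poisson with mean 100 detected photons per
species (a configurable choice — burst brightness distributions are
instrument-specific), allocated multinomially to the three channels with
probabilities from the forward model; backgrounds are homogeneous Poisson
per channel at 0.5/ms defaults.  Donor-only and acceptor-only species
allocate as (1, alpha, 0) and (0, delta, 1).

TIRF: per-frame channel expectations from the same forward model
(brightness 500 counts/frame default), geometric (memoryless) single-step
bleach frames per dye with configurable means — e.g. a mean of 15 frames
at 2.5-Hz sampling emulates an acceptor-limited sample with ~6-s usable
traces — position-dependent excitation via user-supplied 2-D maps, Poisson
background and Gaussian read noise.

Deliberately not simulated: diffusion-shaped burst profiles, triplet and
blinking photophysics, saturation, EMCCD gain statistics, and spectral
crosstalk beyond the linear alpha/delta model.  Passing tests therefore
demonstrate that the estimators are unbiased and correctly ordered under
the linear ALEX model with realistic counting noise; they do not probe
photophysical artifacts (dye stacking, quenching, cyanine isomerization)
that real calibration measurements must still rule out by the anisotropy
and lifetime checks.

A single seed in the scenario description drives every draw, so all
simulator outputs are bit-reproducible.

## Degenerate inputs and tie-breaks

Events with zero total signal are flagged undefined and excluded; S of a
donor-only event with an exactly zero acceptor-excitation channel is 1 by
construction.  Burst search on an empty stream returns an empty list; a
background estimate with every bin above threshold raises.  The gamma/beta
fit refuses populations whose efficiencies span less than 0.05 (default)
and the single-species mode refuses an E interquartile range under 0.1,
where the regression would fit shot noise.  Lookup tables refuse
extrapolation; AV construction raises on buried attachment points (no
passable node within linker-base reach).  All tolerances above are
defaults, overridable through the run configuration.
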