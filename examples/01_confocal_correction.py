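"""Correct a simulated confocal ALEX measurement from raw photons to <E>.

Two double-stranded-DNA-like samples at different donor-acceptor spacings
are simulated with known correction factors (alpha = 0.05, gamma = 0.8,
delta = 0.1, beta = 1), then the full cascade -- background, burst search,
leakage/direct-excitation fits from the donor-only and acceptor-only
populations, global gamma/beta from the two FRET populations -- is run
blind and the recovered factors and mean efficiencies are compared with
the ground truth.
"""

import fretkit as fk


def make_stream(e_true: float, seed: int):
    truth = fk.GroundTruth(
        species=[
            fk.SpeciesSpec("DA", E_true=e_true, fraction=0.7),
            fk.SpeciesSpec("DO", fraction=0.2),
            fk.SpeciesSpec("AO", fraction=0.1),
        ],
        factors=fk.CorrectionFactors(alpha=0.05, beta=1.0, gamma=0.8, delta=0.1),
        seed=seed,
    )
    stream, _ = fk.simulate_confocal_stream(truth, n_bursts=2500)
    return stream


report = fk.run_confocal(
    [make_stream(0.2, 0), make_stream(0.6, 1000)],
    {"r0": 62.6, "av_radius": 10.0},
    names=["lo", "mid"],
)

f = report["factors"]
print("fitted factors (truth: alpha 0.05, delta 0.10, gamma 0.80, beta 1.00):")
print(f"  alpha = {f['alpha']:.4f}   delta = {f['delta']:.4f}")
print(f"  gamma = {f['gamma']:.4f}   beta  = {f['beta']:.4f}   [{f['provenance']}]")
for name, truth_e in (("lo", 0.2), ("mid", 0.6)):
    d = report["datasets"][name]
    print(
        f"{name}: <E> = {d['mean_E']:.3f} (truth {truth_e}), "
        f"R_<E> = {d['R_E']:.1f} Å, R_MP = {d['R_MP']:.1f} Å, "
        f"dR_total = {d['dR_total']:.1f} Å over {d['n_events']} events"
    )
print(f"R_rel (lo/mid apparent-distance ratio) = {report['r_rel']['value']:.3f}")
# <E> should land within a few 0.01 of the generating efficiency, R_<E>
# within the quoted uncertainty of the true separation, and R_rel near the
# value implied by the two efficiencies alone.
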