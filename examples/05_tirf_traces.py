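"""TIRF branch: bleach-step selection, per-trace background, individual gamma.

Simulates surface-tethered molecules sampled at 2.5 Hz under alternating
excitation with stochastic single-step bleaching (acceptor-limited, mean
15 frames, like a cyanine-acceptor sample), runs single-pair selection and
the correction cascade, and compares the molecule-wise (individual) gamma
estimate from acceptor-bleach jumps with the generating value.
"""

import fretkit as fk


def trace_set(e_true: float, seed: int):
    truth = fk.GroundTruth(
        species=[
            fk.SpeciesSpec("DA", E_true=e_true, fraction=0.7, brightness=500),
            fk.SpeciesSpec("DO", fraction=0.2, brightness=500),
            fk.SpeciesSpec("AO", fraction=0.1, brightness=500),
        ],
        factors=fk.CorrectionFactors(alpha=0.02, beta=1.0, gamma=0.8, delta=0.02),
        seed=seed,
    )
    traces, _ = fk.simulate_tirf_traces(
        truth, n_traces=350, frame_period=0.4, bleach_means=(40.0, 15.0),
        n_frames=60,
    )
    return traces


report = fk.run_tirf(
    [trace_set(0.2, 11), trace_set(0.6, 12)],
    {"r0": 62.6, "mode": "tirf"},
    names=["lo", "mid"],
)

print("valid single-pair traces:", report["n_valid_traces"])
f = report["factors"]
print(f"global fit:   gamma = {f['gamma']:.3f}, beta = {f['beta']:.3f} (truth 0.8, 1.0)")
print(
    f"individual:   gamma = {report['gamma_individual_mean']:.3f} "
    f"from {report['gamma_individual_n']} acceptor-first traces"
)
for name, truth_e in (("lo", 0.2), ("mid", 0.6)):
    d = report["datasets"][name]
    print(f"{name}: <E> = {d['mean_E']:.3f} (truth {truth_e}), n = {d['n_events']}")
# Individual gamma carries a small positive offset from leakage and direct
# excitation entering the raw jump ratio; the global fit is free of it.
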