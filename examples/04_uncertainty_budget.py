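"""Distance-uncertainty budget for a single smFRET-derived distance.

Propagates the reference uncertainties (gamma 10%, per-channel background
2%, leakage 10%, direct excitation 10%, Förster radius 7%) into the
uncertainty of R_DA across the usable distance range for R0 = 62.6 Å, and
prints the per-source breakdown at three representative distances.
"""

import numpy as np

import fretkit as fk

r0_frac = fk.r0_uncertainty(fk.R0Components(0.04, 0.01, 0.025, 0.05))
print(f"R0 uncertainty from components (n, Phi, J, kappa2): {100 * r0_frac:.2f}%")

inputs = fk.UncertaintyInputs(rel_dR0=r0_frac)
grid = np.arange(35.0, 90.5, 0.5)
curve = fk.total_distance_uncertainty(grid, inputs)

print(f"{'R/Å':>6} {'dR_gamma':>9} {'dR_bgD':>7} {'dR_bgA':>7} "
      f"{'dR_alpha':>9} {'dR_delta':>9} {'setup':>6} {'total':>6}")
for r in (40.0, 62.5, 85.0):
    row = curve[np.isclose(curve["R"], r)].iloc[0]
    print(
        f"{r:6.1f} {row['dR_gamma']:9.2f} {row['dR_bgD']:7.2f} "
        f"{row['dR_bgA']:7.2f} {row['dR_alpha']:9.2f} {row['dR_delta']:9.2f} "
        f"{row['dR_setup_total']:6.2f} {row['dR_total']:6.2f}"
    )

in_range = curve[curve["R"] <= 80.0]
print(
    f"max setup-related uncertainty (35-90 Å): "
    f"{curve['dR_setup_total'].max():.2f} Å;  "
    f"max total with the R0 term (35-80 Å): {in_range['dR_total'].max():.2f} Å"
)
# All values in Å. The gamma term peaks near R0 where dE is largest; the
# background share grows toward long distances where the acceptor channel
# starves; the R0 term grows linearly with distance and dominates the total.
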