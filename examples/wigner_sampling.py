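"""Sample 0 K Wigner initial conditions around the P well.

Draws 500 phase-space points from the ground-vibrational-state Wigner
distribution of the harmonic well, subselects 30 (the swarm size used for
the dynamics), and verifies the sampled widths against the analytic
quantum values.
"""

import numpy as np

from prochir.constants import HBAR
from prochir.pes import preset
from prochir.wigner import model_well_modes, sample_wigner, subselect

modes = model_well_modes(preset("stilbene"), "P")
print("well normal modes (cm^-1):", np.round(modes.frequencies, 1))

ens = sample_wigner(modes, 500, seed=7)
ics = subselect(ens, 30, seed=8)
print(f"sampled {len(ens)} points, subselected {len(ics)} initial conditions")

sq = np.sqrt(modes.masses_dof)
dq = (ens.positions - modes.reference) * sq
dp = ens.momenta / sq
for i, w in enumerate(modes.omega):
    Q, P = dq @ modes.modes[i], dp @ modes.modes[i]
    print(
        f"mode {i}: Var(Q)/[hbar/2w] = {Q.var() / (HBAR / (2 * w)):.3f}, "
        f"Var(P)/[hbar w/2] = {P.var() / (HBAR * w / 2):.3f}, "
        f"sigma_Q sigma_P / (hbar/2) = {Q.std() * P.std() / (HBAR / 2):.3f}"
    )
print("ratios near 1 mean the ensemble reproduces the minimum-uncertainty "
      "quantum ground state (expect ~ +/-6% scatter at n = 500; the test "
      "suite checks 3-standard-error agreement at n = 1e5).")
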