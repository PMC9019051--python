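# File formats

All exchange formats are plain text.

## Multi-frame XYZ

Standard dialect per frame: atom-count line, comment line, then
`element x y z` (Angstrom) per atom. Reader errors carry the offending
line number; an empty file reads as an empty list (not an error).

## Hessians

* Plain text: whitespace-separated square matrix, kcal/mol/A^2
  (3N x 3N for Cartesian input).
* Molden: only the `[FREQ]`, `[FR-COORD]` (Bohr) and `[FR-NORM-COORD]`
  sections are parsed.

## Transition tables (CSV)

Columns: `energy_eV`, `strength` (dipole strength a.u., or oscillator
strength with `strength_type="oscillator"`), `rotatory_strength` (a.u.,
positive = left-CPL-favoring), optional `geometry_id`.

## Spectra (CSV)

Columns: `wavelength_nm`, `energy_eV`, `eps`, `deps`, `g`
(relative units; `g` empty/NaN where undefined).

## Anisotropy curves (CSV)

Columns: `wavelength_nm`, `g`. Both curves of a scan must share the
wavelength grid.

## Trajectories (CSV)

Columns: `t_fs`, `tau_deg`, `phi_deg`, `state` (0/1), `pop_S0`,
`pop_S1`, `e_total_kcal_mol`.

## Phase-space ensembles (CSV)

Columns `q0..qN` (positions) and `p0..pN` (conjugate momenta) per sample
row; reduced-model ensembles have q0 = tau (rad), q1 = phi (rad).

## Run configuration (YAML)

Strictly validated; unknown keys are rejected. Blocks: `preset`,
`output_dir`, `log_level`, `seeds` (sampling/selection/dynamics/
fixtures; integers, mandatory after resolution), `pes` (the
SurfaceParams fields verbatim), `sampling` (n, k), `dynamics`
(FSSHParams fields), `spectra` (width, convention, blue_shift_ev,
strength_type), `kinetics` (rate constants, convention, regime, window).

## Acceptance output (JSON)

`scripts/acceptance.py` writes `{name: {"value": float, "n": int}}` per
measured quantity.
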