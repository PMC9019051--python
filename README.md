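# prochir

Desk-scale modeling of **electronic prochirality**: molecules whose P/M
helical enantiomers interconvert freely on the ground state but become
configurationally trapped on the first excited state, so that each
enantiomer photoisomerizes *unidirectionally* and circularly polarized
light (CPL) can photoresolve an effectively achiral sample.

The prototype systems are cis-stilbene and cis-stiff-stilbene. Their
helical-inversion barriers are small on S0 (1.6 and 4.9 kcal/mol — the
conformers racemize thermally) but large on S1 (19 and 13 kcal/mol),
while the S1 surface slopes steeply along the ethylenic twist tau toward
the S1/S0 conical intersections at tau = +-90 deg. Excitation therefore
"stiffens" chirality: P rotates clockwise to +90 deg, M anticlockwise to
-90 deg, and the chiral photocyclization product DHP
(4a,4b-dihydrophenanthrene) forms enantioselectively (S,S from P, R,R
from M).

The package is aimed at photochemists and method developers who want a
tested, fully synthetic sandbox for these mechanisms: an analytic
two-state model surface calibrated to the published barriers, 0 K Wigner
sampling, fewest-switches surface hopping, chirality-aware trajectory
analysis, Gaussian-broadened absorption/ECD spectra with Kuhn
anisotropy factors g = 4R/D, and the photostationary kinetic model of
CPL photoresolution, whose enantiomeric excess is, in closed form,

    ee = |[S,S-DHP] - [R,R-DHP]| / ([S,S-DHP] + [R,R-DHP])
       = |k_ct (g_DHP - g_stil g_DHP) + 2 k_rac (g_DHP - g_stil)|
         / [ k_ct (1 - g_stil) + 2 k_rac (1 - g_stil g_DHP) ]

with limits ee -> |g_DHP| for fast photoisomerization
(k_ct >> k_rac) and ee -> |g_DHP - g_stil| / (1 - g_stil g_DHP) for
fast ground-state racemization (k_rac >> k_ct). See `docs/methods.md`
for the models and the choices behind them.

## Worked example

Run a 30-trajectory surface-hopping swarm from Wigner initial conditions
in the P well of the stilbene-calibrated surface:

```
$ python examples/unidirectional_swarm.py
trajectories          : 30
clockwise fraction    : 1.000   (tau first reaches +90 deg)
anticlockwise fraction: 0.000   (tau first reaches -90 deg)
helicity inversions   : 0   (P->M flips while on S1)
mean time to funnel   : 401 fs   (sub-picosecond passage)
```

Every trajectory of the P enantiomer reaches the +90 deg intersection —
the clockwise funnel — within a few hundred femtoseconds, and none flips
to the M helix while excited: excited-state chirality is frozen even
though the same molecule racemizes freely on S0.

The photoresolution side:

```
$ python examples/cpl_photoresolution.py
g_stil = 0.01, g_DHP = 0.02
closed-form ee at k_ct = k_rac : 1.3313 %
  limit fast_isomerization  : 2.0000 %
  limit fast_racemization   : 1.0002 %
five-species steady-state ee   : 1.3335 % (agrees with the closed form to O(g^2))
```

The ee is bounded by the anisotropy factors; realistic |g| < 0.01 is why
CPL photoresolution yields sub-percent excesses. The other examples
cover the surface report, Wigner sampler moments, the Landau-Zener
validation of the hopping algorithm, and enantiomer-antisymmetric ECD
spectra.

A thin CLI wraps the same library:

```
prochir demo --seed 7            # full synthetic chain + JSON summary
prochir pes characterize --preset stilbene
prochir dynamics run --preset stilbene --well P --n 30 --seed 7
prochir spectra broaden --transitions trans.csv --width 0.2 --shift 0.7
prochir scan --regime fast_isomerization --gstil gstil.csv --gdhp gdhp.csv
```

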