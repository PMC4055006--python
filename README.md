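# magtarget

Modelling toolkit for **magnetically targeted cell delivery**: the physics of
attracting superparamagnetic iron oxide (SPIO)–labeled mesenchymal stem cells
(MSCs) to a permanent magnet, a Monte-Carlo simulator of cell capture from
tube flow, and the summary-statistics machinery used to analyze such
targeting experiments.

It is written for researchers in cardiovascular cell therapy and
magnetic-targeting biophysics who want to reason quantitatively about a
common bench setup: a cylindrical NdFeB magnet pressed against a
blood-vessel phantom, with labeled cells flowing past at physiological
velocities.

## What it computes

**Magnetostatics.** An axially magnetized cylinder (radius R, length L,
remanence Br) modelled with the equivalent-surface-charge picture. On the
axis of the pole face,

    Bz(z) = (Br/2) [ (z+L)/√((z+L)²+R²) − z/√(z²+R²) ]

and off-axis the exact closed form in Bulirsch's generalized complete
elliptic integral `cel` is used. The remanence is calibrated so the modelled
pole-face field matches a measured surface flux density (600 mT for the
8-mm magnet that motivates the defaults).

**Cell magnetics.** An SPIO-labeled cell carrying m_Fe of elemental iron as
magnetite has saturation moment m_sat = M_s · (1.382 m_Fe / ρ) with
M_s = 4.8×10⁵ A/m and ρ = 5180 kg/m³. The attraction force on the
point-dipole cell is F = m(|B|) ∇|B|, and its overdamped drift through the
medium is v = F / (3πηd) (Stokes mobility).

**Capture simulation.** Cells released at flux-weighted inlet positions in
Poiseuille flow through a 2.3-mm-ID tube are integrated (adaptive Cash-Karp
Runge-Kutta, vectorized over the batch) until they touch the wall within the
magnet's footprint (captured, Q1) or leave the tube (escaped, Q2). The
capture efficiency is CE = Q1/(Q1+Q2) × 100%.

**Statistics.** Pearson correlation (t-based p), pooled-variance Student t,
one-way ANOVA with Fisher's LSD post-hoc — all operable directly on
mean ± SD ± n summaries as well as raw replicates — plus fold ratios,
relative MRI signal intensity, cell-retention rate, and capillary density.

**Synthetic data.** Seeded generators for labeled-cell populations
(truncated-normal diameter 19.3 ± 5 µm on [6, 36] µm; iron 21.77 ± 3.62
pg/cell), group replicates regenerated from printed summaries, and two-group
retention experiments with lognormal animal-level noise; packaged,
checksummed fixture tables of the reference summary values.

## Worked example

```python
import numpy as np
from magtarget import (CellSpec, default_magnet, on_axis_field, gradient_at,
                       magnetic_force, drift_velocity, ce_velocity_curve)

magnet = default_magnet()           # 8 mm x 8 mm cylinder, 600 mT face field
print(magnet.remanence_t)           # 1.3416  (T, calibrated remanence)
print(on_axis_field(1e-3, magnet))  # 0.4503  (T at the 1-mm working distance)

fs = gradient_at((0.0, 0.0, 1e-3), magnet)
print(fs.grad_bmag[2])              # -141.9  (T/m axial |B| gradient)

cell = CellSpec()                   # 19.3 um MSC, 21.77 pg Fe
force = magnetic_force(cell, fs, magnet=magnet)
print(force.moment_a_m2)            # 2.788e-12 (A m^2 saturation moment)
print(np.linalg.norm(drift_velocity(cell, fs)))   # 2.17e-3 (m/s drift)

table = ce_velocity_curve([4e-3, 20e-3, 100e-3, 500e-3],
                          n_cells=2000, seed=1)
print(table[["velocity_m_per_s", "ce_pct"]])
#    velocity_m_per_s  ce_pct
# 0             0.004    99.4
# 1             0.020    46.5
# 2             0.100    11.4
# 3             0.500     2.3
```

A cell 1 mm from the pole face feels ~0.45 T and a gradient of ~140 T/m,
giving a drift of ~2 mm/s — commensurate with venous-scale flow (4 mm/s),
which is why capture is near-complete there, but negligible against
arterial-scale flow (500 mm/s), where the simulated capture efficiency
collapses more than forty-fold. The same qualitative decline (85% → 1.6%)
is what the bench experiment that motivates these defaults reports; exact
CE values are not a fit target because the bench recirculation and cell
adhesion are deliberately unmodelled (see `docs/methods.md`).

## Command line

```
magtarget field-map --z-m 0.001 --out field.csv     # B and d|B|/dr profile
magtarget capture --velocity 0.004 --n-cells 2000   # one capture run
magtarget ce-curve --n-cells 2000 --seed 1          # CE vs velocity sweep
magtarget stats --summaries groups.csv              # t / ANOVA+LSD
magtarget synth --what cells --n 1000 --out pop.csv # synthetic inputs
magtarget fixtures list                             # packaged summary tables
magtarget reproduce                                 # self-check, nonzero on failure
```

Config files are YAML with explicit SI unit suffixes (`inner_radius_m`,
`mean_velocity_m_per_s`); every run writes a provenance record (config hash,
version, seed).

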