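# Methods

## Field model

The magnet is an axially magnetized NdFeB cylinder treated as uniformly
magnetized. Its field outside the body is computed from the
equivalent-surface-charge model (two oppositely "charged" pole-face disks of
density ±M = Br/μ0) in the exact closed form of Derby & Olbert (Am. J. Phys.
78:229, 2010), evaluated with a vectorized Bulirsch `cel` iteration. This
replaces the finite-element approach often used for such field maps: it is
mesh-free, deterministic, and testable — the suite checks it against an
independent brute-force Riemann quadrature over the two disks (agreement
better than 0.1%, typically ~1e-5 relative) and against ∇·B = 0.

Choices and caveats:

- **Magnet length.** Only the 8-mm diameter of the reference magnet is
  known; the length defaults to 8 mm (1:1 aspect, typical for small NdFeB
  cylinders) and is configurable. All derived numbers depend on it through
  the calibration below.
- **Calibration.** A "600 mT surface field" is ambiguous for the ideal
  uniformly magnetized cylinder, whose field diverges on the pole-face edge
  ring (the real maximum sits at the flank). The default calibrates the
  remanence so the **pole-face center** field is 600 mT
  (Br = 2·0.6·√(L²+R²)/L = 1.3416 T for R = 4 mm, L = 8 mm); a flank
  calibration (|B| = 600 mT at the edge-margin point) is selectable.
- **Edge clamp.** Points within 0.1 mm of an edge ring are clamped outward
  to that margin and flagged; evaluation inside the body is an error.
- **Gradients** are central differences with h = 1 µm by default; the
  analytic on-axis derivative is used as a cross-check. At h = 1 µm the
  truncation and round-off errors are both far below the 0.5% test
  tolerance.
- **Frames.** The canonical magnet frame has the pole-face center at the
  origin and the axis along +z; lab placement is a rigid transform
  (`MagnetSpec.with_pose`).

## Cell moment and force

The cell's elemental iron m_Fe is assumed fully present as magnetite
(mass factor 231.53/(3·55.845) = 1.382; ρ = 5180 kg/m³; bulk saturation
magnetization M_s = 4.8×10⁵ A/m), giving a saturation moment
m_sat ≈ 2.79×10⁻¹² A·m² for the mean 21.77-pg load. Although Prussian-blue
imaging shows the particles distributed as a spherical shell around the
nucleus, the cell is collapsed to a **point dipole** at its center: the
shell-versus-point correction is of order cell radius / working distance
(≈ 10 µm / 1 mm = 1%) and is ignored.

The force law is the saturated point-dipole form **F = m(|B|) ∇|B|** with
the moment aligned to the local field. An optional Langevin field dependence
scales m_sat by L(m_p·B/kT) with m_p the moment of one 62-nm magnetite
particle; at the 0.1–0.6 T working range L > 0.999, i.e. the label is
effectively saturated, which is why "saturated" is the default model.
Drift is Stokes mobility v = F/(3πηd); the medium defaults to water-like
culture medium (η = 1.0 mPa·s, 1000 kg/m³, 37 °C), and gravity/buoyancy is
neglected (density-matched suspension).

## Capture simulation

Geometry is genuinely 3-D: the magnet beside the tube breaks axisymmetry.
The tube axis is lab x ∈ [0, 20 mm]; the magnet axis is +y with the pole
face tangent to the outer wall at the 10-mm midsegment, so the nearest lumen
wall sits at the 1-mm working distance. The magnet's orientation is not
dictated by the reference setup beyond "placed tightly at the midsegment";
perpendicular-to-tube with face tangent to the wall is the reading
consistent with the stated 1-mm working distance.

- **Kinematics.** Overdamped: dx/dt = v_flow + v_drift. Inertia is
  neglected (Stokes number ≪ 1 at all study velocities). The flow is
  undisturbed Poiseuille, v(ρ) = 2v̄(1−(ρ/R)²) — the suspension at
  5×10⁴ cells/ml is dilute, so cell feedback on the flow and cell–cell
  interactions are ignored.
- **Integrator.** Embedded Cash-Karp RK4(5) with per-cell adaptive steps
  (rtol 1e-6, atol 1e-9 m), vectorized across the batch; step displacement
  is additionally capped at 0.2 mm so a step cannot tunnel past the capture
  zone. Cells whose step size underflows or that exceed the time budget
  (200 tube residence times) are flagged and excluded — zero flagged in all
  released configurations.
- **Capture rule.** First wall contact (cell surface touching the lumen
  wall, i.e. transverse offset ≥ R_t − d/2) within the magnet's axial
  footprint ± one magnet radius (|x − x_mag| ≤ 2R_mag by default) is
  capture; contacts elsewhere are elastic — the cell is projected back
  inside and continues — avoiding a model of unknown adhesion physics.
- **Inlet sampling.** Flux-weighted over the accessible inlet disc (for
  Poiseuille the CDF in x = (ρ/R)² is 2x − x², inverted in closed form);
  cells are drawn from the labeled-MSC population model. All randomness
  flows from a single integer seed; identical configuration + seed gives
  bit-identical results.
- **2-D mode.** A mid-plane (z = 0) mode supports validation: with a
  uniform-force stub field (`LinearBmagField`) and plug flow, the
  capture/exit threshold height has the closed form y* = uL/v − R_eff, and
  the capture fraction is the slab formula min(1, uL/(vH)). The simulator
  reproduces the threshold to better than 1% of the gap across ten
  parameter sets.

**What capture results do and do not claim.** With the study
parameterization the simulated CE falls from ≈ 99% at 4 mm/s to ≈ 2% at
500 mm/s — monotone and more than ten-fold, matching the qualitative
behavior (and the 11.3% at 100 mm/s closely) of the bench measurement
(85.0 → 1.6%). Digit-level agreement is *not* claimed or targeted: the bench
run recirculated 20 ml through the tube for an unreported number of passes
and involved adhesion at the wall, both outside this single-pass,
adhesion-free model. The comparison is therefore trend and order of
magnitude, enforced as properties (monotone decline; CE(4) > 10×CE(500))
rather than as value fits.

## Statistics

- "Student t test" is implemented as the pooled-variance two-sample t
  (df = n₁+n₂−2); Welch is available behind a flag. All p-values are
  two-sided.
- One-way ANOVA and Fisher's LSD post-hoc work directly from (mean, sd, n)
  summaries; raw replicates are reduced to summaries first, which is
  algebraically exact. LSD is deliberately uncorrected for multiplicity —
  that mirrors the analysis style being reproduced and is a documented
  limitation, not a recommendation.
- The Pearson p uses the exact t transform r√(n−2)/√(1−r²). For the
  CE-versus-velocity data the correlation is computed over all 12 replicate
  points (4 velocities × triplicate) — the only reading under which the
  reported p ≈ 0.003 is attainable (the 4 means alone give p ≈ 0.23). A
  permutation test on this heavily skewed velocity design gives a *smaller*
  p than the t transform (~1e-4 versus 3.3e-3; the t-based p is
  conservative here); the suite asserts agreement of the two only on
  near-normal data and concordant rejection on the CE data.

## Synthetic data

The generators emulate the *statistical shape* of the reference
measurements, not their biology:

- **Cell population.** Diameter: truncated normal, mean 19.3 µm, SD 5 µm on
  [6, 36] µm. Only the range and mean of the real population are known; the
  SD is a package default (configurable) and no claim is made of matching
  the true distribution. Truncation shifts the realized mean by ≈ +0.05 µm.
  Iron: truncated normal 21.77 ± 3.62 pg, > 0.
- **Group replicates** are drawn normal(mean, sd) per group (truncated at
  zero for count-like measures) — the inverse of mean ± SD reporting. Passing
  tests on these inputs demonstrates correct inference on the *assumed*
  sampling model; real data may violate normality in ways this cannot probe.
- **Retention experiments** use lognormal animal-level noise (unit mean,
  CV 0.3 by default): counts are positive and right-skewed. The estimated
  Mag/NonMag ratio of group means carries a small positive finite-sample
  bias (≈ (1 + CV²/n), under 2% at n = 6), visible in the parameter-recovery
  numbers.
- **Fixtures** transcribe printed summary values only (never numbers read
  off figures) and are SHA-256-checksummed at load.

## Problem sizes

Default validation runs use 2000 cells per velocity for the CE curve
(Monte-Carlo SE ≤ ~1.1 percentage points), 30 random field points against
the quadrature oracle, 10 slab-oracle parameter sets, and 1000 seeds for
retention-fold recovery; all are arguments, chosen as the sizes at which the
Monte-Carlo error is comfortably below every tolerance being checked.

## Known limitations

- Single-pass flow; no recirculation kinetics, no adhesion model, no
  cell–cell aggregation (all present in the bench setup being emulated).
- Ideal uniformly magnetized cylinder; no demagnetization-curve knee, no
  backing iron, no magnet arrays.
- Point-dipole cell; no shell geometry, no label dilution over divisions,
  no viability effects.
- Inference tools reproduce an uncorrected-LSD analysis style; users
  wanting multiplicity control should correct downstream.
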