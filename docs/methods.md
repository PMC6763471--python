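# Methods

## Model

The single-cell growth model treats a yeast cell as a thin spherical
elasto-viscoplastic shell enclosing osmotically active water
(*V*<sub>os</sub>) and an inert solid volume (*V*<sub>b</sub>, constant;
the wall radius is computed from the total volume
*V*<sub>t</sub> = *V*<sub>os</sub> + *V*<sub>b</sub>).  Three state
variables are integrated — osmotic volume, turgor pressure and internal
osmolarity — plus a reference radius recording accumulated plastic strain
(see below).  The assumptions worth keeping in mind:

* spherical geometry with uniform wall stress; constant wall thickness;
* ideal osmometer behaviour (Boyle–van 't Hoff) with a single lumped
  internal osmolyte pool;
* osmolyte uptake proportional to membrane area, consumption proportional
  to osmotic volume — the coarsest description that yields a finite
  final size, r_final = 3·k_uptake/k_consumption;
* all three concentration terms (uptake, consumption, dilution) act on
  *V*<sub>os</sub>: osmolytes reside in, and are diluted by, the
  osmotically active water, which keeps the amount bookkeeping
  n = c·V<sub>os</sub> exact;
* wall mechanics: Hookean strain ε = (1−ν)/E · Π<sub>t</sub>r/(2d) in
  series with a Bingham element whose strain *rate* is
  ϕr/(2d)·max(Π<sub>t</sub>−Π<sub>ct</sub>, 0); the yield threshold is
  included in the plastic branch (f_m is continuous there, so the
  convention only names the boundary regime).

The default parameter set describes a haploid cell at 303 K in 240 mM
medium: L_p = 1.19e-6 μm s⁻¹ Pa⁻¹, E = 2.58e6 Pa, ν = 0.5, d = 0.115 μm,
ϕ = 1e-3 Pa⁻¹ s⁻¹, Π_ct = 2e5 Pa, k_uptake = k_consumption = 2e-16
(mmol μm⁻² s⁻¹ / mmol μm⁻³ s⁻¹), r_b0 = 0.3 μm (solid), r_os0 = 0.1 μm
(osmotic), Π_t0 = 2e5 Pa.  The initial osmolarity is derived, not set:
c_i0 = c_e + Π_t0/RT ≈ 319.4 mM (zero initial water flux).  The two
printed initial radii are interpreted as solid vs osmotic compartments;
with them the plateau radius carries a +0.1% offset over the closed-form
3·k_u/k_c (the fixed point satisfies r³ − 3(k_u/k_c)r² − r_b0³ = 0).

### Units

Internally: μm, s, Pa, mmol; concentrations cross the API in mM
(1 mM = 1e-15 mmol μm⁻³).  In this system Table-style constants compose
without conversion factors and k_uptake/k_consumption is a length — the
dimension check behind the final-radius law.

### Reference radius and regimes

The reference radius r_ref integrates only the plastic strain rate,
ṙ_ref/r_ref = ϕr/(2d)·f_m.  It is non-decreasing, constant during purely
elastic episodes (hyperosmotic shock), and tracks the physical radius up
to the elastic offset during steady growth.  Each output sample carries a
regime flag: elasto-plastic (EP) iff Π_t ≥ Π_ct, else elastic (E).

## Numerics

* Stiff integration via `scipy.integrate.solve_ivp`; LSODA for single
  compartments, BDF for coupled systems (the inter-compartment exchange
  modes defeat LSODA's Newton iteration; BDF at the same tolerances is
  robust).  rtol 1e-8 for presentation runs, 1e-6 inside optimisation and
  sweeps; atol per state (1e-6 μm³, 1e-2 Pa, 1e-9 mM, 1e-6 μm).
* Solver state keeps concentrations in mM so all state magnitudes are
  comparably scaled for the numerically differenced Jacobian.
* External-osmolarity steps split the integration into segments, so
  discontinuities always fall on segment boundaries.
* The Bingham kink at Π_t = Π_ct is *not* event-handled: steady growth
  rides a fraction of a pascal above the threshold (the plastic relaxation
  rate Eϕ/(1−ν) ≈ 5×10³ s⁻¹ pins the excess), so terminal events there
  chatter; f_m is continuous and the stiff solvers integrate the kink
  directly.
* A turgor floor at Π_t = 0 is event-handled (the membrane detaches
  rather than pulling the wall inward — plasmolysis-like; the model text
  defines no negative-pressure mechanics, so clamping is a package
  choice).  While clamped, turgor is frozen at zero; a second event
  releases the clamp when net water flow turns inward.
* Degenerate parameter probes during optimisation (negative volumes from
  wild trial steps) are guarded in the right-hand side and surface as a
  non-converged start, never as a crash.

## Mother–bud coupling

After a delay t_budstart (default 117 min, the estimated mean time to
first budding) a bud is created from the mother's state: same small
osmotic radius the mother started with, solid volume scaled accordingly,
osmolarity inherited (continuity of the shared cytoplasm), and a freshly
deposited *unstressed* wall — reference radius equal to the actual radius
and zero turgor.  Turgor is wall stress, not a cytoplasmic property: a
zero-strain wall cannot carry pressure, and seeding the bud with the
mother's turgor would freeze a soft-walled bud at an unphysical
high-pressure/zero-strain equilibrium.  Water influx pressurises the new
bud within seconds; the mother donates a small volume at that instant
(her volume series shows a kink at bud creation).  Mother and bud
exchange water down the water-potential difference Π_t − Π_i and
osmolytes down the concentration difference.

The exchange coefficients are deliberately fast — the modelled regime is a
*shared cytoplasm*, with gradients vanishing on the observation timescale.
They scale with the bud's current surface: L_x = 10⁷·L_p·G_bud(t),
k_x = 10¹¹·k_uptake·G_bud(t)/c_e.  The magnitudes matter: the bud's own
membrane supplies both an osmolyte surplus (surface-to-volume favours a
small compartment) and a share of the mother's water-influx drive
(~100 Pa), and the residual water-potential edge the bud can hold is the
drive divided by the exchange-to-membrane conductance ratio.  Because
plastic yield responds to *sub-pascal* turgor excess, that edge must be
pushed to ~10⁻⁵ Pa (hence the large factors); with slower exchange the bud
grows like a free cell at any extensibility ratio and the wall-anisotropy
phenomenology disappears.  Both coefficients are config-exposed
(`CoupledParams.L_x/k_x`) for sensitivity work.

With this coupling the bud expands only when its wall is much more
extensible than the mother's: the plastic strain rate scales with radius,
so at equal ϕ the small compartment cannot yield.  The expansion threshold
(bud volume at least doubling over a 600-min horizon) lies between 10^1
and 10^1.5; between two buds, any initial size difference is
self-amplifying and the smaller bud stays far behind.  Varying the bud's
Young's modulus instead (at equal ϕ) separates differently: a much softer
bud wall cannot sustain turgor at any size (its maximum bearable pressure
2E_b·d/((1−ν)e·r₀) falls below Π_ct), so it balloons at the mother's
expense, while equal or stiffer walls leave the bud stunted — wall
extensibility, not elasticity, is the quantity that permits orderly bud
growth.

## Active osmotic response

The HOG-type extension is a deliberately minimal turgor-deficit sensor: an
active fraction H with logistic activation
Ḣ = k_act·max(0, 1−Π_t/Π_ref)(1−H) − k_deact·H drives production of an
internal osmolyte pool (glycerol) that adds to Π_i,
ċ_gly = k_gly·H − k_leak·c_gly − dilution.  It shares the coupling
contract of a full signalling cascade model — input turgor, output
osmolyte production — so a mechanistic HOG model can be substituted behind
`simulate_with_hog` without touching the growth core.  Defaults (k_act =
0.01 s⁻¹, k_deact = 5e-3 s⁻¹, k_gly = 1 mM s⁻¹, k_leak = 1e-4 s⁻¹, Π_ref =
2e5 Pa) were calibrated once so that recovery from a 240→500 mM step
completes in ~16 min versus ~55 min passively.  HOG-coupled scenarios
start at r₀ ≥ 1.2 μm so signalling species are not artificially dilute in
a near-zero-volume cell.  With k_gly = 0 the cell trajectory is computed
by the passive solver (bitwise identical to `scgm.simulate`) and H is
integrated on top of its turgor output with a 60-s step cap (so the solver
cannot leap over a shock transient while H is still identically zero).

The surrogate reproduces the four-phase shock response (fast shrinkage →
Hog1 activation → size/turgor restoration → growth resumption) and the
faster-with-signalling recovery ordering for 400–600 mM steps.  What it
does *not* model: two-branch signalling, transcriptional delays, gated
glycerol export (Fps1).  The last omission matters for hypoosmotic steps:
the package's volume overshoot after a hypoosmotic step is the passive
mechanism (excess accumulated osmolytes over-swell the cell above its
growth trend, then consumption relaxes it back over tens of minutes) and
appears once the cell has fully adapted to the preceding hyperosmotic
phase; a rapid Fps1-type glycerol dump would sharpen it.

## Fitting

`CoupledVolumeModel` binds the coupled model to one observed mother+bud
pair (time in minutes, total volumes in μm³ — microscopy sees whole
cells).  Free parameters: k_uptake, k_ratio = k_uptake/k_consumption,
ϕ_mother, q = ϕ_bud/ϕ_mother, r₀ and t_budstart (dropped when the data
supply it).  The solid volume is held at the reference value (r_b0 =
0.3 μm) rather than scaled with the fitted r₀ — scaling it by the
reference solid-to-osmotic proportion (3:1 in radius) would give a
daughter cell a ~200 μm³ solid core, contradicting the observed volume
scale of newborn cells; `base_params` exposes the choice.

The objective is χ² = Σ[(V_obs − V_sim)/σ]² over both compartments with a
constant noise scale σ (default 1 μm³; the χ² ≤ 50 retention threshold is
meaningful only relative to σ and the series length).  Optimisation is
bounded trust-region least squares in a log-scaled space (k_uptake,
ϕ_mother, q on log10), multi-started from one data-driven guess (bud start
from the first bud observation, r₀ from the first mother volume, k_ratio
from the maximal volume via the final-radius law) plus Latin-hypercube
draws; the finite-difference step (1e-3) sits well above the ODE solver
noise floor, without which the Jacobian is unusable.  Fits are
deterministic given the seed; a fit that fails every start returns a
non-converged result rather than raising.

Identifiability, measured on noiseless synthetic data: k_uptake, k_ratio,
r₀ and t_budstart recover to well under 1%; ϕ_mother and q lie on a
compensation ridge q·ϕ_mother ≈ ϕ_bud and the profile χ² over q (other
parameters re-optimised) is flat above the generating ratio — q is a lower
bound, not a point estimate.  Post-fit filtering retains fits with
k_ratio ≥ 1 μm and χ² ≤ 50 (both inclusive); cohort summaries report
medians, IQRs and a Pearson correlogram including the maximal observed
mother/bud volumes.

## Synthetic cohorts

The generator emulates the microscopy observable: forward-simulate the
coupled model at parameters drawn from independent log-normals around
cohort-typical medians (k_uptake 1.4e-16, k_ratio 1.21 μm, ϕ_mother
5.5e-4 Pa⁻¹ s⁻¹, q 230, r₀ 1.2 μm, t_budstart 93 min; log-spreads from
the corresponding interquartile ranges), sample total volumes every 3 min
over a 300-min first cycle, add i.i.d. Gaussian volume noise (σ = 1 μm³)
and blank the bud before its start time.  Cells whose bud never expands
are flagged `degenerate`, never dropped.  What the generator does *not*
emulate: segmentation outliers and tracking errors, correlated
(cell-shape) noise, multiple cycles, and any parameter correlations — so
recovery benchmarks validate the estimator under the model, not the
microscopy pipeline.

## Problem sizes

Default test and acceptance workloads: single-cell runs to 1.5e5 s
(plateau detection at < 1e-6 μm radius change per hour); coupled sweeps on
≈ 20-point log grids over 600 min horizons; recovery on one noiseless cell
plus a 6-cell noisy cohort with reduced optimiser budgets (2–3 starts).
These sizes make every result reproducible on a laptop-class single core
in minutes; all of them are parameters, not constants, and scale up
directly.
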