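# Methods

## Model

Two constitutive classes of cancer cells share a culture well: class 1
(sensitive, low basal P-gp) and class 2 (resistant, high basal P-gp).
Within a class, the membrane P-gp level of an individual cell is a
continuous activity `x`, normalized log-fluorescence on `[0, 1]`.  The
class state is a density `u_i(x, t)` (cells per unit activity); the
extracellular microvesicle (MV) pool is a single well-mixed
concentration `M(t)` (arbitrary units).  The model deliberately has no
spatial structure (well-mixed cultures; MV diffusion is fast compared
with proliferation) and no class switching (constitutive P-gp levels
change only on mutational time scales, beyond the ~10-day horizons
simulated here).

Each density evolves by a hyperbolic transport equation whose
left-hand side is conservative (phenotype drift; preserves cell number)
and whose right-hand side is non-conservative (birth and death):

* **Transfer velocity** `v_T = κ(C) · M · (x_max − x)/span`.  Drift
  toward higher P-gp, proportional to the MV pool.  The amplitude is a
  two-level switch — `κ0` without drug, `κD` at or above a threshold
  concentration — because the experiments this emulates contrast only
  the absence and presence of one dose; the calibrated `κD/κ0 = 10`
  encodes the ten-fold drug contrast of the transfer amplitude.  The
  boundary factor `(x_max − x)` makes the advective flux vanish at the
  upper boundary.
* **Induction velocity** `v_I = α_I · Hill(C) · (x_max − x)/span` with
  `Hill(C) = C^h/(C50^h + C^h)`.  Drug-gated (zero without drug):
  individual surviving cells up-regulate P-gp under exposure
  (Lamarckian induction).
* **Birth kernel** `W_i(x, x') = r_i(x') φ_i(x | x')`.  Parents at `x'`
  divide at rate `r_i(x') = r_max,i · max(0, 1 − c_cost · x')` — running
  efflux pumps costs proliferative capacity — and daughters land on a
  truncated Gaussian centered at `x' + λ_rev (b_i − x')` with scale
  `σ_div`: each division pulls the lineage a fraction `λ_rev` back
  toward the basal center `b_i`.  Truncation is renormalized on the grid
  quadrature, so birth mass equals `r_i(x')` exactly (no boundary leak).
* **Crowding decay** `g_i = (N_tot/K_cap) · r̄` with `r̄` the
  population-mean division rate.  For a stationary activity profile this
  reduces exactly to logistic growth of the total with capacity `K_cap`.
* **Therapy function** `T(x, C) = δ_max · Hill(C) · σ(x)` with the
  protective sigmoid `σ(x) = 1/(1 + exp((x − x_half)/w_prot))`:
  killing increases with dose and decreases with P-gp (Darwinian
  selection of high expressers).  Applied to both classes; the resistant
  class largely escapes through its high basal `x`.
* **MV pool** `dM/dt = γ_shed ∫ x̂ u₂ dx − γ_up M ∫ u₁ dx − c_clear M`,
  with `x̂` the relative activity.  Resistant cells shed (more so at
  higher P-gp), sensitive cells take up; clearance is available but off
  by default (the pool equation carries no degradation term in the
  underlying description).  By default the resistant class neither takes
  up MVs nor responds to induction — it showed no P-gp changes under
  any condition — so its velocity is identically zero.

**Antagonism.** The advection terms push `u₁` toward the resistant
profile; the birth kernel pulls it back toward basal at rate `≈ r λ_rev`.
Whether resistance emerges in the sensitive class is a competition
between these, which is why weak transfer amplitudes produce
proportionally weak, reversible displacements.

## Basal distributions

The *operational* basal profile of a class is the drug-free stationary
density: the Perron eigenvector of the birth operator (with velocities
zero and an `x`-independent death rate, the normalized density converges
to it).  The truncated Gaussian `N(b_i, s_basal)` parameterizes the
kernel's reversion target and seeds the stationary profile, whose mean
sits within ~2e-3 of `b_i` (the proliferation cost drags it slightly
down).  Scenario initial conditions and relaxation targets use the
stationary profile; with `λ_rev` near 1 the stationary width is
`σ_div/sqrt(λ(2−λ)) ≈ σ_div`, so `σ_div = s_basal` keeps seed and
stationary profiles consistent.

## Parameters (calibrated defaults)

| name | value | units | role |
|---|---|---|---|
| `b1`, `b2` | 0.25, 0.70 | activity | basal centers (well-separated cytometry modes) |
| `s_basal`, `sigma_div` | 0.07 | activity | basal width / daughter dispersion |
| `r_max_1`, `r_max_2` | 0.035, 0.030 | 1/h | max division rates (~21 h and ~29 h effective doubling) |
| `c_cost` | 0.3 | — | efflux cost slope |
| `K_cap` | 2e6 | cells | well capacity |
| `lambda_rev` | 0.95 | — | per-division reversion fraction |
| `alpha_I` | 0.03 | activity/h | induction amplitude at saturating dose |
| `C50`, `h_drug` | 40 nM, 2 | — | dose response (effects most prominent above ~50 nM) |
| `delta_max` | 0.12 | 1/h | max kill rate |
| `x_half`, `w_prot` | 0.45, 0.06 | activity | protection sigmoid (between the two modes) |
| `kappa0`, `kappaD` | 2e-4, 2e-3 | activity/h per MV unit | transfer amplitudes (ten-fold drug contrast) |
| `gamma_shed` | 5e-6 | MV/cell/h | shedding per resistant cell |
| `gamma_up` | 1e-6 | 1/cell/h | uptake per sensitive cell |
| `drug_transfer_threshold` | 1 nM | — | dose gating `kappaD` |
| `mv_clearance` | 0 | 1/h | optional pool clearance (off) |

The exact fitted values behind the original experiments are not
published; these defaults were calibrated, once, so that the model's
emergent behaviour matches the printed anchors of the study design: a
protocol-1 growth delay of ~120 h at 100 nM; monotone dose response over
0/10/50/100 nM with a transient dip of drugged mixtures; complete
relaxation of sorted high-P-gp sensitive cells within ten days (with a
clear shift already at 60 h); a near protocol-independent resistant
response; a conditioned-medium MV load of ~2.3 units after 24 h of
resistant culture; and the ten-fold transfer-amplitude contrast.  They
are the referent of the acceptance computation and are not adjusted by
tests.

### Interpreting the protocol comparison

Protocols 1–3 all deliver 120 h of drug over 240 h.  With these
kinetics, protocol 1 produces the ~120 h regrowth delay; protocol 3
(five 24 h pulses) yields the lowest time-averaged population; and
protocol 2 (60 h + 60 h with a 120 h rest) produces the largest
*cell-number change*, quantified here as the largest drawdown (swing
amplitude) of the treated growth curve: the mid-course rest lets the
culture regrow to a high count that the fully re-sensitized population
then loses to the final drug block.  Ranking protocols by final-count
deficit instead puts protocols 2 and 3 within a few percent of each
other, with 3 marginally ahead — the drawdown metric is the
implementation of "largest change" because it captures the swing the
growth curves display.

### Growth delay

The delay is the lag `τ` minimizing the mean squared log-mismatch
between the treated total `N(t)` and the control total `N(t − τ)`,
restricted to the post-nadir regrowth phase (after the treated total has
doubled from its nadir) and evaluated on the recording lattice (1 h by
default), so the reported value is resolution-limited.  A
time-to-threshold variant (`method="threshold"`) is provided; for a pure
lag both agree.  A treated culture that never regrows above its nadir
returns the horizon with a flag.

## Synthetic data

The generator emulates the *statistical* structure of the two readouts
the calibration consumes:

* **Event samples** — i.i.d. draws from the normalized mixture density
  with multinomial noise at the assay floor (2×10⁴ events), class labels
  drawn from the local class proportions, activities reported at grid
  cell centers.  Instrument spread beyond the biological width is folded
  into `s_basal` rather than added per event; there is no gating,
  compensation or doublet structure, and no FCS binary format (CSV
  stands in).
* **Growth curves** — a sensitive-only simulation from 4×10³ cells
  converted to an impedance proxy *proportional* to cell number
  (normalized to 1 at seeding), sampled every 0.5 h with multiplicative
  Gaussian noise (relative sd 0.02).  The true impedance–cell-number map
  of the instrument is unknown; the calibration only uses relative
  growth, so the proportional proxy is sufficient for its purpose and
  nothing downstream depends on absolute impedance units.

Passing recovery tests on these data therefore demonstrates
identifiability under the model's own noise assumptions — clean
multinomial/Gaussian noise — not robustness to instrument drift,
gating artefacts or model misspecification in real exports.

## Calibration

The fit minimizes 1-Wasserstein distances between observed event
samples and simulated mixture CDFs (an L2-on-histograms alternative is
selectable), plus mean squared relative residuals on growth curves,
with bounded Nelder–Mead (rates bounded by 10× the calibrated defaults,
`λ_rev ∈ (0.01, 1]`).  Identification is staged to limit
non-identifiability: proliferation from drug-free curves → therapy
(δ_max, C50) from the dose ladder → reversion (λ_rev) from the sorting
series → transfer amplitudes (κ0, κD) from the medium-exchange samples,
each stage inheriting the previous stage's values.  The
conditioned-medium MV load is resolved by nested simulation of a 24 h
resistant-only donor culture, not fitted.

## Statistics

Pairs of event samples are compared with the two-sample
Kolmogorov–Smirnov test (Anderson–Darling optional) and mapped to tiers
`***` (p < 0.0005), `**` (p < 0.005), `*` (p < 0.05), `ns`; families of
pairwise comparisons are Holm-corrected.  Note that with *equal* sample
sizes the two-sample KS statistic lives on a coarse lattice and its
null p-values are visibly discrete; the uniformity of null p-values is
therefore checked at slightly unequal sizes, while type-I error
calibration at α = 0.05 holds at equal sizes.

## Numerics

* Grid: 200 uniform cells on [0, 1] by default (minimum 8); densities
  are cell averages; quadrature weight `dx` per cell (exact for cell
  averages; composite trapezoid/Simpson on centers available).
* Advection: first-order conservative upwind (velocities are
  nonnegative by construction), optional second-order MUSCL/minmod
  reconstruction; zero-flux boundaries.  Reaction and MV updates:
  explicit Euler.  Steps obey `dt ≤ min(dt_max, cfl · dx/max|v|)` with
  `dt_max = 0.1 h`, `cfl = 0.9`, and land exactly on schedule switch and
  recording times.
* Positivity: upwind + CFL keep densities nonnegative; values below
  −1e-12 abort the run, smaller negatives are clipped.  `M` is clipped
  at 0.
* Self-convergence: doubling the grid and halving `dt` moves 96 h totals
  of a drugged mixture by ~0.1%.
* Degenerate inputs: zero horizons return the initial state; empty
  populations have zero crowding and flux; empty event samples are
  rejected.

Test-suite problem sizes: the calibration-loop tests run on a 100-cell
grid with `dt_max = 0.4 h` and 10 seeds per recovery check; full-grid
simulations are used everywhere the quantity of interest is a single
trajectory.  Numerical-consistency checks between coarse and fine
settings are part of the suite.

## Known limitations

* First-order upwind adds numerical diffusion of order `v·dx/2`, which
  widens distributions during strong advection episodes; calibration
  and its recovery tests use the same solver, so this is consistent
  within the package but is a bias relative to the exact PDE.
* The MV pool has no saturation; in long simulations of strongly skewed
  mixtures under drug, `M` can grow large and the CFL bound then forces
  small steps.  Enable `mv_clearance` for such regimes.
* The two-level `κ(C)` switch does not interpolate between doses; a
  continuous dose dependence of transfer would need data at more than
  two conditions.
* No nutrient depletion or confluence artefacts: comparisons against
  real growth assays should stay within the pre-confluent window
  (~96 h), as the underlying experiments did.
* Genotypic class switching, pharmacokinetic drug decay in the medium
  and spatial effects are out of scope by design.
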