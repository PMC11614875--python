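# Methods

`micromet` couples four submodels on nested clocks: substrate
reaction–diffusion (default dt = 0.01 min), off-lattice cell mechanics and
motility (0.1 min), stochastic phenotype/interaction rules (6 min), and a
delayed lymph-node ODE advanced with the phenotype clock. One seeded NumPy
generator drives every stochastic draw in a fixed order, so a
(configuration, seed) pair reproduces a trajectory bit-for-bit. Units are
micrometres and minutes throughout.

## Tissue patch and initial state

The default patch is a 700 µm square (35 × 35 voxels of 20 µm). Parenchymal
cells of radius R = 8.4 µm tile it as a confluent hexagonal monolayer —
1927 cells — and 5 cancer cells, 50 unpolarized macrophages and 10 inactive
DCs are dropped at uniform random non-overlapping positions, giving 1992
agents (≈ 2000, the population the classifier thresholds are 5% and 75%
of). A vascular mask flags round(0.088 · n_voxels) voxels, sampled without
replacement with round-half-even so the count is exact; recruited immune
cells enter at these voxels. Agents keep 3-D volume bookkeeping
(V = 4/3 π R³, voxel volume 20³ µm³) so secretion and engulfment stay
dimensionally consistent in the 2-D monolayer.

## Substrate fields

TNF and debris obey ∂ρ/∂t = D∇²ρ − λρ + sources with no-flux boundaries,
split into per-axis backward-Euler diffusion (unconditionally stable;
exactly mass-conserving because the discrete Neumann Laplacian has zero
column sums; positivity-preserving as an M-matrix solve), analytic decay
ρ ← ρ e^{−λdt}, then cell–voxel exchange. The two per-axis operators
commute on the tensor grid, so splitting preserves the lattice symmetry to
round-off. The constant tridiagonal systems are LU-factorized once and
reused. Defaults (config-overridable): D = 555.56 µm²/min for both fields,
λ_TNF = 1.02e−2/min, λ_debris = 1e−3/min; M1/hyperactivated macrophages
secrete 1 TNF unit/min; a corpse releases its at-death volume into the
debris field at a constant rate over τ_clear = 480 min. Samples return the
containing-voxel value and a central-difference gradient (one-sided at
boundaries).

## Mechanics

Overdamped center dynamics: repulsion ccr(1 − d/ΣR)² inside overlap,
adhesion −cca(1 − d/(1.25·ΣR))² inside reach, equal and opposite per pair
(ccr = 10, cca = 0.4 µm/min). Parenchymal cells carry an elasto-plastic
tether to a matrix attachment point; writing d⃗ = x⃗_ECM − x⃗ and
d̂ = ‖d⃗‖ − R, the cell moves at r_E·d̂ along d̂irection d⃗ and the
attachment point drifts toward the cell at r_P‖d⃗‖ (r_E = 0.05,
r_P = 5e−4 /min). The tether's stable manifold is the ring ‖d⃗‖ = R
(d̂ = 0): a cell attached exactly at its center is a degenerate
equilibrium, and slightly off-center cells relax outward to the ring, so
the initializer anchors each parenchymal cell at distance R in a random
direction — an equilibrium start with d̂ = 0. A parenchymal cell whose
deformation exceeds d_max = 1.5 µm dies *only if the largest-overlap
neighbor at that moment is a cancer cell* — the operational reading of
"deformation induced by a cancer cell"; crushing by other parenchymal
cells never kills. The simple pressure p = Σ(1 − d/ΣR)² over overlapping
neighbors gates the cancer cycle; with p_max = 1 a colony equilibrates
near 0.55–0.6 of touching spacing, which is why the patch's realized
carrying capacity exceeds touching-circle packing by roughly a factor of
three.

Neighbor search uses a KD-tree Verlet list with a 10 µm skin, rebuilt when
any cell's accumulated travel reaches 45% of the skin; the fused
force/tether/boundary substep is JIT-compiled (numba) with a vectorized
NumPy reference path kept and asserted equivalent in the tests. Cells
reflect at the patch boundary.

## Cell behaviors

Cancer cells cycle G0/G1 → S-G2-M (fixed 480 min) → division into two
half-volume daughters R_mother apart; r̄₀₁ = 7.2e−4/min ≈ one
division/day unstressed. Daughters regrow exponentially toward the target
volume with τ_grow = 240 min (≈ 95% recovered within one cycle) — without
volume recovery, lineages shrink geometrically, exert no pressure, and the
mechanical feedback that caps colony growth never engages. Parenchymal cells are homeostatic and never
divide. Dying cells shrink linearly over τ_clear while feeding the debris
field unless engulfed first (the macrophage absorbs the entire remaining
volume and enters a τ_digest = 15 min lockout). Every discrete interaction
fires with probability min(1, rate·Δt) per 6-min phenotype step; candidate
partners are tested in randomized order, one success per cell per step,
and the whole agent list is updated in an order re-randomized each step.
Contact means center distance ≤ R_i + R_j.

Macrophage states form the DAG M0 → M1 → {M2, hyperactivated, exhausted}
with M2 and exhausted absorbing. Exhaustion triggers at an ingested volume
of one resting cell volume (2483 µm³) and raises the death rate to
8.7e−4/min; since corpses shrink as they degrade, a typical meal is only a
fraction of that, so macrophages survive several engulfments. M1 and
hyperactivated macrophages secrete TNF; M0, M2 and exhausted do not.

DC activation targets are live-or-dying cancer cells and dying parenchymal
cells (the union of the two phrasings of the eligibility rule; healthy
parenchyma never activates). Activation is instantaneous antigen capture —
the DC is modeled as released immediately rather than held in a bound
state — after which it chemotaxes (TNF+debris) until its departure event
(rate r_leave) removes it to the lymph-node delay queue.

CD8 killing pools attachment time additively across all CD8s bound to one
cancer cell; the target dies when the pool reaches T_attach (60 min
default), so k pinned attackers kill in T_attach/k. Per step each attached
CD8 first accrues Δt of credit and the kill is checked, then a detachment
draw at rate 1/T_attach may release it, withdrawing its own contribution.
(Accrue-before-detach makes the limiting case T_attach = Δt a
single-step kill.) Motility follows the state table: resting phagocytes
follow debris only, activated ones follow TNF+debris at half speed
(s_mot = 1 µm/min baseline, b = 0.5, T_per = 5 min), T cells follow TNF
only, attached cells are immobile.

## Lymph node

Six pools (D_M, T_H1, T_H2, T_C, T_Ct, T_ht) with the delayed drive
k_D·D(t − τ_DC), where D is the tissue DC departure *rate* reconstructed
from an event queue — the reading that keeps arrivals finite and causal.
Integration is classical RK4 with the delay held piecewise-constant per
step and pools clipped at zero. The helper equations are polynomially
self-limited (a cubic deactivation term) and turn stiff when D_M is large;
a step that produces non-finite values, strong negativity or an explosive
jump is retried as two half-steps (adaptive halving preserves the smooth
regime's fourth order, verified by a Richardson test). Defaults put the
helper relaxation rate well inside the stable region at the 6-min clock;
the nonnegativity property is tested over the cohort's ×0.1–×10 envelope
of the cytotoxic/trafficking arm and a ×0.5–×2 envelope of the helper arm.

Dispatch is a pure counter: cumulative tissue arrivals track
T_Ct(t − τ_T) and T_ht(t − τ_T) with unbiased stochastic rounding, never
exceeding the delayed target by ≥ 1 cell; T_C is not drained by dispatch
(the governing equations have no efflux term). φ_C = 1 implies a small
antigen-free trickle (κ_T·φ_C ≈ 7 CD8 over 10 days at defaults), retained
as written. Helper pools start at 1 (they must, to escape the invariant
set T_H = 0), T_C at φ_C.

## Virtual patients, classification, sensitivity

The cohort varies ten parameters: r_recruit, ρ_min, ρ_sat for macrophages
and DCs, the lymph-node production parameters π_T, κ_T, δ_C, and r_leave.
Ranges default to ×0.1–×10 of each baseline on a linear scale. LHS uses
independent random permutations with uniform within-stratum jitter;
manifests assign seed = base_seed + job_index (mod 2³¹), which is
collision-free by construction. The therapy grid re-runs one patient on
the 3 × 3 {min, center, max} mesh of two chosen parameters (default the
two recruitment rates).

A run's label comes from the day-10 live cancer count against thresholds
at 5% and 75% of the patch's total population (100 and 1500 cells at
default scale); boundaries belong to MC. Trajectory compression rasterizes
each snapshot into a 5 × 5 RGB thumbnail — R/G/B = live cancer / immune /
parenchymal counts per bin divided by the hexagonal carrying count of the
bin area and clamped to [0, 1] — and concatenates the 31 snapshots of a
default run into 2325 dimensions. The channel convention and carrying
normalization are this package's explicit, reproducible choice. The
normalization is linear below saturation: scaling counts and carrying
density together leaves the vector unchanged. Sensitivity compares each
parameter between consistently-NC and consistently-SC patients with a
two-sided Mann–Whitney U test (exact for ≤ 12 untied observations,
tie-corrected normal otherwise) at α = 0.05, reported in ascending
p-value order.

## Reduced-scale presets and problem sizes

The three shipped presets (low/moderate/high immune response) share a
380 µm patch — 550 parenchymal cells plus seeds, ≈ 560 agents — run ten
simulated days with coarsened mechanics/diffusion substeps of 1 min (the
implicit field solver is unconditionally stable, and at these decay and
speed scales trajectories are insensitive to refinement; the phenotype
clock stays at 6 min). They differ only in immune strength: the low preset
has a handful of resting phagocytes and no recruitment, so the colony
escapes toward the patch's compressed carrying capacity; the moderate
preset has weak phagocytes and a slow, small lymph-node output whose
delayed CD8 wave prunes but does not clear the colony; the high preset
combines strong phagocytosis, recruitment and a fast lymph-node loop and
eliminates the tumor before day 10. Outcome labels at this scale use the
same 5%/75% rule applied to the preset's own initial population.

The test suite sizes the stochastic checks to keep the full run within a
desktop budget: rate calibrations at 10⁵ trials, recruitment expectations
at 10⁴ draws, lymph-node property sweeps at 100 parameter draws × 10-day
integrations (dt = 30 min), presets at 5 replicates each, and the
Mann–Whitney oracle comparison at 200 random small-sample cases.

## What the synthetic data does and does not show

All inputs are generated internally; there is no patient data. The
generator emulates the *structure* of the biology — confluent epithelium,
stochastic immune encounters, delayed adaptive feedback — with rate
constants chosen for plausible magnitudes (divisions/day, minutes-scale
persistence, hours-scale trafficking), not fitted to measurements. Passing
tests therefore demonstrate internal correctness (equations solved as
stated, invariants held, regimes reproducible), not quantitative fidelity
to any tissue. Known limitations: 2-D monolayer mechanics; two substrates;
a single shared antigen; no NK cells, Tregs, fibroblasts or
anti-inflammatory cytokine field; no tissue healing (escape and
elimination are reproduced, immunoediting's equilibrium phase is not);
classifier thresholds are population fractions, not biologically derived;
and the helper-arm ODE is trusted only inside its non-stiff envelope.
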