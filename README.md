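# micromet

A multiscale agent-based simulator of immune surveillance of epithelial
micrometastases, with a virtual-patient cohort engine, an outcome
classifier and nonparametric parameter-sensitivity analysis.

Micrometastases — clinically undetectable clusters of disseminated cancer
cells seeding a distant tissue — are either eliminated, contained or missed
by the host immune system. `micromet` simulates that contest in a small
patch of epithelial tissue and asks the population-level question: across a
cohort of *virtual patients* (parameter sets), which immune parameters
decide between tumor **escape**, **partial elimination** and **complete
elimination**, and how reproducible is any individual patient's outcome
under the stochasticity of immune–cancer encounters?

It is written for computational-biology researchers studying tumor–immune
dynamics, virtual-patient ensembles and cancer patient digital twins.

## The model

Off-lattice circular agents (cancer, parenchymal, macrophage, dendritic
cell, CD8+ and CD4+ T cells) live on a 2-D tissue patch with two diffusible
substrates (TNF and cellular debris) on a voxel grid, coupled to a delayed
ODE model of the draining lymph node.

* **Tissue mechanics.** Overdamped adhesion–repulsion between cell centers;
  parenchymal cells carry an elasto-plastic matrix tether: with
  d⃗ = x⃗_ECM − x⃗ and d̂ = ‖d⃗‖ − R,

      dx⃗/dt = r_E · d̂ · d⃗/‖d⃗‖ ,      dx⃗_ECM/dt = −r_P · d⃗ .

  A parenchymal cell crushed by a cancer cell beyond d_max dies, freeing
  space. The dimensionless *simple pressure* p = Σ (1 − d/(R_i+R_j))²
  gates the cancer cycle: Prob(G0/G1 → S) = r̄₀₁ · max{0, (p_max−p)/p_max} · Δt.
* **Chemotaxis.** Immune cells follow a biased random walk,
  v⃗ = s_mot ((1−b)ξ⃗ + b·b⃗)/‖·‖ with b⃗ ∝ σ_TNF ∇ρ_TNF + σ_debris ∇ρ_debris
  and Poisson re-orientation at rate 1/T_per.
* **Recruitment.** Macrophages and DCs enter through vascular voxels
  (8.8% of the patch) at rate
  r_recruit ∫_Ω min(1, max(0, (ρ_TNF−ρ_min)/(ρ_sat−ρ_min))) dV.
* **Innate response.** Macrophages engulf dead cells (rate r_phag),
  polarize M0 → M1 (TNF on), can be hyperactivated by CD4 contact (then
  also engulf live cancer cells), convert to anti-inflammatory M2 on CD8
  contact (TNF off, permanent), and exhaust after ingesting a volume
  threshold.
* **Adaptive loop.** Activated DCs leave for the lymph node (rate r_leave,
  delay τ_DC), drive helper/cytotoxic T-cell pools (six delayed ODEs), and
  dispatched CD8/CD4 cells re-enter the tissue after τ_T. CD8s attach to
  cancer cells (rate r_attach); pooled attachment time across all attached
  CD8s kills the target at T_attach.
* **Outcomes.** A run is labeled from the day-10 live cancer count P_M:
  SC (P_M < T_SC), NC (P_M > T_NC), MC otherwise; defaults T_SC = 100,
  T_NC = 1500 (5% / 75% of the ~2000-cell patch).

The cohort engine draws the ten immune parameters by Latin hypercube
sampling, runs replicated simulations, compresses each trajectory to a
31 × 5 × 5 × 3 = 2325-dimensional feature vector, and ranks parameters by
two-sided Mann–Whitney U tests between the consistently-NC and
consistently-SC patients.

## Worked example

`python examples/lymph_node_response.py` — a pulse of 30 dendritic cells
leaves the tissue during day 1; the lymph node expands and ships T cells
back after the trafficking delay:

```
 day      D_M      T_C     T_Ct  cd8 sent  cd4 sent
   1     9.53    38.25     7.32         1         1
   2     0.82    72.73    54.98        28         3
   3     0.05    49.43   100.03        80         6
  10     0.00     1.33   155.35       155         7
```

D_M peaks once the delayed arrivals land and decays at δ_DM; the cytotoxic
pool T_C overshoots and relaxes to its baseline φ_C = 1 after the antigen
pulse; 155 CD8 and 7 CD4 cells are dispatched in total — the integerized,
delayed image of the cumulative counters T_Ct and T_ht.

`python examples/cohort_manifest.py` — a 10,000-patient LHS cohort:

```
r_recruit_M : 10000 of 10000 strata occupied
cohort manifest: 100000 jobs (10000 patients x 10 replicates), 100000 distinct seeds
therapy grid for patient 0: 90 jobs over the 3x3 (r_recruit_M x r_recruit_D) mesh
```

Every parameter's marginal hits each of the 10,000 strata exactly once
(the Latin hypercube property); the 3×3 mesh is the hypothetical
personalized immunotherapy: the patient re-simulated at the
{min, center, max} combinations of the two recruitment rates.

`python examples/outcome_presets.py` — the three immune-response regimes
on the reduced 380 µm patch (ten simulated days each, a few minutes
total):

```
low       immune response: P_M =  872 of 558 initial cells -> NC   (peak CD8 10, parenchymal loss 404)
moderate  immune response: P_M =  337 of 573 initial cells -> MC   (peak CD8 27, parenchymal loss 381)
high      immune response: P_M =    0 of 576 initial cells -> SC   (peak CD8 220, parenchymal loss 62)
```

Unopposed (low), the colony escapes toward the patch's mechanical carrying
capacity and destroys most of the healthy tissue; the moderate response
arrives late and prunes the colony without clearing it; the high response
eliminates it before day 10 with the tissue largely intact.

Other examples: `single_run.py` (a small patch end to end) and
`sensitivity_ranking.py` (Mann–Whitney parameter ranking on a
synthetically labeled cohort).

There is also a thin CLI: `micromet simulate|cohort|therapy-grid|classify|sensitivity --help`.

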