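# Methods

## The circuits

`notchcrypt` models juxtacrine Notch–Delta signaling between adjacent
cells.  Each cell carries NOTCH receptor `N`, DLL ligand `D`, and cleaved
NICD `R` (plus the two mRNAs in the five-species form).  Three regulatory
arms combine:

* **Trans-activation (TA).**  Receptor on cell *i* is activated by the mean
  ligand presented by its neighbors, a bilinear flux `s_i = N_i <D_j>` that
  consumes receptor on the receiver and ligand on the senders and sources
  the readout `R_i` (`dR_i/dτ = s_i − α_R R_i`).
* **Lateral inhibition (LI).**  Signaling represses the cell's own ligand
  transcription through the decreasing Hill function
  `δ(s, k_d, h) = k_d^h/(k_d^h + s^h)`.
* **Positive feedback (PF).**  Signaling activates the cell's own receptor
  transcription through `σ(s, k_p, p) = s^p/(k_p^p + s^p)`.  "PFLI" is LI
  plus this feedback; pure LI is the limit `S_PF = 0`.

The production terms are written as convex mixtures
`β · [(1 − S) + S · regulation]`, so `S_PF, S_LI ∈ [0, 1]` dial the fraction
of production under feedback control at a fixed maximum rate.  All analyses
run on the dimensionless protein-only form (`MODEL3`); the five-species
form (`MODEL2`) is retained for the quasi-steady-state consistency checks,
and the dimensional form is represented only through the rescaling in
`ScalingConstants`.  In the reduced form the NOTCH decay is the *protein*
decay rate of the five-species model (`qssa_reduce` maps `alpha_N` onto the
reduced model's `alpha_n` slot); the reduction multiplies the production
rates by `β_nm/α_n` and `β_dm/α_d`.

## Default parameters

No canonical numeric values exist for this circuit family, so the shipped
defaults are fixtures of this package, chosen once so that the qualitative
regimes of the two circuits are all present (all rates dimensionless; time
in units of the reference timescale):

| parameter | value | meaning |
|---|---|---|
| `beta_N` | 4 | max NOTCH production |
| `beta_D` | 12 | max DLL production |
| `alpha_n, alpha_D, alpha_R` | 1 | decay rates |
| `k_p` | 1.25 | PF half-saturation (signal units) |
| `k_d` | 0.5 | LI half-saturation |
| `p` | 2 | PF cooperativity |
| `h` | 3 | LI cooperativity (default) |
| `S_PF` | 0.95 (PFLI) / 0 (LI) | feedback strength |
| `S_LI` | 1 | full ligand repression |

With these rates: LI is pair-bistable at `h = 2` but not `h = 1`; PFLI is
pair-bistable already at `h = 1, p = 2`; the PFLI single cell shows a
bounded hysteresis window in external ligand (`D_ext ∈ [1.5, 2.8]`) while
the LI response is monostable and monotone.  The default `h = 3` is the
smallest integer at which *pure LI* destabilizes the homogeneous state on a
6-neighbor (triangular-packed, "hexagonal cell") lattice: lateral
inhibition on that lattice is intrinsically harder than on a pair because
the most negative eigenvalue of the neighbor-averaging matrix is −1/2
rather than −1, so a pair-bistable circuit at `h = 2` can still fail to
pattern a sheet.

## Steady states and bifurcation analysis

In the single-cell protocol (`<D_j> = D_ext`, `<N_j> = 0`) the NOTCH
equation decouples, so *all* fixed points are found exactly by dense
sign-change bracketing of a scalar self-consistency function followed by
Brent refinement; ligand and NICD follow algebraically.  Fold points are
reported at the midpoints of grid cells where the root count changes.

Pair-cell fixed points use deterministic multistart root finding
(unscrambled Sobol' design over `[0, 2β/α]` per species) augmented with
warm starts obtained by *integrating* from symmetric and strongly
asymmetric initial conditions — integration lands in every attracting
basin, so no stable state can be missed — and completed under the
cell-exchange symmetry.  Roots are deduplicated at 1e-6 relative distance.
Stability is classified from the analytic Jacobian spectrum; eigenvalues
within ±1e-9 of the imaginary axis are conservatively classified unstable
and flagged marginal.

## Patterning competence (MLE)

Patterning onset is the linear instability of a spatially uniform steady
state: the maximum Lyapunov exponent is the largest real part of the
multicell Jacobian spectrum at that state.  Uniform states are enumerated
exhaustively (the uniform ligand balance has a unique solution `D(N)`,
reducing the uniform-state condition to one scalar equation in `N`).  When
the uniform dynamics are multistable the state with the largest MLE is
used: patterning competence means *some* homogeneous steady state is
laterally unstable, and the deterministic patterning protocol perturbs
exactly that state.  At a uniform state the Jacobian decomposes over
eigenvalues `μ` of the row-normalized adjacency into 3×3 blocks `A + μB`
("modes" method, used for sweeps); the dense full-lattice eigensolve is
retained and tested to agree to 1e-8.

The production-rate sweep reports the patterned-area fraction over
`beta_N ∈ [4, 23]`, `beta_D ∈ [1, 20]` (20×20), bracketing the default
operating point: receptor production below the default rate cannot sustain
signaling in a circuit whose transcription is predominantly
feedback-driven, so the sweep starts at the default Notch rate and spans
weak-to-strong ligand presentation.  The sweep's cooperativity label `H`
varies the LI Hill coefficient `h` only; the PF cooperativity `p` is a
distinct knob of the circuit and stays at its default.

## Deterministic patterning runs

Runs start from the homogeneous state with multiplicative i.i.d. uniform
noise (`ε = 0.01`, single integer seed) and integrate with a stiff BDF
solver (rtol 1e-8, atol 1e-10, analytic Jacobian) — bistable dynamics near
saddles need tight tolerances for reproducible basin assignment.  Species
undershooting zero by less than 10·atol are clamped; worse negativity is an
error.  `pattern_time` is the time at which the maximum over cells of
|dD/dτ| last falls below 1e-4 (configurable); it is quantized at the
trajectory sampling step (0.25 at the default 801 samples over τ ∈ [0, 200]).
Final cells are split into NICD-high/low classes by a deterministic 1-D
2-means.  `match_notch_levels` rescales LI's `beta_N` by bisection so the
NICD of the Notch-high cell in the pair's patterned state matches PFLI's
within 2% (scale ≈ 0.87 at the defaults).

## The cellular-Potts crypt model

The stochastic tissue model is a 2-D GGH lattice representing the unrolled
crypt base: an immobile SUPPORT stripe (basement membrane, 4 rows) under a
monolayer of ~60 epithelial cells (5×5 px each, 300×40 lattice, periodic
columns), MEDIUM above.  This is a deliberate 2-D simplification of the
3-D crypt: the claim under test — pattern robustness against proliferation
— does not depend on the finger geometry.  Per Monte-Carlo step (MCS):

1. **Mechanics** — one sweep of random pixel-copy attempts with Boltzmann
   acceptance `min(1, exp(−ΔE/T))`, `T = 6`;
   `E = Σ J(type, type') · [heterologous boundary] + λ Σ (v − v_target)²`
   with `λ = 2`; cell–support contact is cheapest (J = 3), cell–cell
   moderate (6), cell–medium expensive (16).  Support pixels never flip.
2. **Signaling** — every niche cell's (N, D, R) advances by `ode_dt = 0.01`
   (fixed-step RK4, 4 substeps) with neighbor means weighted by shared
   contact length (juxtacrine flux is contact-proportional); a cell without
   epithelial contact sees zero ligand.
3. **Fate and growth** — NICD ≥ threshold ⇒ Notch-high stem cell (boundary
   inclusive); stem cells' target volume grows by
   `growth_rate × turnover_multiplier` (0.09 × multiplier px/MCS);
   Notch-low Paneth-like cells neither grow nor divide but keep signaling
   and may revert.  The threshold is the midpoint of the pair-cell high/low
   NICD levels, recomputed from the active circuit.
4. **Division** — a stem cell at twice its reference volume splits along a
   random axis through its centroid; daughters inherit the mother's
   signaling state.
5. **Removal** — a cell displaced above the monolayer band exits the niche
   (upward migration); a cell that loses all support contact in place dies
   by anoikis.  Both are logged, and the cell-count ledger
   `ΔN = divisions − anoikis − exits` is exact.

A master seed spawns independent streams for Potts flips, initial noise,
and division axes; identical seeds give byte-identical outputs.

The crypt experiments run the circuits at `h = 2` — the low-cooperativity
regime where pure LI is marginally patterning-competent on the contact
graph and the feedback's contribution is decisive, which is exactly the
regime the robustness comparison probes; both circuits are pair-bistable
there and both form stable mosaics in a slowly proliferating niche.  A run
is 1500 MCS ≈ 15 dimensionless signaling time units, a few patterning
timescales; at `turnover_multiplier = 4` a stem cell divides roughly every
150 MCS, so pattern repair and mechanical disruption compete.

Readouts: Sarle's bimodality coefficient (with small-sample correction) of
the NICD samples pooled over the trailing third of the run — pooling
captures cells in transit between modes, the "blur" of a disrupted
pattern — and the checkerboard score (fraction of contact-graph edges whose
endpoints differ in high/low class) of the final snapshot.

**Feedback suppression.**  Two protocols are implemented.  The default
`rescale` swaps regulated for basal production at a fixed maximum rate, so
`S_PF = 0` is exactly the pure-LI circuit.  Because the production factor
`(1 − S) + S·σ` *rises* as `S` falls (σ < 1 at any operating point),
rescaled suppression cannot lower NICD levels; the genetic perturbation the
model mirrors (mutation of the feedback enhancer) instead removes the
regulated transcription while keeping basal, implemented as `knockdown`
(the sweep value is the retained fraction of regulated production).  Under
knockdown the stem fraction and the NICD level of the high mode fall
monotonically as the feedback is lost.

## What the generator does and does not emulate

The synthetic tissue reproduces: contact-mediated signaling with
area-weighted neighbor averaging, proliferation-driven cell rearrangement,
loss and replacement of niche cells, and inheritance of signaling state at
division.  It does not include: 3-D crypt geometry, Wnt/EGF gradients or
any second pathway, directed migration, cell-cycle structure (growth is
linear in target volume), cis-inhibition, or transcriptional noise (the
ODEs are deterministic; stochasticity enters only through mechanics and
initial conditions).  Passing tests therefore demonstrate properties of
the circuit logic under mechanical churn, not quantitative predictions for
real crypts.

## Numerical choices and degenerate cases

* Stiff BDF with analytic Jacobian everywhere in the deterministic layer;
  fixed-step RK4 (local error ≪ the Potts noise floor) inside the tissue
  loop, where adaptive stepping per cell per MCS would dominate runtime.
* Hill functions evaluate as `t/(1+t)` with `t = (x/k)^n` and explicit
  overflow handling, so saturating inputs return exactly 1 (or 0).
* Zero-variance NICD samples make the bimodality coefficient undefined
  (NaN), never an exception, so sweeps survive degenerate runs.
* A cell's last pixel is never removed by a fluctuation (volume-1 flips are
  rejected); cells disappear only through the logged removal channels.
* `two_means_split` on constant input labels everything "low" with the
  boundary at the common value.

## Known limitations

* The checkerboard label score structurally favors pure LI at strong PF:
  the feedback tolerates high-high-low neighbor motifs that strict lateral
  inhibition forbids, so PFLI's *spatial alternation* score can sit
  slightly below LI's even while its *bimodality* (level separation) is
  clearly more robust to turnover.  The robustness contrast lives in the
  level statistics.
* Quantities derived from medians over seeded runs (pattern times, crypt
  summary statistics) carry sampling noise of a few percent at the default
  seed counts.
* The 1-row monolayer makes the niche contact graph chain-like; mosaic
  geometry on a true 2-D crypt base is richer.
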