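# Methods

This note documents the models behind `dyndesign`, the constants they use,
and the design choices made where several defensible options existed.

## The canonical kinetic landscapes

Each variant (WT, D66A, H70A) is a continuous-time Markov jump process on
five macrostates labelled by the conformation of the two loops:
`o100_c70` (100s open / 70s closed), `c100_c70`, `intermediate`,
`o100_o70`, `c100_o70`. Stationary populations are model constants:

| state | WT | D66A | H70A |
|---|---|---|---|
| o100_c70 | 0.41 | 0.15 | 0.41 |
| c100_c70 | 0.29 | 0.10 | 0.29 |
| intermediate | 0.05 | 0.40 | 0.05 |
| o100_o70 | 0.13 | 0.18 | 0.13 |
| c100_o70 | 0.12 | 0.17 | 0.12 |

Only some of these are published quantities (the 41% ground state, the ~5%
and ~40% intermediate, the ~15% former ground state, and the 70:30 / 25:75
closed:open aggregates); the remaining individual values are conventions
chosen once to satisfy the printed aggregates, and are asserted as model
constants, not as claims about the real protein.

**Rates.** Off-diagonal rates are k_ij = c_ij·π_j with symmetric c_ij, which
guarantees detailed balance for any positive c. Adjacency is restricted to
100s-loop flips within each 70s group and to transitions through the
intermediate (no direct closed↔open 70s jump). Two symmetric coefficients
(one for 100s edges, one for intermediate edges) are calibrated
deterministically by root finding:

* the mean 70s-loop group-interconversion MFPT is 5 ms for WT/H70A and
  5/12 ms for D66A (millisecond regime; exactly the 12-fold speed-up,
  inside the published 10–15-fold band);
* the WT-structure 70s/100s MFPT ratio is set to **11**. The published
  statement is "one order of magnitude", and downstream checks bound the
  *estimated* ratio from below at 10, so the truth is placed inside the
  [8, 12] band with headroom on both sides rather than exactly on the
  boundary of its own acceptance test.

MFPT here means the stationary-flux-weighted hitting time of the target
group, computed by linear solve on the generator (ground truth) or on the
transition matrix (estimates).

**Sampling interval.** Trajectories are strided at 2 µs per frame. This is a
synthetic-data choice, not an MD frame rate: it makes the canonical
100 × 20,000-step experiment cover ~4 s of aggregate time, i.e. several
hundred slow 70s-loop transitions, which is the regime in which macrostate
populations are recoverable to a percentage point — the same role the
paper-scale cumulative MD sampling plays. The chain is exactly Markovian at
every stride, so MSMs are estimated at lag 1 by default.

**Microstate expansion.** Each macrostate is split into n equal
sub-populations; intra-macrostate exchange is a complete graph relaxing at
100× the fastest inter-macrostate rate (configurable, ≥ 50× enforced), which
leaves the four slow eigenvalues of the expanded chain within 1% of the
macro-level ones (checked at construction, 5% tolerance). Microstate feature
means jitter the macrostate mean by a fixed deterministic offset so the
expansion is identifiable in feature space.

**Emissions.** Features are 2-D Gaussians in ("70s openness", "100s
openness") with σ = 0.12 — sufficient for clustering tests, with no pretence
of Cartesian coordinates. H-bond indicators are independent Bernoulli draws
per frame with macrostate-conditioned probabilities; the planted pattern
gives D66 three strong closed-state-only bonds (designable) and H70
state-independent bonds (the negative control). Per-state ¹⁵N shifts differ
between 70s-closed and 70s-open states by 0.5–3.5 ppm for loop residues
(¹H by 1/12 of that), zero elsewhere; the intermediate sits halfway.

## MSM estimation

Transition counting is sliding-window by default (strided available);
trajectories are never concatenated. Estimation is restricted to the largest
strongly connected set (largest by size, then count mass). The reversible
MLE uses the standard self-consistent fixed-point update on the symmetric
flux x_ij ← (c_ij + c_ji)/(c_i/x_i + c_j/x_j), converged at max|Δπ| < 1e-10
(max 10⁵ iterations); every iterate satisfies detailed balance exactly by
construction. Lumping uses PCCA+-style memberships: vertices of the simplex
spanned by the dominant eigenvectors are found by orthogonal farthest-point
search, memberships are the (clipped, renormalised) barycentric coordinates,
and crisp assignments take the argmax with ties to the lowest macrostate
index. Eigenvalue degeneracy at the spectral cut (gap < 1e-10) is an error
suggesting a different macrostate count.

Bootstrap intervals resample whole trajectories with replacement (the
trajectory is the exchangeable unit), re-estimate and re-lump each
replicate, and align replicate macrostates to the full-data ones by maximal
stationary-weight overlap (Hungarian assignment); percentile intervals at
95% by default, 200 replicates by default (50–100 in the packaged
experiments, where the interval widths are already stable). Replicates that
lose connectivity are dropped and counted; > 50% drops is an error. With
~25 resampling units the percentile intervals run somewhat below nominal
coverage (~70% observed at the 80% level in the test suite), which is the
known small-n behaviour of the trajectory bootstrap, not a defect of the
estimator.

Validation reports implied timescales t_k(τ) = −τ/ln λ_k(τ) across lags and
Chapman–Kolmogorov deviations max|[T(τ)]^k − T(kτ)| coarse-grained onto the
macrostate sets, k ≤ 5.

## Designability scoring

Hydrogen bonds use a geometric criterion (unpublished in the source
analysis, so a documented convention here): donor–acceptor distance
≤ 3.5 Å and D–H···A angle ≥ 120°, both inclusive; donors are N/O with an
attached hydrogen (inferred geometrically and flagged when the structure has
none), acceptors are N/O in a different residue. The partner set for
per-residue profiles defaults to the 70s loop (residues 65–77). Group
definitions: closed = {o100_c70, c100_c70}; open = {intermediate, o100_o70,
c100_o70}. Scores are population-weighted mean H-bond counts per group;
residues are ranked by |Δ| = |mean_closed − mean_open|. RMSF/RMSD are
computed on Cα after least-squares superposition.

## NMR forward model

Fast exchange within each 70s group is assumed, so within-group shifts are
population-weighted averages; between-group exchange is handled by the
two-state mapping: pA/pB from aggregated populations, kex = 1/MFPT(A→B) +
1/MFPT(B→A), Δω per residue from the difference of group-averaged ¹⁵N
shifts. CSP = √(ΔδH² + (0.14·ΔδN)²) (common convention). Constants:
γH/γN = −9.862, ¹⁵N Larmor = 0.1013 × ¹H field, N–H 1.02 Å, ¹⁵N CSA
−160 ppm. The heteronuclear NOE uses Lipari–Szabo spectral densities
J(ω) = (2/5)[S²τc/(1+(ωτc)²) + (1−S²)τ/(1+(ωτ)²)] with the signed (negative)
¹⁵N gyromagnetic ratio. No temperature scaling is applied anywhere (the
mismatch between simulated and measured temperatures in the source problem
is acknowledged, not modelled).

With millisecond MSM kinetics (kex ≈ 1000 s⁻¹ from the mapping) and planted
loop Δω of 2–3.5 ppm, the forward-predicted Rex for 70s-loop residues is in
the hundreds of s⁻¹ — an order of magnitude above measured exchange
contributions, reproducing the known over-prediction when MSM rate constants
are combined naively with computed shift differences.

## Relaxation dispersion

**CPMG.** The closed form is Carver–Richards (equal intrinsic R2). The
numerical model builds one echo cycle δ–180–2δ–2×180…–δ (δ = 1/(4νCPMG)) of
the 2×2 complex Bloch–McConnell propagator and extracts R2eff from the decay
per cycle of the dominant eigenmode — the long-relaxation-delay limit of
−(1/T)ln(I/I₀), independent of the arbitrary delay and of minor-mode
amplitude factors. Under these definitions the two agree to numerical
precision; a finite-delay intensity definition would differ by up to
~1.6 s⁻¹ in slow exchange, which is an amplitude effect, not a rate effect.
Closed-form overflow falls back to the numerical route with a warning.

**R1ρ.** The analytic form is the Miloushev–Palmer (Laguerre, second-order)
expression with the tilt angle from the population-averaged offset; the
numerical oracle propagates the full 6×6 two-state matrix and measures the
two-delay decay of magnetisation locked along the average effective field.
Agreement is ≤ 5% in the fast/intermediate regime (kex ≥ Δω), ~0.2% over the
canonical grids.

**Canonical datasets.** WT: pB = 2.0%, kex = 2200 s⁻¹; D66A: pB = 0.5%,
kex = 2000 s⁻¹ — the published global-fit values. Ten 70s-loop residues
carry the planted Δω pattern (0.5–3.5 ppm); fields 600 and 800 MHz; 15
νCPMG points (25–1000 Hz, multiples of 25 so echo trains close); four
on-resonance spin locks (1–3 kHz); R2,0 ≈ 11–15 s⁻¹ with a mild field
dependence; R1 = 1.2 s⁻¹; Gaussian noise σ = 0.3 s⁻¹ per point (a typical
experimental uncertainty for well-measured R2eff). Noiseless simulations
record unit errors so weights stay defined.

**Global fit.** Parameters: shared kex ∈ [1, 10⁶] s⁻¹ and pB ∈ (10⁻⁴, 0.499)
(minor-state convention removes the relabelling degeneracy); per-residue
|Δω| in ppm (sign not identifiable from dispersion alone, magnitude
reported; converted per field via the ¹⁵N Larmor fraction); per-(residue,
field) R2,0. R1 is treated as independently measured and fixed (1.2 s⁻¹ by
default); on-resonance it enters only through cos²θ ≈ 10⁻⁵ and is not
identifiable. Initialisation: R2,0 from the minimum observed rate per curve;
|Δω| by inverting the fast-exchange Rex estimate at the start's (kex, pB).
Multi-start over kex ∈ log-grid 100–30,000 s⁻¹ × pB ∈ {0.5, 1, 2, 5, 10}%:
all 35 starts are scored by their initial χ², the best three are refined by
Levenberg–Marquardt, and the lowest final χ² wins, ties to the lowest kex —
fully deterministic. Uncertainties come from residual-resampling bootstrap
(percentile intervals); in degenerate regimes (fast exchange, single field)
the pB interval widens by an order of magnitude rather than reporting false
precision. Model comparison against the exchange-free (flat per-curve)
model uses an F-test on the χ² reduction at α = 0.01, with AIC reported
alongside.

## Problem sizes and what the tests show

The packaged experiments use 100 trajectories × 20,000 steps (2×10⁶ frames,
~4 s aggregate) for landscape recovery, 50–100 bootstrap replicates, and 20
seeded regenerations per dispersion ground truth; these sizes put every
recovered quantity comfortably inside its published uncertainty band while
keeping a full run to minutes on one CPU.

The generator emulates the *statistical* structure of the study's data —
state populations, timescale separations, emission asymmetries, measurement
noise — not its physics. Features are Gaussian, H-bonds are conditionally
independent Bernoulli draws, the discrete chain is exactly Markovian, and
chemical shifts are planted rather than predicted from structure. Passing
tests therefore demonstrate that the estimators recover what was planted at
realistic sizes and noise levels (and that the forward models agree with
independent oracles); they do not validate force fields, clustering of real
MD coordinates, or shift prediction. Known limitations: no three-state
dispersion models, no off-resonance CPMG, no TICA/TRAM estimators, and the
adaptive MD seeding loop of the original protocol is documented but not
automated (it requires an MD engine).
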