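# Methods

This note documents the models implemented in `crmalign`, the numerical and
design choices behind them, what the simulator does and does not emulate,
and the known limitations. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Substitution models

**Background.** General time-reversible (GTR) rate matrices over
`{A,C,G,T}`, built from six exchangeabilities and an equilibrium
distribution and normalised to one expected substitution per unit branch
length, so Newick branch lengths are on the substitutions-per-site scale and
the branch coefficient `c_branch` is interpretable as a rate multiplier.
Finite-time matrices are `expm(tQ)`; reversible matrices are diagonalised
via the `diag(π)^{1/2}` symmetrisation, which keeps the decomposition real
and well conditioned, and the decomposition is cached per matrix.

**Foreground.** Each PWM column defines a functional class whose rate
matrix is the Halpern–Bruno construction: the background rate `q_ij` scaled
by the fixation factor `x ln x / (x−1)` with
`x = (π_j q_ji)/(π_i q_ij)` for the column's probabilities π. The result is
reversible with stationary distribution exactly the PWM column, and is *not*
re-normalised: selection slows the site, which is the conservation signal
the aligner exploits. PWMs are read from JASPAR-style count matrices with a
pseudocount of 0.1 added to every cell; the minus strand uses the
reverse-complemented profile (reversed column order, complemented bases), so
decoding remains single-pass.

**Cross-functional mixture.** When a residue's class changes along a branch
(gain or loss of function), the change time is uniform on `[0, t]` and the
substitution matrix is `(1/t)∫₀ᵗ P_B(s) P_b(t−s) ds`, evaluated in closed
form as `M₁ (K ∘ Φ(t)) M₂⁻¹` with `K = M₁⁻¹M₂` and
`Φ_ij = (e^{d₁ᵢt} − e^{d₂ⱼt}) / (t (d₁ᵢ − d₂ⱼ))`. Near-degenerate
eigenvalue pairs (|difference| < 1e−9) use the analytic limit `e^{dt}` to
avoid cancellation; defective matrices fall back to adaptive quadrature at
relative tolerance 1e−8. The closed form is tested against a 1e5-panel
trapezoid quadrature of the defining integral (agreement < 1e−6).

## Site turnover

Candidate intervals are a two-state birth–death process (vacant ↔
occupied) with birth rate λ and death rate µ, giving closed forms

    p(t) = (λ + µ e^{−(λ+µ)t}) / (λ+µ)      retention
    q(t) = 1 − p(t)                          loss
    b(t) = b∞ (1 − e^{−(λ+µ)t}),  b∞ = λ/(λ+µ)   gain

verified against Runge–Kutta integration of the defining ODE system. The
detailed-balance identity `(1−b∞) b(t) = b∞ q(t)` holds for all t: at
stationarity gains and losses balance, which is what keeps the assembled
model reversible. The density constraint `λ = δµ/(1−δ)` makes `b∞ = δ`
exactly. Defaults: µ = 0.08 (a value at which hill-climbing showed little
sensitivity in the original Drosophila protocol), δ estimated from training
annotations.

## Model assembly and calibration

The CRM template wires a reversible affine background indel model (match /
insert / delete; gap-open probability `1 − e^{−αt}`, extension β, no
insert↔delete adjacency) to per-factor, per-strand retention, gain and loss
submodels. Retention chains are gapless; gain chains pair cross-functional
match states (bg → Wᵢ) with delete states (extra ancestral background
residues) and insert states (site residues without an ancestral partner);
loss chains are the exact mirror. Submodel transition structure is derived
from the background indel parameters restricted to the chain topology and
renormalised per state.

Two calibration points matter and are easy to get wrong:

* **Interval-to-column conversion.** Birth–death probabilities are per
  candidate *interval* (one per site length L), while transition closures
  fire per *column*. Entry weights are therefore scaled by
  `κ/b∞` with `κ = δ/(L̄(1−δ) + δ)` (L̄ the frequency-weighted mean profile
  length), which makes the model's stationary fraction of residues inside
  sites equal δ exactly. Without this factor the implied density is ~L̄×
  too high and the site prior is inflated accordingly.
* **Whole-site weights in per-column recursions.** The clade likelihood
  recursions run per column, but turnover is a whole-site event. Each
  column of an L-column class therefore carries the L-th root of the
  site-level retention/loss probability, so a class history that keeps (or
  drops) an entire site across a branch is charged exactly p(t) (or q(t))
  once per branch. Charging the full p(t) per column instead makes the
  model prefer "lost" for every site once per-branch loss approaches 1/L
  (the decoder visibly collapses at high turnover); the L-th-root weights
  remove that failure mode. The per-column factorisation still permits
  column-inconsistent histories at intermediate weight — an approximation
  we accept for tractability.

Entry weights from the background are `freq_f · 0.5 · w_event · κ/b∞` with
`w_gain = (1−b∞)b(t)`, `w_loss = b∞ q(t)`, `w_retention = b∞ p(t)`; the
0.5 halves each factor's mass between strands, and the three event weights
sum to the background-exit probability `s(t)`. The small constant
ε = 0.00001 is the stop/termination probability. A *complete-orthology*
variant (used as a baseline) drops the gain and loss submodels and enters
retention with the stationary weight `b∞ · κ/b∞ = κ`.

## Emission recursions

Every clade profile column stores, per functional class, a conditional
likelihood vector (linear values with a per-column log scale to prevent
underflow). Three recursions propagate them:

* **standard** — plain Felsenstein pruning under a single class;
* **lossy** (up-pass) — per branch, the class may be retained (weight
  p(t)^{1/L}, same-class matrix) or lost to background (weight q(t)^{1/L},
  change-time mixture matrix), options *summed*; gains are not allowed, to
  keep the liberal pass from hallucinating function;
* **gain-loss** (down-pass) — the same two options *maximised* per branch
  and per parent nucleotide, the decoding-time analogue of maximising over
  gain/loss histories; gains inside the clade are represented by the
  explicit gain states of the branch being decoded rather than inside the
  recursion.

All three agree with brute-force enumeration (over ancestral nucleotides,
and over loss labelings for the lossy sum) on 3- and 4-leaf clades to 1e−10
in log space. The marginal emission weights the root vector by the class
equilibrium. `N` bases are missing data (vectors of ones).

## Decoding

Pairwise Viterbi runs in log space over the dense state set with a numba
kernel laid out state-last (all states of one DP cell share cache lines).
The many "entry" transitions share one outgoing distribution up to a
per-source scale; the kernel exploits this verified factorisation with a
per-cell junction maximum, cutting the edge count several-fold.
Tie-breaking is deterministic: match > delete > insert, then lowest state
id. Hirschberg divide-and-conquer decoding (forward scores to the middle
row, reverse scores with the transposed transition matrix, combine, recurse
with pinned boundary states) is engaged automatically above a configurable
state-cell budget (default 5e7) and reproduces full-matrix scores to 1e−8;
when the optimum is unique it reproduces the path exactly, and at exact
ties (e.g. deleting vs. inserting the same base under the symmetric
background model) it returns a verified co-optimal path.

For the reversibility guarantee ("identical alignments whichever sequence
comes first"), the joint emission `diag(π)P` of reversible same-class
states is symmetrised (averaged with its transpose), which makes mirrored
decodes perform bitwise-identical arithmetic.

The up-pass aligns siblings on a branch of length t₁+t₂; the parent profile
is the union of sibling columns (matches merged, one-sided columns kept).
Dollo parsimony then assigns each column's origin to the MRCA of the leaves
carrying it and removes the column from every node above the origin.
The down-pass decodes the root profile with a single-sequence phylo-HMM
(site entry at the stationary per-column weight κ), then re-decodes each
branch constrained to the parent's functional parse: ancestor-consuming
states must carry the parent's class at that column. The ancestral side of
a branch decode uses the sibling's likelihood contribution (excluding the
child being aligned); information from above the parent enters through the
fixed parse. If a constraint ever renders all paths infeasible the branch
falls back to unconstrained decoding with a warning. Columns removed by the
Dollo filter at an ancestor simply re-align as descendant insertions, which
resolves the inconsistencies the filter can introduce. Sites are extracted
as complete profile runs in each taxon's parse; each run is labelled
`gained`, `retained` or (at the root) `ancestral` from the states that
produced it.

## Simulator

The forward simulator shares the aligner's model exactly: residues carry
persistent identities through replication (giving the true homology graph
over all nodes, ancestors included); sites are seeded at the root at the
stationary per-column rate κ with residues drawn from the PWM; on each
branch every site is independently retained (p) or lost (q, residues
substituting under the change-time mixture), gains occur as
`Binomial(⌊vacant/L̄⌋, b(t))` placed uniformly on vacant windows with
residues drawn through the bg→site mixture (so molecular homology is
preserved through gains), and background residues substitute under the GTR
process. Indels (geometric lengths with parameter β, opening probability
`(1−e^{−αt})/2` per position per direction) never touch currently
functional sites. Statistical tests confirm base composition, substitution
fractions and realized loss frequencies match the closed forms at 3σ.

What the simulator does *not* emulate: context-dependent or compensatory
turnover, local rearrangement, overlapping sites, rate variation beyond the
functional classes, and sequencing artefacts. Passing round-trip tests
therefore demonstrate correctness of the machinery under the model's own
assumptions, not performance on real enhancers.

## Training

* `estimate_indel_params`: gap-open/extension counts over parent–child row
  pairs of training alignments (add-one smoothing); α is the pooled MLE
  under `P(open at distance t) = 1 − e^{−αt}`, β the extension fraction.
  Recovers (α=0.05, β=0.7) within 10% from 100 simulated truth alignments.
* `fit_background_model`: joint L-BFGS maximum likelihood for GTR
  exchangeabilities, equilibrium and branch lengths on gap-free columns
  (patterns aggregated). Rates and times are confounded; the matrix stays
  normalised and the scale lives in the branch lengths.
* `estimate_factor_frequencies`: smoothed per-factor site counts; the 0.5
  strand factor is applied at assembly.
* `fit_discriminative_coeffs`: coordinate-wise hill-climbing of `c_indel`
  and `c_branch` (optionally λ) against mean site-level F on annotated
  training regions, multiplicative steps ×/÷1.5 refined to ×/÷1.1,
  stopping when no single move improves; ties keep the current value.

## Study conditions and problem sizes

The acceptance suite and `scripts/acceptance.py` use these frozen
conditions (chosen once; the seed controls only the simulated data):

* **Six-taxon tree** `(((a,b),(c,d)),(e,f))` with branch lengths
  0.02–0.07, scaled ×0.65 (total ≈ 0.29) for the low-divergence round-trip
  study and ×2.0 for the turnover study.
* **Round-trip study**: 10 replicates × 300 bp, three 12-column profiles of
  ~18–20 bits (the sharp end of curated PWMs — site identity must be
  unambiguous because the property under test is coordinate-exact recovery
  by the machinery, not detection power), δ = 0.1, turnover and indels
  disabled. Extracted predictions equal simulator truth exactly.
* **Turnover study**: 25 matched-seed replicates × 250 bp, two 8-column
  profiles (~10–13 bits, typical of real factors), δ = 0.2, µ = 2.0 (about
  20% of sites lost per 0.1-length branch — turnover events are common),
  α = 0.02. The full model's mean site-level F strictly exceeds the
  complete-orthology baseline's.
* Oracle grids: 20 random matrix pairs for the mixture; a 20×10
  (parameters × branch lengths) grid at RK4 step 1e−5 for the birth–death
  forms; exhaustive path enumeration over all `{A,C}` pairs of length ≤ 3;
  50 pairs each for Hirschberg equivalence and decode reversibility.

## Known limitations

* Whole-site turnover coherence is approximated per column (see above);
  column-inconsistent histories receive intermediate weights.
* Information above the parent (beyond its parse) is not propagated into
  branch re-decoding — a one-level outside approximation.
* Dollo decisions are final within a run; removed ancestral residues are
  not resurrected by later branch decodes.
* A single taxon's predictions cannot overlap; overlapping sites require
  separate runs with different factor subsets.
* Trees must be rooted and strictly binary; branch lengths are taken as
  given (tree estimation is out of scope).
* The discriminative coefficients repair, but do not remove, the mismatch
  between substitution-fitted branch lengths and the scales best suited to
  indel and turnover probabilities; separate branch-length sets per model
  component would be the principled extension.
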