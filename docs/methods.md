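# Methods

## Model

The predictor treats miRNA–disease association inference as diffusion on
four similarity networks. Let A ∈ {0,1}^(m×d) be the known associations.
Two networks are supplied by the user — the miRNA functional similarity FMS
and the disease semantic similarity DSS — and two are reconstructed from A
itself by locality-constrained linear coding: RMS over miRNAs (from the
rows of A) and RDS over diseases (from the columns). Known labels Y = A are
propagated over each normalized network and the four resulting score
matrices are averaged uniformly. The method's core assumption is that
similar miRNAs associate with similar diseases; everything below serves
that assumption.

### Disease semantic similarity

Each disease is a rooted DAG of ontology terms (ancestor closure of its
descriptor in a MeSH-style hierarchy). Contributions decay by a constant
factor per level: D_A(A) = 1 and D_A(t) = max over children t′ of
decay·D_A(t′). Because the decay is a single constant, the max-over-children
recursion equals decay^h for h the minimum child→parent hop count from the
disease to t; the implementation uses this shortest-hop form (breadth-first
traversal), and a test checks it against brute-force enumeration of all
root-to-ancestor paths on random DAGs. Similarity is the shared-ancestor
mass normalized by the two semantic values, which is symmetric, lies in
[0,1], is exactly 1 for identical DAGs and 0 for disjoint ones.

`decay` is exposed as a parameter (default 0.5, the conventional constant)
since nothing in the construction depends on its specific value. Terms found
in only one DAG contribute nothing. A roster entry whose term is missing
from the ontology raises instead of silently producing a singleton DAG.

### LLC reconstruction

For sample x_i with dictionary D (all other samples' profiles as columns),
the coding weights minimize ‖x_i − Dw‖² + λ₁‖P_i ⊙ w‖² subject to 1ᵀw = 1,
with the locality adapter P_ij = exp(‖x_i − x_j‖₂/γ) ≥ 1. The solution is
the normalized solve of (C + λ₁·diag(P_i)²)·w̃ = 1 with
C = (x_i1ᵀ − D)ᵀ(x_i1ᵀ − D). Since C is positive semidefinite and
diag(P_i)² ⪰ I, the system matrix is positive definite for any λ₁ > 0, so
the solve cannot fail for valid inputs.

Design choices that were genuinely open:

* **Dictionary contents.** The sample itself is excluded — including it
  would make w_i = e_i the trivial optimum and the reconstructed network an
  identity matrix, useless for propagation.
* **λ₁ in the system matrix.** The normal-equations form of the stated
  objective is C + λ₁·diag(P_i)²; setting λ₁ = 1 recovers the common
  unscaled variant. Default λ₁ = 0.1: small enough that reconstruction
  fidelity dominates, large enough to condition the solve.
* **Bandwidth γ.** Default is the median of pairwise sample distances
  (median heuristic), resolved once per reconstruction and logged; if all
  samples coincide the median is 0 and γ falls back to 1 (all penalties are
  exp(0) = 1 regardless). A fixed numeric γ can be supplied instead.
* **Adapter orientation.** P grows with distance (a penalty, entries ≥ 1);
  no max-subtraction normalization of P_i is applied.
* **Negative weights.** The affine constraint permits them. Default
  post-processing clips negatives to zero (without renormalizing — the
  sum-to-one property is a property of the raw solution only) and
  symmetrizes as (W + Wᵀ)/2, because the propagation normalization needs a
  nonnegative symmetric matrix. With clipping disabled the result may carry
  signed weights; `normalize_similarity` rejects such input loudly.
* **Degenerate samples.** All-zero profiles (which arise under LODOCV
  masking) are ordinary inputs: distances stay finite and the solve
  proceeds. Duplicate dictionary samples split weight symmetrically through
  the linear solve, with no special casing. A one-entity axis has no
  dictionary at all and yields an empty (all-zero) network, which
  propagation degrades gracefully on.

### Propagation and fusion

Networks are normalized symmetrically, S ← D^(−1/2)·S·D^(−1/2) with D the
diagonal of row sums; for symmetric nonnegative input the spectral radius
is then ≤ 1 and the iteration F ← rate·S·F + (1 − rate)·Y from F(0) = Y
converges for any rate in (0,1) to (1 − rate)(I − rate·S)^(−1)·Y. Zero-sum
rows map to zero rows (an isolated entity keeps only its (1 − rate)·Y
prior). Both the iterative mode (default, tol 1e−6, max 1000 iterations,
non-convergence returns the last iterate with a warning) and the
closed-form solve are provided; they agree to ~10·tol and a test enforces
it. All four networks are normalized identically. Disease-space propagation
uses Yᵀ and the result is transposed back before the uniform average
F = (F_M + F_RM + F_D′ + F_RD′)/4. The rates default to α = β = 0.5.

## Evaluation protocols

* **Global LOOCV**: each known pair is zeroed in turn, the full pipeline
  (including LLC reconstruction) is re-run on the masked matrix, and the
  held-out pair is ranked against every pair that is 0 in the original
  matrix. Other known pairs are excluded from the negative pool by default
  (a flag includes them for sensitivity analysis).
* **Local LOOCV**: the pool is restricted to the held-out pair's disease.
  Per-disease AUCs are reported alongside the pooled value; diseases with
  no knowns or no candidates are skipped with a log notice.
* **k-fold CV** (default 5 folds × 20 repeats): known pairs are shuffled and
  split per repeat; each repeat draws from its own child of the top-level
  seed, so the first repeats of two runs with the same seed coincide
  regardless of the repeat count.
* **LODOCV**: a disease's entire column is zeroed; its removed miRNAs are
  ranked against the disease's remaining candidates. This probes diseases
  with no known labels and is the most stringent protocol.

AUC uses the midrank Mann–Whitney convention (ties count ½), which equals
the trapezoidal ROC area; the equality is asserted in tests rather than
assumed. Pooled reports build their ROC from each positive's rank among its
round's negatives. The masking is leakage-free by construction — the
reconstruction inside a fold sees only the masked matrix — and a test
verifies that re-inserting a single held-out bit changes both the
reconstruction and the final scores.

The α×β sweep utility evaluates a rate grid under a fixed seed; fold
partitions are identical across cells and the LLC reconstructions (which do
not depend on the rates) are cached, so the grid is exactly what
independent per-cell runs would produce, only faster.

## Synthetic data

The generator plants the structure the method assumes: miRNAs and diseases
are split into co-clusters; associations are Bernoulli(density_within)
inside a co-cluster and Bernoulli(density_between) outside, then flipped
with a small probability (label noise); miRNA similarity is drawn high
(U(0.6, 0.9)) within blocks and low (U(0, 0.2)) between, symmetrized with
unit diagonal; disease DAGs give same-block diseases a shared three-term
ancestor chain and different blocks only a common root, and about half the
diseases get a private intermediate term so semantic values vary within a
block. A block model was chosen over degree-heterogeneous alternatives
because the co-cluster is the literal form of the "similar miRNAs ↔ similar
diseases" assumption. Everything is deterministic given the seed.

The standard fixture — 20 miRNAs × 15 diseases, 3 blocks, densities
0.7/0.05, 2% flips, seed 7 (86 known associations) — is committed as TSV
files and doubles as the regression dataset. Problem sizes throughout the
tests and the acceptance script (20×15 up to 40×30, ≤ 50-dimensional oracle
instances) are chosen so the whole suite completes in seconds while still
exercising every code path at a scale where the planted signal is clearly
recoverable.

What the fixture does **not** emulate: the heavy-tailed degree
distributions of real association databases, miRNA family/cluster
correlation structure, ontology DAGs with many roots and reconvergent
paths, and realistic sparsity (real matrices are ~3% dense and much
larger). Passing tests therefore demonstrate correctness of the machinery
and recoverability of clean co-cluster signal, not expected performance on
curated biological data.

## Measured behaviour on the standard fixture

With the defaults (λ₁ = 0.1, median γ, α = β = 0.5) the committed fixture
gives global LOOCV AUC 0.8818, local LOOCV 0.9034, five-fold × 20 0.8584
and LODOCV 0.7452 — the expected ordering, with LODOCV hardest. The
propagation rates matter more at this scale than on large datasets: the
α×β ∈ {0.1..0.9}² five-fold grid spans ≈ 0.18 AUC, almost entirely from
the heavy-diffusion corners (rate 0.9), where with only ~86 labels the
diffusion smooths the signal away. Every one of the four component score
matrices shows the same degradation individually, and the spread shrinks as
the dataset grows, so this is a small-sample property of label propagation
itself, not of the fusion or the implementation.

## Known limitations

* Dense linear algebra throughout; fine for ontology-scale inputs
  (hundreds of entities), not tuned for tens of thousands.
* The LOOCV frameworks re-run the full reconstruction per held-out pair
  (leakage-free but O(knowns) pipeline runs); at HMDD scale (5,430 knowns,
  495×495 solves each) a run takes hours, not seconds.
* Uniform fusion of the four score matrices is the stated design; no
  learned weighting is provided.
* The miRNA functional similarity is consumed as a precomputed matrix; the
  package does not derive it from disease terms.
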