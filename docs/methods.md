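# Methods

## The model

A *protein-coding unit* collects, for one gene, the chromatin-accessibility
peaks assigned to its transcript promoters (layer `a`), the protein-coding
transcript isoforms (layer `s`) and the protein product (layer `p`).
Causality flows one way — accessibility enables transcription, transcripts
are translated — so the unit is a three-layer DAG with edges only `a→s` and
`s→p` and directed paths of length at most two.  Treating each unit as a
Bayesian network, the joint density factorizes over the DAG, and every
*missing* edge corresponds to a conditional independence ("Markov
condition") x ⊥ y | C for a d-separating set C.  Because the graph is known
from sequence annotation and every node is measured, the factorization can
be tested empirically: the package enumerates the conditions and checks
each one with a sample partial correlation.

### Canonical conditioning sets

For three-layer DAGs the nodes can be well ordered so local
(parent-conditioning) and global (d-separation) Markov conditions coincide.
The canonical sets used per class of non-adjacent pair are:

| class       | pair                      | C                                    |
|-------------|---------------------------|--------------------------------------|
| `a-a`       | two peaks                 | ∅ (roots; every path has a collider) |
| `a->s`      | peak, non-child splice    | pa(s)                                |
| `s-s`       | two splices, same unit    | pa(s₁) ∪ pa(s₂)                      |
| `a->p`      | peak, protein             | ch(a) ∪ co-parents of ch(a)          |
| `s-between` | splices of merged units   | pa(s₁) ∩ pa(s₂) (shared peaks)       |
| `p-p`       | proteins of merged units  | pa(p_first), the first protein's splices |

The co-parent augmentation for `a->p` is needed whenever a peak's child
splice has additional peak parents: conditioning on the shared child opens
the collider `a→s←a'`, so the co-parent a' must be blocked as well.  On
units without shared splices the set reduces to ch(a).  Every emitted set
is asserted to d-separate its pair (moralized-ancestral-graph check via
networkx).  A `minimal=True` mode greedily prunes each set to a minimal
d-separator; the default keeps the canonical sets because |C| enters the
Fisher degrees of freedom.

The class `s->p` never occurs: every isoform is connected to its protein by
construction.  All `s-s` pairs of a unit are moral edges (the shared
protein makes `s₁→p←s₂` a v-structure), so their conditions say nothing
about missing causal edges; the between-layer classes `a->s` and `a->p`
are the structurally informative ones.

For joint graphs produced by shared-peak merging, the within-unit
conditions are kept and two cross-unit classes are added (splice pairs
given their common peaks, protein pairs given the first protein's splice
set).  Cross-unit s/p pairs carry no condition.  Protein-complex couplings
add an undirected p–p edge; the graph is then mixed, the coupled pair is
treated as adjacent, and no condition is generated across it.

## Dynamical correlation

Trajectories are compared through the span-normalized inner product
⟨u,v⟩ = (t_N−t_1)⁻¹ ∫ u v dt, discretized on the sampling knots with
trapezoid weights w₁ = (t₂−t₁)/2T, w_N = (t_N−t_{N−1})/2T,
w_k = (t_{k+1}−t_{k−1})/2T; the weights sum to one.  Replicated series are
centered by the grand mean of per-replicate time averages, standardized by
the pooled variance Var = (M−1)⁻¹ Σ_r ⟨x_r^C, x_r^C⟩, and pooled as
R_ij = (M−1)⁻¹ Σ_r ⟨x_{i,r}^S, x_{j,r}^S⟩ (for M = 1 the prefactors drop).
R is exactly unit-diagonal, positive semidefinite, bounded by one in
magnitude, invariant to positive affine rescaling per variable, and flips
sign under negation — all asserted by randomized property tests.

Numerical choices:

- The boundary convention printed alongside the discrete formula in the
  source method ("t₀ = t_{N+1} = 0") would make the last weight negative
  whenever t_{N−1} > 0; we treat it as a typo and use the standard
  trapezoid endpoint weight, which matches the printed first weight when
  t₁ = 0.
- The replicate-centering formula is read as subtracting the grand mean
  over replicates of per-replicate time averages (its printed replicate
  index is inconsistent); only a constant offset is involved either way.
- The knot-product rule Σ w_k u_k v_k is used as printed, not the exact
  integral of products of linear interpolants (which would add a cross
  term).  It is exact whenever u·v is piecewise linear on the grid.
- Native grids are lifted to a common uniform grid (default [0, 24] h at
  0.5 h, i.e. 49 points) by cubic splines with not-a-knot boundaries, one
  spline per replicate.  Correlations are computed on the common grid
  because peak/splice grids (6 points) and the protein grid (5 points)
  differ.
- Partial correlations come from inverting the restriction of R to
  {x, y} ∪ C; submatrices with condition number above 1e10 are skipped and
  flagged rather than pseudo-inverted.

A Kolmogorov–Smirnov screen against N(0,1) (α = 0.01) is applied to the
pooled standardized ("detrended") values per variable before correlation
analysis.

## Verification threshold

x ⊥ y | C is *verified* when |R_xy.C| < θ with

θ = tanh( Φ⁻¹(1−α/2) / √(N − |C| − 3) ),

the largest magnitude not rejecting independence under the Fisher z test.
Defaults: α = 0.05 and N = 147 (49 interpolated points × 3 replicates),
giving θ ≈ 0.162.  By default θ uses |C|-specific degrees of freedom; a
single global θ (|C| = 0) is available as `theta_mode="global"`.

**Caveat — effective sample size.**  N = 147 counts interpolated points.
The information content of a replicate is bounded by its six native
samples, and the quadrature weights concentrate ~83% of their mass on the
[6, 24] h segment, so the effective sample size of the inner product is
closer to ~10 than to 147.  Empirically, the sample dynamical correlation
of two *independent* smooth signals sampled on the native design has a
null spread of ≈ 0.27, far above θ.  Consequences for synthetic data:
truly conditionally independent pairs verify at only ~10–20% under the
default θ, and ranking-style analyses (balance enrichment, planted-edge
detection, ROC sweeps) are more informative on this generator than
absolute verification rates.  N is exposed in `TestConfig` precisely so
users can study this trade-off; the default remains 147.

## Balance and inverse balance

The signed graph G(R) of a correlation matrix is balanced when every cycle
has an even number of negative edges, equivalently when a gauge d ∈ {±1}ⁿ
makes D R D entrywise nonnegative.  `is_balanced` assigns spins by BFS and
either returns the gauge or a violating odd cycle.  Inverse balance is
balance of G(P) with P = 2I − H the partial-correlation matrix
(equivalently the concentration matrix gauges to an M-matrix — signed
MTP₂).  Inverse balance implies balance; under inverse balance the
contraction |R_xy.C| ≤ |R_xy| holds systematically (verified on 1000
random signed-MTP₂ matrices), under plain balance it is typical only, and
unbalanced motifs supply counterexamples where conditioning expands the
correlation.

A condition's motif is the complete signed subgraph of G(R) on {x, y} ∪ C
(including the x–y edge); |C| = 0 motifs are balanced by convention
(no cycle).  Sample correlations are almost never exactly zero, so entries
with |R_ij| < 1e-8 are treated as absent edges purely to guard degenerate
synthetic cases.  For the ROC/precision-recall analysis, balance
(or inverse balance) is the truth and "verified at threshold θ" the
prediction; θ sweeps 1001 equally spaced values in [0, 1] and AUCs use the
trapezoid rule.

## Synthetic data generator

No public generative model exists for the study's joint ATAC/RNA/protein
time courses; the generator is an explicit stand-in with the statistical
structure the analysis assumes:

- **Design**: 3 biological replicates; peak/splice grids
  [0, 0.5, 1, 2, 6, 24] h; protein grid [0, 1, 2, 6, 24] h (no 0.5 h
  protein sample, the 120 h point is not modeled).
- **Structure**: each unit draws 1–3 peaks and 1–5 splices (uniform);
  every splice gets one uniform-random primary peak parent plus extra
  parents with probability 0.25; orphan peaks attach to a random splice;
  all splices feed the protein.
- **Signals**: each root peak carries a smooth latent trajectory — cubic
  B-spline bumps on [0, 24] h (6 basis functions) with standard-normal
  coefficients — shared across replicates, mimicking one differentiation
  response measured in triplicate.
- **Equations**: instantaneous linear propagation, s = Σ w·a + ε,
  p = Σ w·s + ε, with smooth spline noise ε of coefficient scale 0.15 and
  edge weights uniform on [0.5, 1.5] (sign flipped with probability 0.2,
  bounded away from zero so true edges are detectable).  There are no
  transport delays: the correlation machinery is delay-free.
- **Observation noise**: iid N(0, 0.25²) per replicate per native time
  point.
- **Violations**: optional direct a→s edges bypassing the assumed DAG and
  hidden smooth confounders loading on ≥2 splices; both enter the
  generating equations but not the assumed DAGs, and are recorded in a
  ground-truth ledger for recovery studies.

What the generator deliberately does not emulate: count-based noise
(negative binomial), read-level artifacts, normalization effects,
regulatory coupling between units (TFs, shared machinery), and
non-stationarity beyond what the smooth latents induce.  Passing tests on
this generator therefore validate the *machinery* (enumeration, estimator
identities, threshold logic, balance classification, recovery of strong
planted violations) — not that real multi-omics data will reach any
particular verification rate.

Known generator-linked limitations, measured and accepted:

- Between-layer verification rates on synthetic populations sit at
  ~10–15%, far below the rates reported for the real study data, because
  of the effective-sample-size issue above.  Detection of *planted* a→s
  edges with weight ≥ 3× the total noise scale remains reliable (~92%
  flagged), and verified conditions are significantly enriched in
  balanced motifs, reproducing the qualitative balance→verification link.
- The two null models (randomized y; randomized y and C) produce success
  distributions statistically indistinguishable from the true conditions
  on this generator: partial-correlation success probabilities are
  invariant to per-variable rescaling, so "C captures information about x"
  confers no advantage when every variable carries the same effective
  degrees of freedom.  Under a fully independent generator the true/null
  comparison is correctly calibrated (uniform t-test p over seeds).

## Pipeline sizes and determinism

Default study sizes (pipeline and acceptance script: 40 units, ≈ 350
conditions; recovery studies: 50 seeds × 6 units) were chosen to make all
reported rates stable to a few percent while keeping any single run in
seconds.  All randomness derives from a single integer seed through
`numpy.random.SeedSequence` streams per stage; identical config + seed
yields byte-identical outputs.
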