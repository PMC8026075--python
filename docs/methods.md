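# Methods

## Coefficient registry

The registry maps a contingency quadruple (a, b, c, d) — positive matches,
the two mismatch directions, negative matches for a pair of binary
attributes over n observations — to 71 similarity values. Families follow
the conventional taxonomy: 18 co-occurrence coefficients that ignore
negative matches (Jaccard, Gleason/Dice, Kulczynski, Ochiai/Driver–Kroeber,
…), co-occurrence coefficients with total matches a + d (simple matching
and its relatives), association coefficients carrying the table determinant
ad − bc (phi, Yule's Q and W, Cohen's kappa-like form, …),
chi-square-type measures (Pearson I/II, Stiles), the pair-counting Rand and
adjusted Rand indices expressed through the observation-pair counts
N = n(n−1)/2, B = ab + cd, C = ac + bd, D = ad + bc, A = N − B − C − D, and
Loevinger's H.

Readings fixed where the conventional printed forms are ambiguous:

- **Yule's W** is the square-root (coefficient of colligation) form
  (√(ad) − √(bc)) / (√(ad) + √(bc)), which keeps it distinct from Yule's Q;
  this reading is corroborated by the exact affine tie of the
  Baroni-Urbani & Buser pair (II = 2·I − 1), which likewise requires the
  √(ad) reading in both.
- **Tetrachoric approximation**: cos(180° / (1 + √(ad/bc))), the 180 read
  as degrees (π radians). The bc → 0 limit is +1 and the ad → 0 limit −1;
  these limits are returned rather than an undefined value. Only the 0/0
  case is undefined.
- **Pearson II** is √(χ² / (n + χ²)) with χ² the Pearson statistic of the
  2×2 table (shared with Pearson I and Stiles); Stiles uses log₁₀, the
  Consonni–Todeschini family and Gilbert–Wells natural logarithms.
- **Rand index**: the pair-agreement proportion (A + D)/N — pairs of
  observations co-clustered by both attributes plus pairs separated by
  both. (A + B)/N, occasionally seen, equals the one-sided quantity
  C(a+b,2) + C(c+d,2) over N, which depends on one attribute's margin only
  and is not a similarity between the two attributes; the adjusted Rand
  numerator N(A + D) − [(A+B)(A+C) + (C+D)(B+D)] confirms A + D as the
  agreement count. The A.51-style adjusted Rand coefficient is
  algebraically identical to the Hubert–Arabie index of the two binary
  partitions, and the package cross-validates its two independent
  implementations (quadruple form vs cluster cross-tabulation) in the test
  suite.
- **Loevinger's H** is 1 − e/(n·π₁·π₂) where π₁ ≤ π₂ are the base rates of
  the two attributes and e counts observations on which the
  lower-base-rate attribute is 1 and the other 0. When the population
  rates are known — as in a designed simulation — they are used as given
  constants; for observed data the sample margins stand in. This matters:
  with estimated margins the denominator co-fluctuates with e and the
  coefficient's correlation with determinant-based measures is noticeably
  inflated at asymmetric base rates. A `variant="mokken"` flag provides the
  scaling-theory form 1 − e/(n·π₁·(1−π₂)) (observed over expected Guttman
  errors), which is centred at 0 for independent attributes; it is not the
  form used in the experiment pipeline.

### Undefined values

Evaluation is total: a vanishing denominator or an out-of-domain logarithm
yields NaN, never an exception (e.g. Jaccard on (0,0,0,d), the odds ratio
when bc = 0, Kulczynski I when b = c = 0). An optional Haldane +0.5
correction is available for the odds ratio but is off by default.

One undefined case is systematic rather than exotic: Stiles' continuity
correction (|ad − bc| − n/2)² is *exactly* zero whenever |ad − bc| = n/2.
Because ad − bc = n·a − (a+b)(a+c) lives on a coarse integer lattice, this
happens on roughly one trial per thousand at n = 2000 — not the
measure-zero event a continuous heuristic would suggest. The correlation
layer therefore treats rare NaNs by pairwise complete-case deletion and
only drops a coefficient outright when more than 1% of its values are
undefined (or when its defined values are constant, which makes
correlation meaningless). With the default design this excludes exactly
Goodman–Kruskal I and Anderberg — their shared numerator τ₁ − τ₂ is
identically zero at every cell where one margin dominates — leaving 69
coefficients; a coefficient dropped at any cell is excluded from every
cell so that all partitions share one label set.

## Synthetic data generator

Each trial draws two independent binary attributes with base rates
π₁ ≤ π₂ over n = 2000 observations and reduces them to a quadruple. Under
independence the quadruple is multinomial with cell probabilities
(π₁π₂, π₁(1−π₂), (1−π₁)π₂, (1−π₁)(1−π₂)); the default sampler draws it
directly (≈3 orders of magnitude faster), and an explicit-vector sampler is
retained for fidelity checks — the two are distributionally identical, and
the test suite compares their moments. The design is a grid of 15
base-rate pairs, [.1,.1] through [.9,.9], with 100,000 trials per pair by
default. n = 2000 makes zero cells essentially unobservable at these
design cells (the rarest cell count has expectation 20).

Seeding: one master seed; each base-rate pair derives an independent child
stream keyed by the pair's identity, so cells can be generated in any
order, or alone, with identical results.

What the generator does *not* emulate: dependent attributes (the design is
independence-only, so all inter-coefficient correlation arises from shared
sampling fluctuations of the quadruple, not from real association),
respondent-level heterogeneity, and structured missingness. Conclusions
about coefficient concordance therefore describe behaviour under the null
of unrelated attributes at controlled margins; they say nothing about how
the coefficients rank truly associated attribute pairs.

## K-median partitioning

Partitions maximise Z = Σᵢ max_{j∈Q} s_ij over exemplar subsets |Q| = K.
The similarity matrix must have each diagonal entry maximal in its row
(ties allowed — perfectly correlated coefficients produce off-diagonal
entries exactly equal to 1), so exemplars are always self-assigned.

The solver is multistart fast interchange: random initial exemplars,
assignment of every item to its most similar exemplar, then repeated
evaluation of exemplar/non-exemplar swaps until no swap improves Z.
Numerical choices:

- **First-improvement** by default (accept a swap as soon as one improves,
  rescan), scanning exemplars then candidates in index order;
  best-improvement is available via a flag. Both end 1-interchange locally
  optimal; only the path differs.
- A swap must improve Z by more than 10⁻¹² to be accepted, preventing
  cycling on floating-point ties.
- Assignment ties go to the lowest-index exemplar, making partitions
  reproducible when coefficient columns are exactly tied.
- The default 2000 restarts is conservative for p ≈ 69, K = 2; the test
  suite verifies on random instances that 50 restarts already match
  exhaustive enumeration ≥ 99% of the time, and the experiment defaults can
  be lowered accordingly (the bundled study runs use 200–500).
- A brute-force enumerator (guarded at 10⁶ subsets) serves as the exact
  oracle for small instances.

## Partition comparison

Agreement between two partitions is the Hubert–Arabie adjusted Rand index
computed from the cluster cross-tabulation: 1 for identical partitions up
to relabelling, expectation ≈ 0 under chance. Cross-cell structure is
summarised two ways: the full matrix of pairwise ARIs between the 15
per-cell partitions (with ≥ .65 conventionally read as at least fair
agreement), and co-membership stability — for each coefficient pair, the
number of cells in which they share a cluster. Subsets stable across all
cells are the connected components of the all-cells co-membership graph;
at the full threshold co-membership is an intersection of equivalence
relations, so components are provably cliques (the code verifies rather
than assumes this). Below the full threshold the relation loses
transitivity and maximal cliques are reported instead.

## Scales used by the bundled runs

The test suite and the acceptance script run the full pipeline at 20,000
trials per cell (with 200 and 500 restarts respectively) rather than the
100,000-trial default: at 20,000 trials the Monte-Carlo standard error of
an inter-coefficient correlation is below 0.006 everywhere, comfortably
inside the comparison bands used, while the whole study completes in
seconds. The exact affine-identity structure (e.g. Hamann = 2·simple
matching − 1, Johnson = 2·Kulczynski II) holds at *any* number of trials,
so the six perfectly correlated coefficient groups are scale-free checks.

## Known limitations

- The two-cluster K-median solution at some design cells is *bistable*:
  two exemplar sets with nearly identical Z exist, corresponding to
  cutting the coefficient spectrum at two different places (this is
  pronounced at the asymmetric mid cell [.3, .7]). Which optimum wins
  depends on the sampling seed, at any practical number of trials.
  Downstream cross-cell ARI values involving such cells inherit this
  sensitivity, so single printed ARI values should be read as one draw
  from a small discrete set of attainable configurations.
- ARI between 69-item two-cluster partitions is strongly quantised:
  relocating a single coefficient moves the index by ~0.06–0.12. Small
  numerical differences between runs therefore appear as discrete jumps.
- Loevinger's H depends on which base rates are plugged in (population vs
  estimated margins); both are supported but they are not interchangeable
  in fine-grained correlation comparisons.
- K > 10 would need metaheuristics beyond multistart interchange; the
  package deliberately stops at the multistart heuristic plus a small-p
  exact enumerator.
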