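# Methods

## Model and procedure

`sdcons` treats each docking program as a black box that assigns every
molecule of a library a scalar score with a declared direction
(free-energy-like scores: lower is better; fitness scores: higher is better).
For program p with scores s_p, mean μ_p and sample standard deviation σ_p
(n−1 denominator), the goodness z-score is

    z_p(m) = ± (s_p(m) − μ_p) / σ_p

with the sign chosen so that larger z is always better. The stand-out set of
program p at multiplier x is {m : z_p(m) ≥ x}; in raw score units the cutoff
sits x·σ_p from the mean, which is how it is reported.

* **SDC** intersects the k stand-out sets at fixed x (default 2, motivated by
  the shape of library rank curves, where the stand-out good tail detaches
  from the unimodal bulk at roughly two standard deviations).
* **vSDC** fixes the selection size n_test and scans x downward over the grid
  {3.5, 3.499, 3.498, …} until the intersection holds at least n_test
  molecules. Because the intersection at cutoff x is exactly
  {m : min_p z_p(m) ≥ x}, the scan is resolved in closed form from the
  n_test-th largest min-z, then verified against the literal grid so the
  result is bit-identical to a step-by-step scan.
* **USC** takes the top ⌊n_test/k⌋ molecules of each ranking, unions them,
  and tops up round-robin over programs in input order (each contributing its
  next-best not-yet-selected molecule) until exactly n_test are selected.

The rationale for intersection-based consensus is probabilistic: scoring
functions err on different molecules, so the chance that all k independently
promote the same false positive is small, while a genuinely active molecule
tends to score well — if not at the very top — in all of them.

## Metrics

For a selection of n_test molecules containing h actives out of the A actives
present in the library: Y = h/n_test, E = h/A, and the corrected yield
Y_C = h/min(A, n_test). Y_C equals Y when n_test ≤ A and E when n_test ≥ A,
so it stays informative in both early-recognition corner cases (h = n_test ≪ A
gives Y = 1 but E ≪ 1; h = A < n_test gives E = 1 but Y < 1). Cohort-level
summaries are the fraction of targets with at least one hit (T_h>0), the
unweighted mean of Y_C over targets (valid because the dilution protocol
equalizes active density across targets, making Y_C comparable between them),
and the net balance Δp of per-target win/loss counts with ties excluded from
both counts but retained in the denominator. The mean Y_C is reported with
the standard error of the mean; SEM is one reasonable dispersion estimator
among several, and is stated explicitly for that reason. Inter-program
divergence is quantified with Spearman's rank correlation (average ranks for
ties) on the common molecules, both rankings direction-normalized first;
rank correlation is preferred over Pearson because scoring functions report
heterogeneous units.

## Parameters and conventions

| Parameter | Default | Notes |
|---|---|---|
| SDC multiplier x | 2.0 | in SD units of each program's score distribution |
| vSDC scan start | 3.5 | SD units |
| vSDC scan step | 0.001 | SD units |
| vSDC floor x_min | −10.0 | diagnosable infeasibility instead of an unbounded scan |
| dilution density | 0.005 | actives / library after removal |
| supported programs k | 2–12 | ≥ 2 for any consensus; 1 accepted by vSDC as a top-n degenerate mode |

Numerical and tie-break conventions, pinned so every result is deterministic
and seed-free where randomness is not inherent:

* **Sample SD** (n−1). At library scale (≥10³ molecules) the difference from
  the population SD is < 0.1 %; tests pin the convention on toy sizes.
* **Boundary-inclusive** stand-out membership (z ≥ x): deterministic under
  grid search and generically indistinguishable from the strict inequality.
* **Variant collapse before standardization**: structure variants
  (enantiomers/tautomers/protomers) are collapsed to their parent compound,
  keeping the best-scoring variant under the table's direction; consensus and
  hit counting operate on unique compounds.
* **Missing molecules**: a molecule absent from one program's table is never
  stand-out for that program and can never enter an intersection consensus;
  a warning reports how many ids are not shared by all tables.
* **vSDC overshoot**: the intersection size jumps, so the scan stops at the
  first grid x with size ≥ n_test; by default the overshoot is trimmed to
  exactly n_test by keeping the highest summed-z members, guaranteeing the
  user-facing contract "you get n_test molecules". `trim=False` exposes the
  raw intersection (used by the oracle tests). Whether to trim at all is a
  genuinely open choice; both behaviours are first-class.
* **Ordering** of consensus members is by decreasing summed z across
  programs; all ties anywhere break lexicographically by molecule id.
* **Degenerate inputs**: a zero-SD score column raises
  `DegenerateDistributionError`; a target with A = 0 raises
  `UndefinedMetricError` (no findable hits — the dilution protocol
  guarantees A ≥ 1); vSDC infeasibility raises an error carrying the maximum
  achievable nCM, and inside a cohort sweep degrades to a flagged zero-hit
  outcome so one pathological target cannot abort the run.
* **USC for n_test not a multiple of k** is generalized via the round-robin
  top-up; the benchmark additionally offers a `usc_paper_mode` that averages
  the evaluations at the two adjacent multiples (e.g. 48 and 52 for 50),
  the convention under which equal per-program shares are preserved.
* **Dilution** removes randomly chosen actives from the library entirely
  (they are eliminated, not relabelled), keeping the retained count A the
  largest integer with A/(N_inactive + A) ≤ density, and is performed once
  per target with a recorded seed.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
docking physics. Each molecule carries a latent goodness g ~ N(0,1); program
p observes z_p = w·g + (1−w)·ε_p + s_p·1{active}, with independent noise
ε_p, shared-signal weight w and per-program sensitivity s_p (the mean z-shift
of planted actives). Raw scores are a per-program affine map of z respecting
the declared direction. Defaults: 2,000 molecules, 0.5 % actives, k = 4
programs, w = 0.3 (inter-program r ≈ 0.15, the weak-correlation regime of
divergent docking programs; w spans independence at 0 to identical rankings
at 1, covering the occasional r ≈ 0.6–0.7 pairs as well), s = 2.0. Cohorts
jitter the sensitivities per target (truncated normal, SD 0.4) so that which
program performs best varies by target, as it does on real benchmarks; the
acceptance cohort uses heterogeneous base sensitivities (2.5, 2.4, 1.8, 1.7)
emulating the common two-stronger/two-weaker program regime. An optional
nuisance covariate (off by default) adds a shared molecule-size-like term to
chosen programs, emulating scoring functions that correlate with atom count.

What the generator does **not** reproduce: heavy-tailed or multimodal score
distributions, chemistry-driven clustering of actives, target-dependent
correlation structure beyond a single shared factor, and score ties. Passing
tests therefore demonstrate algorithmic correctness and the expected
qualitative behaviour of consensus under a shared activity signal — not
performance guarantees on any particular real screen.

## Problem sizes

The test suite and acceptance script run on deliberately scaled problems
chosen as representative while keeping runs quick: oracle-equivalence trials
use 30–500-molecule libraries over 100 seeds; the recovery study uses
20-target cohorts of 2,000 molecules at 0.5 % active density over 20 seeds
(A = 10 per target, the regime where n_test ≈ A); the cohort smoke test uses
102 targets of 1,000 molecules. Worked-example recomputations use the
original library sizes (14,307 and 8,152 compounds) since building a ranked
table of that size is trivial.

## Known limitations

* Consensus quality is bounded by the programs supplied: intersecting k
  copies of a bad ranking yields a bad consensus, and with strongly
  heterogeneous program quality the consensus can trail the best single
  program even while beating the average (consistent with the two-program
  analyses on real benchmarks).
* vSDC's x_used is reported on the scan grid; two molecules whose min-z
  differ by less than the step can be separated only by the trim rule.
* The harness evaluates selections against fixed labels; it does not model
  assay noise or the cost asymmetry of false positives vs false negatives.
* Activity files admit only binary labels; potency-weighted variants are out
  of scope.
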