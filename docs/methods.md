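# Methods

## The model

Transcriptional control is modeled log-linearly: the relative log2 expression
of gene *i* at condition *m* is a weighted sum of latent TF activities,
`E = A P`, with `A` (genes × TFs) the control-strength matrix carried by a
known connectivity support (zero off-support) and `P` (TFs × conditions) the
activity matrix, each TF's activity defined relative to the reference
condition (zero at time 0). The model assumes mRNA levels are governed by
transcriptional regulation alone — mRNA stability, translation and
post-translational control are outside it — and that the connectivity support
is correct where it is nonzero (the fitted strengths may be any sign and
magnitude, including effectively zero).

`make_log_ratios` offers two references for building `E`: the treated arm
relative to its own time-0 mean, or the treated arm relative to the matched
control at each time. The second (the default in the pipeline) cancels
time-dependent effects shared by both arms.

## Fitting: alternating least squares

`fit_nca` minimizes ‖E − AP‖²_F by exact alternating least squares: given
`P`, each gene's supported strength entries solve an ordinary least-squares
problem on the activity rows in its support (grouped by support size and
solved as batched normal equations; a ridge of 1e-10 is the fallback for a
singular group); given `A`, `P` solves one full least-squares problem. Both
half-steps are exact minimizers, so the objective is non-increasing — this is
asserted per-iteration in the test suite. Convergence is declared when the
relative objective decrease falls below `tol` (default 1e-8, on the objective
rather than the parameters, since the parameters carry a scaling ambiguity);
`max_iter` defaults to 2000. Each of `n_restarts` (default 10) runs starts
from `P = pinv(A0) E` with `A0` random on the support; the best final
objective wins, and restarting stops early once an objective below
`tol · ‖E‖²` is reached, which no further restart could meaningfully improve.

## Identifiability

Uniqueness of the decomposition up to a per-TF diagonal rescaling requires:
(i) the support pattern has full generic column rank; (ii) removing any TF
together with all its targets leaves a pattern of full column rank; (iii) the
activities have full row rank, whose design-testable part is
`n_conditions ≥ n_TFs`. Criteria (i)–(ii) are evaluated by generic rank —
the rank of a random real matrix on the pattern, maximized over three fixed
seeds — which equals the symbolic rank of the pattern with probability one;
the test suite verifies exact agreement with a symbolic (sympy) rank oracle
on small patterns. Note that two TFs with identical target sets pass (i)
(their random instantiations are independent columns) and are caught by (ii),
whose reduced pattern contains an all-zero column.

`fit_nca` refuses a prior failing (i) or (ii). Criterion (iii) is reported
but only warned about: time courses commonly carry far fewer conditions than
TFs, and a sufficiently sparse support often pins the solution down anyway —
on the 50 × 10 × 6 benchmark the noiseless fit recovers truth to machine
precision despite 6 < 10. The package does not claim uniqueness in that
regime; it demonstrates recovery empirically. `reduce_to_identifiable`
prunes greedily (duplicate columns first, then rank-redundant columns,
fewest-targets-first) until the checker passes; the pipeline enforces only
the structural criteria by default (`enforce_sample_criterion` turns on the
sample-count rule, at the cost of pruning the TF layer to the condition
count).

## Normalization and bootstrap

The residual ambiguity `A → AX`, `P → X⁻¹P` (diagonal X) is resolved by
convention after fitting: `unit_max_activity` scales each activity row to
max |value| = 1 (alternatively `unit_norm_strength` normalizes strength
columns), with the sign chosen so the activity correlates non-negatively with
the TF's own expression when measured, falling back to a positive peak
entry. Scales within 1e-12 of unity are snapped to 1 so the operation is
bitwise idempotent. The objective is invariant by construction.

`bootstrap_nca` resamples gene rows with replacement, redraws resamples whose
pattern loses structural identifiability (aborting if more than half must be
redrawn — small supports with single anchor genes are genuinely too fragile
for row resampling, and the pipeline records that as "bootstrap skipped"),
refits each replicate warm-started from the full-data solution plus random
restarts, maps back to all genes by re-solving strengths against the
replicate's activities, normalizes, and reports 2.5/50/97.5 percentiles per
entry. Conditions are never resampled: with 4–6 of them, column resampling
would be meaningless.

## Differential expression

`moderated_t` is a two-sample empirical-Bayes test per time stage: per-gene
pooled variances `s²_g` (df `d = n_t + n_c − 2`) are shrunk toward a prior
variance, `s²_post = (d0·s0² + d·s²_g)/(d0 + d)`, and the statistic
`lfc / sqrt(s²_post (1/n_t + 1/n_c))` is referred to a t distribution on
`d + d0` df. The hyperparameters come from closed-form moment matching of the
observed variances against their scaled-F marginal (`s² ~ s0²·F(d, d0)`),
followed by a bounded profile-likelihood polish; when the observed spread is
no larger than chi-square sampling noise, `d0` is capped at 1e6 (near-complete
pooling). `d0 = 0` recovers the ordinary pooled t-test exactly. Selection
requires fold change > 1.5 on the linear scale in either direction **and**
p < 0.05, in at least two stages; p-values are used raw, with no
multiple-testing correction, because the downstream stages consume the
selected set rather than individual significance claims. Fold change is the
difference of arm means on the log2 scale.

## Enrichment and crosstalk

Pathway over-representation is the exact hypergeometric upper tail
`P(X ≥ k)` with the universe defaulting to the union of pathway genes
(configurable); significant pathways need at least two hits and p < 0.1.

For crosstalk, the PPI network is re-weighted per stage: node
differential-expression p-values from the moderated t, edge co-expression
p-values from the two-sided Pearson test across the stage's six samples
(both arms pooled; constant genes get p = 1 with a warning). The edge score
is Fisher's combination over the three p-values (k = 3); it is nonnegative,
zero only at all-unit p-values, and strictly decreasing in each argument.
Stouffer's Z is available as an alternative combiner. The overlap O_ij of a
pathway pair contains every edge with one endpoint in each set, in either
orientation, counted once — edges inside the intersection qualify. The
permutation null draws two independent same-size gene sets from the
pathway-covered portion of the network (configurable to all nodes) and uses
the add-one estimator, so p ∈ [1/(B+1), 1] and never 0. A pair with zero
observed score short-circuits to p = 1, flagged as an empty overlap.
`crosstalk_dynamics` repeats this per stage, seeding each (stage, pair) cell
deterministically from the top-level seed so the table is reproducible and
independent of pair order. B defaults to 10,000 per pair (2,000 in the
bundled pipeline configuration); millions of draws per pair are possible but
unnecessary at the bundled problem sizes, where the add-one resolution
1/(B+1) is far below every decision threshold in use.

## The synthetic-data generator

The generator emulates a two-arm perturbation time course (treated vs
vehicle control at 0/4/12/24 h, 3 replicates per cell, log2 scale with
per-gene lognormal-location baselines) and the priors around it:

- **Connectivity**: each TF receives one exclusive anchor target plus draws
  from a shared pool, making the pattern identifiable by construction
  (asserted at generation time).
- **Activities**: each TF is early-, mid- or late-phase; its activity rises
  from zero to a signed peak at the first, middle or last nonzero time and
  decays linearly. Rise curvature and decay rate vary per TF so that no two
  activity rows are proportional — without this, same-phase TFs would be
  exactly collinear and per-gene strengths unidentifiable in principle.
  Default amplitude 2.0 (log2 units, i.e. up to ~4-fold activity effects).
- **Expression**: treated replicates are baseline + (A·P) + Gaussian noise
  (default sd 0.1 log2 units, a typical well-replicated array dispersion;
  the source study does not state its platform noise); control replicates
  are baseline + noise. At zero noise the log ratios reproduce A·P to
  machine precision. TF mRNA rows, when enabled, track each TF's own
  activity with a configurable coupling (default 0.5) so activity–expression
  correlation analyses have signal.
- **Planted DEGs** are the regulated genes whose true log-ratio exceeds twice
  the selection fold-change cut at two or more stages; the doubled margin
  keeps the planted set unambiguous under the default noise.
- **PPI + pathways**: background edges are independent at a sparse rate
  (default 0.005, interactome-like); planted pathway pairs have their
  cross-set edge probability multiplied by `cross_edge_boost` (clamped at 1
  with a warning). Pathways are uniform random gene sets, optionally
  disjoint.

What the generator does *not* emulate: probe-level artifacts, normalization
and batch effects, correlated (non-independent) replicate noise, hub/scale-
free PPI degree structure, and curated-pathway gene overlap patterns. Tests
passing on this synthetic world therefore certify the algorithmic and
statistical contracts of the pipeline — exact recovery, calibration, power,
determinism — not performance on any particular microarray platform.

## Benchmarks and numerical choices

The benchmark problem sizes were chosen to exercise every property at desk
scale: recovery on 50 genes × 10 TFs × 6 conditions (noiseless, and noise
sd 0.1 over 5 seeds); DEG selection on 100 genes with 25 planted effects of
1.2 log2 units at noise sd 0.25 (about five noise standard deviations, an
unambiguous perturbation); permutation calibration over 200 *independent*
synthetic replicates — independence matters, as p-values of many pairs
sharing one network are correlated and would invalidate a KS uniformity
check — and permutation power with 2 planted pairs among 20 disjoint
25-gene pathways on a 0.002-rate background with a 20× boost, scored on a
null-expression world so the C ranking reflects topology rather than extreme
node weights.

Numerical details: generic rank uses three fixed instantiation seeds and
numpy's default rank tolerance; zero p-values entering Fisher's combination
are floored at the smallest positive double with a warning; correlation
distance matrices are symmetrized before linkage; the Pearson edge test is
the closed-form t transform `t = r·sqrt((n−2)/(1−r²))` vectorized over
edges; all randomness flows from integer seeds through
`numpy.random.SeedSequence`, and per-(stage, pair) seeds are derived
hash-style so results do not depend on iteration order.

## Known limitations

- With fewer conditions than TFs, uniqueness is not guaranteed by the rank
  theory; recovery rests on support sparsity and is verified empirically,
  not proven.
- The bootstrap resamples genes, treating gene rows as exchangeable; with
  strongly heterogeneous per-gene noise this understates strength
  uncertainty for well-measured genes.
- The moderated-t hyperparameter fit is moment matching (plus a likelihood
  polish), not the full marginal-likelihood estimator of the established
  reference implementation; the two agree closely at realistic gene counts
  but are not identical.
- The hypergeometric enrichment needs an explicit universe; the default
  (union of pathway genes) is conservative when the measured platform is
  much larger than the annotated set.
- Crosstalk p-values are per-pair and uncorrected; stage-resolved tables over
  many pairs should be read as screening output.
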