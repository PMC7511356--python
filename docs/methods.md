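# Methods

This note documents the models, parameter choices and numerical
conventions behind `ripcpe`, in the order the pipeline runs them.

## Binder calling: the NB enrichment model

Counts for transcript *t* in sample *s* are modelled as negative binomial
with mean `μ_ts = f_s · q_tg(s)` and variance `μ + α_t μ²`, where `f_s` is
a per-sample size factor, `q_tg` a per-group (IP or control) abundance and
`α_t` the per-transcript dispersion.

**Size factors** use the median-of-ratios method: `f_s = median_t
(K_ts / geomean_s K_ts)` over transcripts with nonzero counts in every
sample, rescaled to geometric mean 1. When no transcript is nonzero
everywhere (very sparse matrices) the factors fall back to column totals
under the same rescaling. Scaling one sample's counts by *k* scales its
relative factor by *k* and leaves the fold-change estimates invariant.

**Dispersion** is estimated per transcript by the method of moments on
normalized counts, `α̂ = (s² − m̄)/m̄²` with within-group means and
variances pooled across the two groups by degrees of freedom, floored at
`α_floor = 1e-8` (numerical stability of the variance formula; transcripts
with zero mean get the floor and are untestable). With only a few
replicates per group this raw estimator is extremely noisy and its
downward errors are consequential: transcripts whose dispersion happens to
be underestimated get overstated Wald statistics, and in simulation at
3 vs 3 replicates roughly 12% of null transcripts fall below p = 0.05.
The estimator is therefore *moderated* by default: each `α̂_t` is raised
to at least the across-transcript median `α̂`. This one-sided floor — no
estimate is ever shrunk downward — restores calibration (≈5% of null
transcripts below p = 0.05) while leaving genuinely high dispersions
untouched. It is deliberately simpler than the empirical-Bayes shrinkage
used by full differential-expression tools; replicating those numerics is
a non-goal.

**The test** is a Wald test on the log₂ ratio of group means of normalized
counts with pseudocount c = 0.5 on each mean (bounded log-ratios for
sparse transcripts): `log2fc = log2((m_IP + c)/(m_ctrl + c))`. The
standard error comes from the delta method with the NB variance of each
group mean, `Var(m_g) = n_g⁻² Σ_s (m_g/f_s + α m_g²)`, and the two-sided
p-value from the standard normal. All-zero transcripts are emitted with
p = NA (log2fc = 0 by convention) and excluded from the FDR batch.

**Multiple testing** uses Benjamini–Hochberg step-up on the non-NA
p-values. **Binder rule**: `log2(IP/control) > lfc_min` and `q < fdr_max`,
defaults 0 and 0.01; both are flags, so a nominal-p rule (e.g. p < 0.05)
is reachable. The denominator group is whatever the sample sheet labels
`control` — the statistics are identical whether the practical control is
an IgG pulldown or input RNA.

## Motif scanning

The four element classes are literal RNA pattern sets: CPEC
{UUUUAU, UUUUAAU} (the `UUUUA(1–2)U` consensus read as one or two A's —
the conventional reading of the repeat notation), CPENC {UUUUAAAU,
UUUUACU, UUUUCAU}, Hex {AAUAAA, AUUAAA}, PBE {UGUAAAUA, UGUAUAUA}.
Sequences are normalized to uppercase RNA (T→U); characters outside
{A,C,G,U} are preserved and can never match.

A class's count is the number of *distinct 1-based start positions* at
which at least one of its patterns matches. Overlapping matches at
different starts all count; two patterns of the same class sharing a start
count once; classes are counted independently, so Hex or PBE may overlap a
CPEC. Scanning is sense-strand only (CPEs are defined on the mRNA).
Per-kilobase density is `count × 1000 / UTR length`; zero-length UTRs are
an error, zero-count transcripts are included in density comparisons.

Position maps list every match `(class, start, end, pattern)` in 1-based
inclusive coordinates; clusters are maximal runs of pooled matches whose
consecutive starts differ by ≤ `cluster_gap` (default 400 nt, chosen to
merge locally co-occurring elements while splitting clusters separated on
the multi-hundred-nucleotide scale; configurable). BED output converts to
0-based half-open per the BED standard.

## Binder vs non-binder statistics

For each class, transcripts are cross-tabulated as binder/non-binder ×
(count > k)/(count ≤ k), with k = 3 by default and strict inequality,
per class rather than on combined totals. Fisher's exact test uses the
minimum-likelihood two-sided rule (the sum over tables with the observed
margins whose hypergeometric probability does not exceed the observed
table's); this convention is stated because the alternative
(tail-doubling) disagrees on asymmetric tables. The reported odds ratio is
the sample ratio ad/bc, infinite when bc = 0 with ad > 0 and 1 when both
cross-products vanish.

Density (CPEC, CPENC) and UTR-length contrasts use the Mann–Whitney
rank-sum test with midranks for ties: exact null enumeration when the
pooled sample size is ≤ 12 with no ties, otherwise the normal
approximation with tie and continuity corrections (exact where cheaply
enumerable, standard elsewhere; the two agree to < 0.01 absolute p at the
switch point).

## The binder score

A deliberately simple operationalization of the observation that UTR
length and CPE abundance predict binding: logistic regression of the
binder flag on log₁₀ UTR length and the four per-kb densities, fitted by
minimizing the *mean* log-loss plus an L2 penalty (λ = 1e-4) on the
standardized-scale coefficients with L-BFGS. Using the mean (not the sum)
makes the fit invariant to duplicating records; the penalty makes it
deterministic and immune to perfect separation; constant features are
dropped with a warning. Held-out probabilities come from deterministic
round-robin 5-fold splits; coefficients are reported back on the raw
feature scale. The score is an explicit extension of the comparative
statistics, off by default (`--score`).

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis assumes,
with ground truth for every claim the tests make:

- **Counts**: per-transcript expression log-normal(0, 1) normalized to
  `depth` expected reads per library (default 2×10⁶); NB sampling with
  `var = μ + αμ²` (default α = 0.1, Poisson at α = 0); IP means multiplied
  by `ip_fold_change` (default 4) for the binder subset (default 10%);
  per-sample log-normal library-size jitter (sd 0.15). Default design
  3 IP vs 3 control replicates — a realistic minimal replicated design.
- **UTRs**: lengths log-normal per label group, floored at 50 nt to avoid
  degenerate per-kb densities; defaults give non-binder median ≈ 800 nt
  and binder median ≈ 1200 nt (1.5×), matching the qualitative
  longer-UTR structure of CPEB-bound target sets. Background bases are
  i.i.d. AU-rich (A 0.30, C 0.20, G 0.20, U 0.30), typical of mammalian
  3′-UTRs. Motifs are planted as literal in-place substitutions at uniform
  positions at a per-kb Poisson rate per class (binders 2× the non-binder
  rate by default), never overwriting a previously planted motif (up to
  100 placement retries, then skip with a warning). Planted counts are a
  lower bound on scanned counts, because the background — especially an
  AU-rich one — also spells motifs by chance.
- **Determinism**: each generator call consumes one documented random
  stream keyed on (seed, stream index); identical configuration and seed
  reproduce outputs byte for byte.

Not emulated: read-level artifacts (alignment, GC bias, positional
coverage), batch effects, correlated expression, secondary structure, and
any dependence of binding on sequence context beyond the planted motif
densities. Passing tests therefore demonstrate that the pipeline's
statistics behave correctly under the assumed generative model — not that
any particular biological dataset satisfies those assumptions.

## Problem sizes and conditions used by the checks

The packaged checks run at 5,000 transcripts (3 vs 3, depth 2×10⁶) for
calibration and recovery — 10 seeds each — and 2,000 transcripts × 100
seeds for the qualitative binder-contrast reproduction; the motif scanner
is verified against a brute-force oracle on 1,000 random sequences up to
5,000 nt. These sizes give stable statistics while keeping a full run in
minutes on one CPU.

## Known limitations

- The Wald test with moderated moment dispersions is conservative for
  transcripts whose true dispersion is far below the matrix median, and
  has no shrinkage toward a mean-dispersion trend; with many replicates
  a GLM-based test would be more efficient.
- Fisher p-values are taken from scipy's implementation of the
  minimum-likelihood rule; probability ties are resolved with a small
  relative tolerance there, which for pathological margins could in
  principle differ from exact rational arithmetic (the test suite checks
  agreement to 1e-12 across random margins).
- The pipeline handles exactly two groups (IP vs control); paired or
  multi-factor designs are out of scope.
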