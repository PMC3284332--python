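# Methods

## Study design and data model

The package models a whole-chromosome recombination survey in which a
female-meiosis product is transmitted hemizygously, so each genotyped
marker reads the parental haplotype directly.  A dataset is a marker map
(positions plus the two parental alleles) and, per progeny, a vector of
calls in {P1, P2, missing}.  Crossovers (COs) are switches between long
parental blocks; noncrossover gene conversions (GCs) are short embedded
tracts of the opposite parent.

## Synthetic meiosis

`meiorec.simulate` generates ground-truth chromatids and degraded
observations.  Defaults define the reference study conditions:

| parameter | default | rationale |
|---|---|---|
| `n_progeny` | 30 | survey size of the reference dataset |
| chromosome length | 22,400,000 bp | X-arm scale |
| markers | 93,538 | reference marker density (~1/240 bp) |
| map `clustering` | 6.0 | gamma-weighted inter-marker gaps; calibrated so that, at the default call rate, roughly 40% of conversion tracts cover ≥ 2 called markers — the detectability regime of the reference survey |
| `co_count_probs` | (0.4, 0.5, 0.1) | per-chromatid CO count distribution (mean 0.7 ≈ 0.5 per arm per chromatid scaled to survey yield) |
| CO density | 90% of mass on the distal 2/3 | strong distal bias of exchange |
| interference | 4 Mb minimum separation | double COs only far apart |
| `nco_dsb_rate` λ | 1.8 × 10⁻⁸ /bp/chromatid | reference ML estimate |
| `tract_p` | 1/239 | geometric cessation; one-sided mean 238 bp |
| `call_rate` | 0.7 | fraction of markers confidently called |
| `false_call_rate` | 1.2 × 10⁻⁵ | rare isolated miscalls |

Each GC event is a DSB at a uniform position whose tract extends
`Geometric(p) − 1` nucleotides independently left and right (the DSB site
itself is converted).  Observation degrades truth by independent marker
dropout and allele flips.  All randomness derives from
`default_rng([seed, chromatid_index])` substreams, so any chromatid is
reproducible in isolation.

## Event detection

Called markers are segmented into maximal same-parent runs.  A short
internal run (extent ≤ `max_gc_extent` = 10 kb) flanked on both sides by
runs of the other parent is a conversion candidate; it is confident when
it has at least `min_gc_markers` (default 2) converted markers, and
low-confidence otherwise — isolated single-marker switches are mostly
miscalls at the default false-call rate.  Remaining run boundaries are
crossovers.  Tract statistics follow the marker geometry: the *minimum
tract* spans the outermost converted markers, the *maximum tract* the
innermost nonconverted flanks.  Inter-marker distances within unconverted
stretches are tallied (up to b = 10,000 bp) into the span histogram: the
counts `N_a` of spans of length `a` with no observed conversion, the
likelihood's "no-event" observation class.

## Likelihood

For a span of length *i* with marker at each end, with q = 1 − p, the
probability that no conversion is observed (no DSB, or one DSB whose
tract touches neither flanking marker; at most one DSB per span — the
one-DSB truncation) is

P_no(i) = e^{−iλ} (1 + λ S(i)),  S(i) = i − 2q(1 − qⁱ)/p + i q^{i+1},

where S(i) is the closed form of Σ_k (1 − q^k)(1 − q^{i−k+1}).  An
observed conformation — span *i* with first/last converted markers at
offsets f and i − r — has probability

p_gc = λ e^{−iλ} Σ_{k=1..i} (q^{max(0,k−f)} − q^k)(q^{max(0,d−k)} − q^{i−k+1}),  d = i − r,

i.e. one DSB at ordinate k whose left extension reaches f but not the
distal flank, and whose right extension reaches d but not the proximal
flank.  The log-likelihood is Σ_a N_a ln P_no(a) + Σ_events ln p_gc.

**Fitting.**  A 60 × 60 log-spaced grid over λ ∈ [10⁻¹⁰, 10⁻⁶] and
p ∈ [10⁻⁴, 1] locates the optimum; Nelder–Mead on (ln λ, ln p) refines it
(skipped when there are no conformations, where the likelihood is
monotone in λ).  Profile-style intervals are the parameter values where
the log-likelihood falls 2 units below the maximum with the other
parameter held at its MLE, found by geometric bracketing and bisection;
the tract interval is reported on the one-sided-mean scale (1 − p)/p.
The likelihood-ratio test pins λ so that 4 × λ × genome length equals a
hypothesised genome-wide event total minus the observed CO count, leaves
p free, and refers 2ΔlnL to χ²₁.

**Derived rates** from (λ, p): one-sided mean tract (1 − p)/p, total mean
tract 2(1 − p)/p, per-bp conversion rate λ × total mean tract, per-arm
rate λ × 22.4 Mb, per-haploid-genome rate λ × 119 Mb, per-meiosis rate
4 × that, and the GC:CO ratio against 5 COs per meiosis.

## Resampling tests

- **Clustering null**: place n = 15 uniform integer coordinates on a
  14-Mb arm, take the minimum adjacent distance, repeat 10,000 times; the
  fraction ≤ 25 kb matches the closed form 1 − (1 − (n−1)d/L)ⁿ ≈ 0.316.
- **Annotation placement null**: re-place the observed span lengths
  uniformly on the chromosome and recompute the exonic overlap fraction,
  giving an empirical P with the (r + 1)/(n + 1) estimator.
- **Word-count Fisher test**: counts of a length-w word in two sequence
  pools are compared in a 2 × 2 table whose position totals are the
  nonoverlapping word positions ⌊length/w⌋; `alternative` selects the
  sidedness.

## Motif statistics

Word counts are overlapping exact matches (optionally both strands; a
palindrome then counts twice by construction).  O/E ratios divide by the
composition expectation (pooled or per-region base frequencies).  PWM
scanning scores log₂ odds against the background at every offset/strand;
exact p-values come from a dynamic-programming convolution of the score
distribution discretized at 1e-4 granularity with floor rounding, which
can only overstate (never understate) a reported p-value.  Matches are
kept when p × width ≤ 0.001 (the inverse direction is available as a
compatibility option).  Flank-versus-span enrichment uses two-sided
Fisher tests on nonoverlapping positions with Benjamini–Hochberg
correction within each flank width.  Metamotifs are connected components
of the motif-similarity graph with edges where p × alignment length
≤ 0.001, reported largest first with a per-component tally of distinct
discovery runs.  MEME-minimal text and TSV similarity tables are the
interchange formats; motif discovery and alignment themselves are
upstream tools, not reimplemented.

## Numerical choices

- All grids and profile searches work in log-parameter space; the span
  kernel S(i) uses the closed form (O(1) per span, stable for small p).
- PWM probabilities get a 10⁻⁶ pseudocount before log-odds.
- Writer/reader round trips are exact for every format; event tables are
  insensitive to input row order.
- Every stochastic routine takes an explicit seed; derived substreams use
  `SeedSequence`-style spawning, never global state.

## Limitations

- **One-DSB truncation.**  The per-span outcome probabilities do not sum
  to the two-term Poisson mass e^{−iλ}(1 + iλ): summing the conformation
  probabilities over all observable conformations recovers λe^{−iλ}S(i)
  exactly (the tract-avoidance kernel), not λe^{−iλ}·i.  The gap is the
  probability that a single DSB's tract converts a flanking marker of the
  span — an outcome the span bookkeeping assigns to a *different*
  (longer) observed span.  A test in `tests/test_acceptance.py` asserts
  the literal two-term identity and fails by design; the exact partition
  identity is asserted in `tests/test_mle.py`.
- **Word-test sidedness.**  On the packaged core-word counts (25 hits in
  12,925 bp of CO spans vs 7 in 8,151 bp of GC tracts) the two-sided
  Fisher P is 0.066; only the one-sided ("CO-enriched") P = 0.034 is
  below 0.05.  The corresponding acceptance test asserts the two-sided
  convention and fails by design; both values are computed in
  `tests/test_resampling.py` and `analysis/05_motif_words.py`.
- **Clustering-null mean.**  The expected minimum adjacent distance for
  n uniform points on length L is L/((n−1)(n+1)), i.e. 62.5 kb for
  n = 15 on 14 Mb; quoting "~65 kb" overstates it slightly.  The
  Monte-Carlo mean is tested against the exact value.
- **Detection sensitivity.**  At the default call rate only ~30–40% of
  true conversion tracts are confidently detected end to end (the
  acceptance suite measures ~31% over 2,000 chromatids), so fitted rates
  use the confident events and the no-event spans; single-marker
  detection (`min_gc_markers=1`) is appropriate only for noise-free
  data — at the default miscall rate it admits roughly one spurious
  single-marker "conversion" per chromatid.
- The likelihood conditions on the realized marker spacing and assumes
  at most one DSB per inter-marker span; both are excellent
  approximations at λ ≈ 10⁻⁸ but degrade for λ orders of magnitude
  larger.
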