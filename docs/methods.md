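# Methods

## The entropy model

A mature miRNA's isomiR population is summarized by the mean per-site
Shannon entropy of its aligned read stack. At precursor position *i*, the
observed distribution runs over five symbols — A, U, G, C and the gap
character `-` — where a read contributes its base when it covers the site
and a gap otherwise, weighted by its abundance count. With `p_j(i)` the
frequency of symbol *j* at site *i* (denominator = total read count, which
is the same at every site by the gap convention):

    MIH  = -(1/L)  Σ_i Σ_j p_j(i) log2 p_j(i)

The full window is the canonical mature region ± 4 nt (`L = mature
length + 8`); MIH5 and MIH3 restrict the average to the 9 positions
centered on the canonical 5' and 3' ends. Values live in
`[0, log2 5 ≈ 2.32]` bits/site; in practice end-wobble of a few nt keeps
them well below 1.

Assumptions baked into the model:

* **Reads are gapless placements.** A read occupies a contiguous interval
  on the precursor; there is no indel-aware realignment. Substitutions
  need no special handling — a mismatched base simply shifts the site
  distribution.
* **Counts weight reads.** A read of count *c* contributes *c* times.
  Unit-weighting unique sequences would discard all expression structure;
  entropy is invariant to splitting a read's count or scaling all counts.
* **Gap pooling.** Non-coverage and N bases both land in the fifth
  symbol. No pseudocounts anywhere.
* **Window clipping.** When a mature sits within 4 nt of a precursor
  end, the window is truncated at the precursor boundary and the
  *effective* L divides the sum (averaging over nonexistent sites would
  deflate the score); the result carries a `clipped` warning. Bases of
  reads overhanging the precursor 3' end (non-templated tails) fall
  outside every window for the same reason.

## Cohort assembly

A read is assigned to a mature miRNA when **both** of its ends fall
within ± 4 nt of the canonical ends — the same ± 4 nt notion the entropy
window uses. This keeps reads of the opposite arm (which would flood the
window with gaps) out of the stack, and makes the depth filter
per-mature: a mature enters the cohort only when its own substack holds
strictly more than `min_count = 50` and strictly fewer than
`max_count = 10000` reads. The lower bound guards against systematic
underestimation of heterogeneity at low depth, the upper against PCR
amplification bias; both are CLI-tunable (`--min-count/--max-count`) and
always strict.

Arm identity comes from the mature name alone: a terminal `-5p`/`-3p`
(or `.5p`/`.3p`, case-insensitive) token maps to an arm, anything else is
"single". No coordinate-based inference is attempted for suffix-less
names. Arm pairing emits one pair per precursor with exactly one 5p and
one 3p result; the pair's high/low MIH assignment breaks ties by setting
both to the common value.

## Statistics

* **KS test** (arm classes vs single-arm): the statistic is the supremum
  of the absolute ECDF difference over all observed points; the two-sided
  p comes from the classical limiting Kolmogorov series evaluated at
  `sqrt(n1·n2/(n1+n2))·D`. The statistic, not the p, is the
  enumeration-tested quantity.
* **Wilcoxon signed-rank** (MIH5 and MIH3 between paired arms):
  zero differences dropped, midranks under ties, statistic
  `min(W+, W−)`. Up to 25 effective pairs the two-sided p is exact — the
  full distribution of W+ over all 2^n sign patterns, computed by
  subset-sum convolution over doubled midranks, with the smaller tail
  doubled and capped at 1. Beyond 25 a normal approximation with
  continuity correction and tie-corrected variance takes over. This is
  implemented in-package because library routines decline exact p-values
  in the presence of ties.
* **Pearson correlation** panels: product-moment r with the t-transform
  p (needs ≥ 3 pairs and nonzero variance; otherwise the report row is
  marked skipped rather than dropped).
* **Enrichment**: rank the cohort by one entropy key, keep the top
  `ceil(fraction·n)` (default fraction 0.15; ties at the cutoff are
  included), collapse matures to unique precursors, and test each
  annotation term by the one-sided hypergeometric upper tail against the
  reference universe of all precursors in the cohort, after intersecting
  each term with that universe. Benjamini-Hochberg FDR runs across all
  tested terms; rows are flagged significant at p < alpha (default 0.05).

## The generative model and its oracle

`simulate_stack` draws `depth` reads i.i.d.: the 5' start offset from a
categorical distribution `q5` over −4..+4, the 3' end offset from `q3`,
then substitutes each templated base independently with probability
`sub_rate` (uniform over the three alternatives). One seeded generator
drives all draws in a fixed order (all starts, all ends, then
substitutions read by read), so stacks and fixture files are byte-stable
under a fixed seed. Offsets that would push a read outside the precursor
or below 10 nt are rejected at configuration time.

Because end offsets are the only source of coverage variation, the
end-window entropies have a closed form in the infinite-depth limit: at
position *p* relative to the canonical 5' end, the coverage probability
is the left tail `c_p = Σ_{o≤p} q5(o)`, the site distribution is
`{gap: 1−c_p, template base: c_p(1−s), each alternative: c_p·s/3}`, and
`expected_mih5` is the mean of the 9 site entropies (mirrored right tail
for `expected_mih3`). Parameter-recovery tests check that deep simulated
stacks (depth 10^5) reproduce this limit within 0.01 bits/site across a
grid of offset distributions × substitution rates, and that the deviation
shrinks monotonically in median over seeds as depth grows 10^2 → 10^4 →
10^5.

### Fixture cohorts

`generate_fixture_dataset` writes a complete synthetic cohort (precursor
FASTA, mature annotations, read-stack TSV, MFE TSV, synthetic annotation
sets). Its defaults are fixed study conditions chosen to mirror the scale
and structure of the pooled public data this metric targets:

* 65% of precursors express a single arm, 35% both arms (a 545-precursor
  cohort yields ≈ 736 matures, the published cohort's shape);
* per-mature depth: 80% log-uniform on (60, 9000), 10% at 10–50 and 10%
  at 10000–20000, so the strict depth filter visibly acts on both sides;
* cleavage-offset spread: exponential-decay offset distributions over
  −2..+2, with two-arm products drawing broader spreads (scale
  0.6–1.6) than single-arm products (0.2–0.8) — encoding the qualitative
  finding that two-arm miRNAs are the more heterogeneous class;
* substitution rate 0.005 per base;
* MFE drawn from N(−30, 8) kcal/mol (clipped at −1), independent of the
  entropy parameters.

What the generator does **not** emulate: correlation of MFE or precursor
length with heterogeneity (real hairpins fold; synthetic energies are
independent draws, so the corresponding correlation panels hover near 0),
position-dependent error profiles, PCR duplication structure beyond the
depth cap, and non-templated tailing beyond the precursor (the simulator
keeps reads templated; the parsers and entropy engine do accept
overhanging reads). Passing tests therefore demonstrate correctness of
the computation and calibration of the generative model — not biological
conclusions about real cohorts.

## Numerical choices

* log base 2 throughout; `0·log2 0 = 0`.
* Entropy columns are computed from exact integer tallies; the
  brute-force comparison tolerance is 1e-12.
* Entropy tables render floats to 6 decimals (round-trip stable to the
  4-decimal contract).
* Exact Wilcoxon enumeration switches to the normal approximation above
  25 effective pairs (2·10^7 sign patterns would still be enumerable via
  the convolution, but the approximation error is already negligible).
* Degenerate inputs (all-zero differences, zero variance, empty samples)
  raise typed errors; the pipeline's report converts them to `skipped`
  rows so one bad comparison never kills a run.

## Problem sizes

The test suite runs the entropy oracle on 200 random ≤ 6-read stacks over
≤ 40-nt precursors, KS/Wilcoxon/hypergeometric enumeration oracles at
n ≤ 6 / n ≤ 8 / universe ≤ 12, and recovery at depth 10^5 over a 6-point
parameter grid; the acceptance script simulates one 545-precursor cohort.
These sizes keep the whole suite under a minute while every check is
exhaustive or oracle-backed at its scale.

## Known limitations

* The miRBase-style alignment-block parser is best-effort: the upstream
  dialect is not formally specified, so it accepts both `-` and `.`
  fillers and takes the last whitespace token as the count.
* Arm classification trusts names; coordinate-based arm inference is out
  of scope.
* No entropy confidence intervals; depth-dependent bias at the low end is
  handled by the inclusion filter, not modeled.
* MFE is an input column passed through to the correlation panels; the
  package never folds RNA.
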