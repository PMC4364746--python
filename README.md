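# mirentropy

Shannon-entropy profiling of miRNA isoform (isomiR) heterogeneity from
aligned small-RNA read stacks.

## The problem

Drosha and Dicer do not cut a pre-miRNA hairpin at exactly the same
position in every molecule. High-throughput small-RNA sequencing therefore
shows, for each mature miRNA, a *stack* of near-identical reads whose 5'
and 3' ends wobble around the canonical cleavage sites (plus occasional
substitutions and non-templated tail bases). `mirentropy` quantifies how
heterogeneous that isomiR population is, for researchers studying
processing fidelity, arm selection, or the functional role of isomiRs.

## The metric

For one mature miRNA, align its reads on the precursor and consider the
canonical mature region extended by 4 nt on each side. At every site *i*
in that window, each read contributes its base when it covers the site and
the gap character `-` when it does not, giving an observed frequency
`p_j(i)` over the 5-symbol alphabet {A, U, G, C, -}. The isoform entropy
is the mean per-site Shannon entropy in bits:

    MIH = -(1/L) * sum_i sum_j  p_j(i) * log2 p_j(i)

with `L = mature length + 8`. **MIH5** and **MIH3** apply the same average
to the 9 positions centered on the canonical 5' and 3' ends (`L = 9`),
isolating 5'-end (Drosha- or Dicer-side) from 3'-end heterogeneity.
Counts weight reads by abundance; MIH = 0 means a single dominant isoform,
larger values mean blurrier processing (the ceiling is log2 5 ≈ 2.32).

Around the metric the package provides the standard analysis chain:
a strict per-miRNA depth filter (more than 50 and fewer than 10000 reads),
5p/3p/single-arm classification from mature names, two-sample KS
comparison of arm classes, paired Wilcoxon signed-rank tests between arms
(exact under ties up to n = 25), Pearson correlation panels (entropy vs
precursor length, folding energy, depth, and between arms), and
hypergeometric set enrichment of top-entropy precursors with
Benjamini-Hochberg FDR. A seeded generative model (categorical cleavage-
offset distributions ± uniform substitution noise) produces synthetic
cohorts and has a closed-form infinite-depth entropy limit used as a
recovery oracle.

## Worked example

Simulate a 12-precursor cohort, compute the entropy table, and run the
comparison battery:

```sh
mirentropy simulate --n 12 --seed 42 --out demo
mirentropy compute --precursors demo/precursors.fasta \
    --annotations demo/matures.tsv --stacks demo/stacks.tsv \
    --mfe demo/mfe.tsv --out demo/entropy.tsv
mirentropy stats --entropy demo/entropy.tsv --out demo/stats.tsv
```

`compute` reports `16 matures retained (2 filtered, 0 without reads)` —
two matures fell outside the strict (50, 10000) depth band. The first
rows of `demo/entropy.tsv`:

```
mature_name   precursor_id  arm     total_count  MIH       MIH5      MIH3
sim-miR-1     sim-mir-1     single  187          0.068324  0.080575  0.079818
sim-miR-2     sim-mir-2     single  607          0.055514  0.050154  0.067292
sim-miR-3-3p  sim-mir-3     3p      701          0.184649  0.319180  0.238307
```

`sim-miR-2` is nearly homogeneous (MIH ≈ 0.06: one isoform dominates),
while `sim-miR-3-3p` wobbles at both ends (MIH5 ≈ 0.32). The report in
`demo/stats.tsv` starts:

```
comparison              statistic_name  statistic  p_value     n   status
ks_mih_arms_vs_single   ks_d            1          0.00110617  16  ok
wilcoxon_mih5_5p_vs_3p  wilcoxon_w      4          0.875       4   ok
```

— in this toy cohort the two-arm miRNAs are uniformly more heterogeneous
than the single-arm ones (KS d = 1), matching how the generator was
configured. `mirentropy enrich` then tests whether the top-15% MIH5
precursors concentrate in annotated function terms, and `mirentropy
run-all --config run.yaml` chains all three steps.

The same operations are importable (`mirentropy.compute_mih`,
`mirentropy.ks_two_sample`, ...) for scripted analyses.

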