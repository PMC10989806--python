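# reporterscore

Reporter-score pathway enrichment for microbiome functional profiles —
with the statistically correct, **undirected** interpretation built in.

## The problem

Metagenome functional profiles are usually summarized as KEGG orthology
(KO) abundances per sample. To ask "which pathways respond to a condition",
a popular approach aggregates per-KO differential-test P values into a
per-pathway *reporter score*:

1. Per-KO inverse-normal transform:  `Z_i = Φ⁻¹(1 − P_i)`
2. Size-independent pathway aggregate over its k member KOs:
   `Z_pathway = (1/√k) · Σ Z_i`
3. Background correction against random KO sets of the same size:
   `Z_corrected = (Z_pathway − μ_k) / σ_k`

where μ_k and σ_k are the mean and standard deviation of the aggregate over
random size-k subsets of the tested KO universe (enumerated exhaustively
when C(n, k) is small, seeded Monte Carlo otherwise). A pathway with
`Z_corrected > 1.64` is enriched at the one-sided P = 0.05 level.

**The score carries no direction.** `Φ⁻¹(1 − P)` is negative exactly when
P > 0.5 — i.e. when a KO shows *no* differential signal. A strongly
negative reporter score therefore means "members less significant than a
random set", never "downregulated". Reading the sign as a regulation
direction is a widespread misinterpretation; this package's scoring,
output flags, simulators, and docs are all built to make that mistake hard
to commit. For direction-aware results it implements the directed
(Reporter-Feature-style) complement: each KO's two-sided P is split into
one-tailed `p_up = P/2` (statistic > 0, else `1 − P/2`) and
`p_down = 1 − p_up`, and the up/down aggregates are scored separately.

A hypergeometric over-representation test (ORA) over the same universe is
included as the classical comparator.

## Worked example

Generate the built-in demonstration dataset — 200 KOs with uniform P
values (exactly 50 below 0.05), 10 pathways with consistent within-pathway
direction, and one pathway (`pathway_04`) deliberately assembled from the
*least* significant KOs, all "upregulated" — then score it:

```bash
reporterscore simulate --replica --seed 1 --out demo/
reporterscore compare --stats demo/ko_stats.tsv --sets demo/pathways.gmt \
    --seed 7 --out demo/
```

`demo/reporter_results.tsv` (abridged):

```
pathway      mode        k   z_pathway  mu_k      sigma_k   reporter_score  p_equiv   significant
pathway_08   undirected  24  2.877395   2.125589  1.152920  0.652088        0.257172  False
pathway_09   undirected  14  2.323011   1.575671  1.219389  0.612881        0.269978  False
...
pathway_02   undirected  28  -0.258015  2.340377  1.169865  -2.221105       0.986828  False
pathway_04   undirected  29  -7.822882  2.283254  1.163581  -8.685375       1.000000  False
```

`pathway_04` has a reporter score of −8.69 even though every one of its
members is "upregulated": the naive |score| > 1.64 reading would call it a
significantly *downregulated* pathway. The ORA table shows what is really
going on — none of its 29 members reaches P < 0.05:

```
pathway      k   n_sig  overlap  p_hyper
pathway_07   19  50     6        0.327087
...
pathway_04   29  50     0        1.000000
```

The score is low because the pathway contains no signal, not because it
points "down". Flipping the sign of every KO statistic reproduces the
undirected table bit for bit.

For abundance-level input, `reporterscore run --abundance table.tsv
--metadata meta.tsv --reference control --sets pathways.gmt --out out/`
runs the per-KO tests (Welch's t by default; `--method student_t`,
`--method wilcoxon`, optional `--log`) before scoring; `--mode directed`
emits separate up/down rows per pathway.

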