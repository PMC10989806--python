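# Methods

## Model and procedure

The toolkit scores gene sets (KEGG pathways or modules, represented as sets
of KO identifiers) against a universe of per-KO two-group test results.

**Per-KO statistics** (`diffstats`). For a KO × sample abundance table and
a two-group assignment, each feature is tested with Student's t (pooled
variance), Welch's t (default), or the two-sample Wilcoxon rank-sum test.
P values are two-sided; the signed statistic is positive when the
treatment group's location exceeds the reference group's. The Wilcoxon
variant uses exact enumeration when both groups have ≤ 20 samples and the
pooled data are tie-free, and otherwise the normal approximation with tie
correction; the continuity correction is disabled so a perfectly balanced
tied configuration yields p = 1 exactly. Features that are constant in
both groups get p = 1 / statistic = 0 with a logged warning rather than an
exception (a single flat KO must not abort a run) — this applies even when
the two constants differ, where a t statistic would be ±∞. P values are
never truncated at this stage.

**Reporter score** (`reporter`). With per-KO P values `P_i`:

- `Z_i = Φ⁻¹(1 − P_i)`, with P clipped into `[1e−15, 1 − 1e−15]` so p = 0
  or 1 maps to a large finite Z rather than ±∞;
- `Z_pathway = (1/√k) Σ Z_i` over the k members present in the universe.
  The `1/√k` normalization is the variance-stabilizing ("size-independent")
  form: under the null each `Z_i` is standard normal, so `Z_pathway` is
  standard normal for every k. A plain `1/k` average would shrink with k
  and is not size-independent; this rendering ambiguity is resolved in
  favour of `1/√k` and flagged here deliberately;
- `Z_corrected = (Z_pathway − μ_k)/σ_k`, where μ_k and σ_k are the mean
  and *population* (divide-by-n) standard deviation of the aggregate over
  random size-k subsets of the full scored universe. The population/sample
  SD distinction is negligible at the default sampling depth but is fixed
  for bit-reproducibility.

The equivalent one-sided P value is `1 − Φ(Z_corrected)`; rows carry a
Benjamini–Hochberg q value across pathways of the same mode, and a
`significant` flag at the configurable cutoff (default 1.64 ≈ one-sided
P = 0.05). The flag compares the score itself, never its absolute value:
**a negative reporter score is evidence of nothing, not of
downregulation** — the central interpretation rule this package exists to
enforce.

**Background estimation.** When `C(n, k) ≤ 100,000` all subsets are
enumerated; otherwise `n_background` subsets (default 1,000; the original
description says only "several sets") are drawn uniformly without
replacement within each subset from a single seeded generator. Draws are
made in sorted-k order so results do not depend on pathway input order.
Subsets come from the full universe, not from non-pathway KOs, mirroring
random selection from the whole metabolic graph.

**Directed complement.** Each KO's two-sided P is split by the sign s of
its statistic into `p_up = P/2` (s > 0) or `1 − P/2` (s < 0), with
`p_down = 1 − p_up` and (0.5, 0.5) when s = 0. The up and down P-value
universes are each pushed through the same transform/aggregate/correct
pipeline, giving two independently background-corrected rows per pathway.

**ORA comparator** (`ora`). Upper-tail hypergeometric test of the overlap
between each pathway and the set {KO : P < α} (α default 0.05), computed
by exact integer summation of binomial coefficients. The universe is the
set of *tested* KOs, identical to the reporter universe, so the two
methods are directly comparable. One-sided enrichment only; depletion is
out of scope.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `min_k` | 3 | pathways with fewer members in the universe are dropped; singletons make the background degenerate |
| `n_background` | 1000 | Monte-Carlo subsets per distinct k |
| `exhaustive_cap` | 100,000 | max subset count for exact enumeration |
| `cutoff` | 1.64 | one-sided score cutoff ≈ P = 0.05 |
| `alpha` | 0.05 | per-KO cutoff for ORA's significant list |
| `seed` | 0 (CLI) | one RNG stream per run; identical seed ⇒ identical output bytes |

## Synthetic data

`simulate_replica` emulates a minimal dataset that exposes the sign
misreading: 200 KOs whose P values are stratified-uniform (exactly 50
drawn from U(0, 0.05), 150 from U(0.05, 1) — the significant count is a
generator contract, not a random outcome), 10 pathways with sizes uniform
on [8, 30] sampled without replacement per pathway (pathways may overlap),
consistent within-pathway signs, and a designated pathway (the 4th by
convention) consisting of the k *largest* P values with every member
"upregulated". Signed statistics are reconstructed as
`sign · Φ⁻¹(P/2)`-magnitudes. A truth table records each pathway's
construction so downstream checks never re-derive ground truth. The size
range [8, 30] keeps backgrounds stable at n = 200; the reference
demonstration states only "a random number (k)".

Because pathways may overlap, a KO shared by two pathways of opposite sign
takes the sign of the later-constructed pathway; the designated
least-significant pathway is constructed last so its all-positive
guarantee always holds.

`simulate_abundance` produces log-normal abundances: per-feature log-mean
~ N(2, 1), within-feature log-SD 0.5, n_per_group default 10 — typical
magnitudes for relative functional profiles at modest cohort size. Effect
KOs get their treatment-group log-mean shifted by `effect_size` × 0.5
(i.e. effect_size within-feature SDs). What these simulators do *not*
emulate: compositionality and sequencing-depth variation, correlated KOs,
zero inflation, covariates. Passing tests therefore demonstrate the
statistical behaviour of the scoring machinery, not robustness to every
property of real metagenome data.

## Numerical conventions and degenerate inputs

- P-clip at 1e−15 before Φ⁻¹ (above); score→P uses the survival function
  directly. The Φ⁻¹(1 − Φ(z)) round trip is exact to ~1e−8 at |z| = 6,
  the double-precision limit of the 1 − Φ representation.
- σ_k below `1e−12 · max(1, |μ_k|)` is snapped to exactly 0 (float residue
  on constant universes).
- σ_k = 0 with the pathway aggregate exactly at μ_k (e.g. every P = 0.5)
  scores 0 — no deviation from background. σ_k = 0 with a deviating
  aggregate (reachable only through unlucky Monte-Carlo draws) yields a
  missing score plus a warning; never a crash or ±∞.
- Output rows are sorted by reporter score descending (missing last), ties
  broken by pathway id, so runs are diffable. Result TSVs are written at 6
  decimal places with a full-precision JSON sidecar; readers prefer the
  sidecar.
- Two-column KO→pathway mappings auto-detect an optional `ko	pathway`
  header; duplicate members and duplicate pairs are deduplicated with
  warnings; duplicate pathway names are an error.

## Problem sizes used in the test suite

Simulation-based checks run at deliberately desk-scale sizes chosen to
make the statistics decisive: null calibration uses 200 uniform P values ×
1,000 random size-10 pathways with 1,000 background sets; Monte-Carlo vs
exhaustive background agreement uses universes with ≤ 500 subsets and
20,000 draws (3-standard-error bands); parameter recovery runs 50
replicates of a 2-SD effect planted in a 20-KO pathway at n = 10 per
group, requiring the planted pathway to rank first in ≥ 95% of replicates.

## Known limitations

- No compositional normalization (CLR, rarefaction), covariate adjustment,
  or paired designs in `diffstats`; abundances are tested as given
  (optionally log(x+1)-transformed).
- No network-topology-aware scoring: pathways are plain sets, not
  neighbourhoods in a metabolic graph.
- The directed split assumes the per-KO test is symmetric enough that
  P/2 approximates the one-tailed P; for heavily skewed tests a native
  one-tailed test would be preferable.
- BH adjustment treats pathway scores as independent; overlapping pathways
  violate this, as they do in every standard enrichment tool.
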