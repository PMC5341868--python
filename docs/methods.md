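# Methods

`mirsynergy` re-implements, as a tested library, the computational arm of a
paired colorectal-cancer (CRC) miRNA study: differential miRNA calling on a
paired normal/adenoma/carcinoma design, target-set pathway enrichment,
miRNA–miRNA functional synergy networks with hub scoring, and 2×2
marker-positivity association statistics. A synthetic-data generator provides
every input with the statistical structure the analysis assumes, so the whole
pipeline is testable without downloads.

## Synthetic paired cohort

The generator emulates an 830-miRNA array over six tissue pairs per class.
Expression is generated directly on the log2 scale:

    x_ij = baseline_i + delta_i(class_j) + noise_sd * e_ij

* `baseline_i` ~ Uniform(4, 12) per miRNA — only relative expression matters
  on such arrays, so no intensity model is attempted.
* `delta` plants 40 up- and 8 down-regulated miRNAs at |log2FC| = 1.5 in
  carcinoma. Adenoma receives `adenoma_effect_fraction` (default 0.5) of the
  carcinoma effect, encoding partial ("initial") deregulation on the
  normal → adenoma → carcinoma axis; the fraction is configurable and is a
  declared convention, not an inference.
* `e_ij` ~ N(0, 1), with `noise_sd` = 0.3 per observation. `noise_sd = 0` is
  allowed as the noise-free limit, in which planted fold changes are
  reproduced to machine precision.
* miR-155 always fills the first up slot and miR-143/145/192/378 the first
  down slots, matching the direction each moves in carcinoma; remaining slots
  are drawn uniformly from the filler miRNAs.

**Sign-switching coupling.** miR-155 and the miR-143/145/192/378 group share a
single latent factor whose loading sign for miR-155 flips between normal and
tumour tissue, producing within-class correlations of −`corr_strength` with
each group member in normal samples and +`corr_strength` in adenoma and
carcinoma. `corr_strength` (default 0.8) is interpreted as the within-class
correlation magnitude itself. When a class has more samples than the
five coupled miRNAs, the draw is *empirically exact* in the
`mvrnorm(empirical = TRUE)` sense: the noise block is centred and whitened so
its sample correlation equals the target to machine precision. Two properties
motivated this choice over a plain stochastic factor:

1. with six samples per class, the sample correlation of a stochastic factor
   at ρ = 0.8 has an SD of roughly 0.15, so the planted coupling would miss
   the default correlation-network threshold (|r| ≥ 0.7) in about one run in
   five and could even flip sign at ρ = 0.6 — making the generator's
   advertised structure unrecoverable by the very stage it feeds;
2. centring keeps the latent factor out of paired class differences, so the
   coupled quintet is recovered by the differential stage at the same power
   as every other planted miRNA.

For fewer samples the generator falls back to a Cholesky draw.

One root seed derives named child streams (baselines, planted-set selection,
noise, latent block) via `SeedSequence` spawn keys, so adding a component
never perturbs earlier draws and equal seeds give bit-identical output.

**Power under the defaults.** The paired difference of a planted miRNA is
N(±1.5, 2·0.3²/6); the fold-change criterion |mean| ≥ 1 fails with
probability ≈ 0.002 per planted miRNA and the paired t-test at α = 0.05 has
power > 0.999, so the default profile recovers exactly 40 up / 8 down calls
at its seed (42) and at roughly 84 % of arbitrary seeds; the residual misses
are fold-change threshold noise, not test failures. Under a global null the
fold-change filter dominates: a null mean difference needs a ≈ 5.8 σ
excursion to reach |log2FC| ≥ 1, so the non-ns rate is far below 0.1 %.

**Annotations.** `simulate_annotations` wires miR-155 as a hub: each of
`n_partners` (default 8) partner miRNAs — the correlated group first — gets a
dedicated pathway whose full gene set is planted into both its own and
miR-155's target list. A full-overlap pathway of size ≥ 8 in a universe of a
few hundred genes is far below any Holm-corrected threshold, so each pair is
guaranteed a shared enriched pathway while partners share none among
themselves; infeasible size combinations raise instead of silently dropping
the guarantee. The TF table always contains SMAD3→miR-155, SMAD4→miR-155 and
CEBPB→miR-143 (the regulators reported for those host genes) plus an NF-κB
edge covering the quintet and random TF→miRNA pairs.

**Positivity generator.** `simulate_positivity` draws exposure ~
Bernoulli(`p_exposure`) and marker | exposure with
logit P = ±log(OR)/2 — a symmetric parameterisation whose conditional odds
ratio equals the request exactly and whose marker marginal is ½ at the null.
Inverting the OR is equivalent to swapping the marker rows, and flipping
`p_exposure` to the exposure columns.

## Differential calling

Per miRNA, the paired log2 differences (class b − class a, matched by pair
id) give the fold change as their *mean* (mean of paired log differences, not
log of mean ratio — a declared convention) and a two-sided paired t-test
p-value. A call requires both p < α (default 0.05, raw — the study design
states only "t-test, P < 0.05"; Holm and Benjamini–Hochberg are options) and
|log2FC| ≥ `fc_threshold` (default 1.0, a declared convention). Zero
within-pair variance leaves the t statistic undefined; an exactly repeated
non-zero shift is treated as certain (p = 0) and a zero shift as null
(p = 1), flagged `degenerate_variance`. Rows with missing paired values are
called `ns` and flagged.

## Enrichment statistics

* **Right-sided hypergeometric test.** P(X ≥ k) for X ~ Hypergeom(N, K, n) is
  summed in log space (log-gamma binomial terms with a max-shift), exact to
  well over 10 significant digits; the test oracle recomputes every tail as an
  exact rational with integer binomials.
* **Holm (Bonferroni step-down).** adj(i) = min(1, max_{j ≤ i} (m−j+1)·p(j))
  in ascending order, stable ties, mapped back to input order. The
  multiple-testing family is *the pathways within one miRNA's target set* —
  the analysis enriches each deregulated miRNA's target list separately — not
  the global miRNA × pathway grid; this is a declared convention.
* **Universe.** Defaults to the union of all pathway genes (overridable);
  target sets are intersected with it before testing, and miRNAs left with no
  targets are skipped with a warning.
* **Kappa grouping.** Cohen's kappa over the binary pathway-membership
  vectors on the universe; enriched pathways joined at κ ≥ 0.3 and grouped by
  connected components (single linkage — the simplest rule consistent with a
  "functionally grouped annotation network"). Each group's representative is
  its lowest-adjusted-p member, ties lexicographic. Both the kappa universe
  and the linkage rule are declared conventions.

## Synergy networks and hubs

Three undirected weighted graphs over miRNAs:

* **Pathway co-regulation** (primary): edge iff two miRNAs share ≥ 1
  *enriched* pathway; weight = number shared; evidence = pathway ids. The
  "shared enriched pathways" reading is used because edges represent
  co-regulated pathways; a raw shared-target variant
  (`target_synergy_network`) is available for the alternative reading.
* **Shared TF**: edge iff ≥ 1 TF regulates both; weight = number of shared
  TFs.
* **Co-expression**: within one tissue class, edge iff |r| ≥ `min_abs_r`
  (default 0.7, a declared convention; Pearson default, Spearman optional);
  weight = |r|, signed r kept as evidence. Zero-variance miRNAs are dropped
  with a warning; at six samples per class the null distribution of r is wide,
  so the default threshold admits a sizeable background of spurious edges —
  the planted quintet is distinguished by its exact ±0.8 coupling, not by
  being the only edges.

"Node size" is operationalised as the weighted degree (`hub_score`), the
minimal quantitative reading of a network figure's largest node; the
handshake identity Σ hub_score = 2 Σ weight is asserted at build time by
construction and in tests. Rankings sort by descending score, ties
lexicographic. Networks are deterministic functions of their inputs,
including serialization order (edge lists sort endpoints lexicographically).

## Association statistics

For a 2×2 table in the layout a = exposure+/marker+, b = −/+, c = +/−,
d = −/−: OR = ad/bc; Woolf log-normal CI
exp(log OR ± z·√(1/a+1/b+1/c+1/d)). The Woolf interval is the default
because it reproduces both published intervals from the published counts.
The Haldane–Anscombe +0.5 correction is applied to all cells only when a
zero cell exists, and the method field records it. The default test is
Fisher exact (two-sided, by summing margin-fixed tables no more probable
than the observed); chi-square with or without Yates correction is optional,
with a logged warning when any expected count is below 5. Percentages are
reported to two decimals of the cohort total.

## Pipeline

Stages (simulate → diff → enrich → network → hubs → assoc) communicate only
through files in a run directory; each stage validates that its upstream
outputs exist and logs its wall time and input SHA-256 prefixes. The
resolved configuration is written as a YAML sidecar; re-running an identical
configuration reproduces byte-identical outputs. The enrichment stage
restricts to miRNAs called up/down by the differential stage, mirroring the
"deregulated miRNAs and their verified targets" design. Configuration
validation collects *all* failures and suggests near-miss key names.

## Problem sizes in tests

The default profile (830 × 18) simulates in ~50 ms, so tests use it
directly. The hypergeometric exactness check sweeps every valid
(k, K, n, N) with N ≤ 40 (~2·10⁵ instances) against integer-rational
enumeration; network equivalence uses 50-miRNA random fixtures against an
O(M²·P) brute-force oracle; the positivity generator's odds-ratio
calibration averages 10 000 replicates at n = 78.

## What the synthetic data does and does not show

The generator reproduces the *design* of the study — paired classes, planted
effect sizes, a sign-switching coupling, hub-structured annotations — under
homoscedastic Gaussian log2 noise with no probe-level artifacts, no
normalization residue, no batch effects, no missingness and a single shared
latent factor. Passing tests therefore demonstrate that the statistics and
graph constructions are implemented correctly and recover planted structure
at the stated sizes; they do not validate array preprocessing, nor imply the
biological claims (SMAD signalling, immune evasion) that motivated the
original analysis.

## Known limitations

* No moderated-variance (empirical-Bayes) testing; at n = 6 pairs a
  per-miRNA t-test is noisy, which is faithful to the emulated analysis but
  not state of the art.
* The enrichment family convention (per miRNA) and the p ≤ 0.05 retention
  threshold are configurable but the global-grid alternative is not built in.
* The correlation network treats |r| symmetrically; no multiple-testing
  control is applied to its edges.
* GO-style term hierarchies, ClueGO file emission and graph layout are out
  of scope; networks are exported as GraphML/edge lists for external tools.
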