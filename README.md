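# mirsynergy

miRNA synergy-network analysis for paired colorectal tissue studies.

Colorectal tumours deregulate dozens of miRNAs at once, and single-miRNA
statistics miss how those species act together: two miRNAs that co-regulate
the same pathways, answer to the same transcription factors, or co-vary
across tissues form a *functional synergy pair*. `mirsynergy` implements the
computational workflow of such a study end to end, for analysts who want the
statistics reproducible and testable rather than buried in a figure legend:

* **Synthetic paired cohort** — an 830-miRNA array over six paired
  normal/adenoma/carcinoma tissues with 40 planted up- and 8 planted
  down-regulated miRNAs (|log2FC| = 1.5, σ = 0.3) and a latent coupling
  between miR-155 and miR-143/145/192/378 whose sign flips between normal
  and tumour tissue. Every downstream stage is testable with no downloads.
* **Paired differential calling** — per-miRNA two-sided paired t-test with
  fold change as the mean paired log2 difference; a call requires
  p < 0.05 and |log2FC| ≥ 1 (both configurable; Holm/BH optional).
* **Pathway enrichment** — right-sided hypergeometric test
  P(X ≥ k), X ~ Hypergeom(N, K, n), of each miRNA's target genes against
  GMT pathway sets, Holm (Bonferroni step-down) correction within each
  miRNA's family, retention at corrected p ≤ 0.05, and grouping of
  redundant terms at Cohen κ ≥ 0.3 over gene memberships.
* **Synergy networks** — weighted undirected miRNA graphs from shared
  enriched pathways, shared upstream TFs, or within-class co-expression
  (|r| ≥ 0.7); hub score = weighted degree; GraphML / edge-list export.
* **2×2 association** — odds ratio ad/bc with the Woolf log-normal CI
  exp(log OR ± z·√(1/a+1/b+1/c+1/d)) and Fisher exact test; the published
  TGF-β1 × B7-H3 / B7-H4 positivity tables (n = 78) ship as a fixture.
* **Assay arithmetic** — comparative-Ct 2^−ΔΔCt with Ct ≥ 30 censoring,
  dual-luciferase normalisation, MTT relative viability, and the
  width²·length/2 xenograft volume formula.

## Worked example

```python
from mirsynergy import (
    SimulationConfig, simulate_expression, simulate_annotations,
    differential_mirnas, enrich_mirna_targets,
    pathway_synergy_network, hub_ranking, correlation_network,
)

config = SimulationConfig(seed=42)          # the default paired CRC profile
expr = simulate_expression(config)

table = differential_mirnas(expr, class_a="normal", class_b="carcinoma")
print(table["call"].value_counts().to_dict())

bundle = simulate_annotations(config, seed=42)
enrichment = enrich_mirna_targets(bundle.target_map, bundle.pathway_db)
network = pathway_synergy_network(enrichment)
print(hub_ranking(network)[:2])

normal_net = correlation_network(expr, "normal")
print(round(normal_net.edges["miR-155", "miR-143"]["evidence"][0], 2))
```

prints

```
{'ns': 782, 'up': 40, 'down': 8}
[('miR-155', 8.0), ('miR-143', 1.0)]
-0.8
```

— the differential stage recovers exactly the 40 up- and 8 down-regulated
miRNAs that were planted; miR-155 is the top hub of the pathway
co-regulation network (it shares one enriched pathway with each of its
eight engineered partners, the runner-up only one); and within normal
tissue miR-155 is inversely co-expressed with miR-143 (r = −0.8), a
coupling that turns positive in carcinoma samples.

The 2×2 association module reproduces the published marker table from its
printed counts:

```text
$ mirsynergy assoc
marker  odds_ratio  ci_low  ci_high  p_value   pct_a  method  test
B7-H3   2.96        1.12    7.81     0.03505   35.90  woolf   fisher
B7-H4   4.50        1.61    12.55    0.004336  38.46  woolf   fisher
```

A file-based pipeline runs everything in one go
(`mirsynergy run-all --outdir run/`), writing the differential table,
enrichment table, the three networks, the hub ranking and the association
results, plus a YAML sidecar of the resolved configuration; re-runs are
byte-identical. Short narrative scripts, one per capability, live in
`examples/`.

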