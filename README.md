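# paskit

Pathway activation strength (PAS) analysis of bulk RNA-seq time courses,
built for the study design that motivated it: comparing normal and
accelerated liver regeneration across surgical procedures in mouse
(sham, transection, portal vein ligation (PVL), left-lateral lobectomy,
ALPPS two-stage hepatectomy, standard 68% hepatectomy) sampled at
0.5–12 h post-surgery.  It is equally usable for any case-vs-reference
expression design scored against a pathway knowledge base with
activator/repressor gene roles.

## The statistic

For pathway *p* and sample *s*,

```
PAS(p, s) = Σₙ  ARRₙₚ · BTIFₙₛ · lg(CNRₙₛ)
```

summed over the pathway's member genes *n*, where

* **CNR** (case-to-normal ratio) — the gene's normalized expression in the
  sample divided by its mean over the reference ("normal") group;
* **BTIF** (beyond-tolerance-interval flag) — 1 only when the perturbation
  is both large (CNR ≤ 0.66 or ≥ 1.5) and statistically significant
  (two-sided Gaussian tail of the log2 abundance under the reference
  distribution, p < 0.05), else 0;
* **ARR** (activator/repressor role) — a discrete weight in
  {−1, −0.5, 0, +0.5, +1} encoding the gene product's role in the pathway;
* **lg** — the decimal logarithm.

Positive PAS = activators up / repressors down relative to normal.  Around
the statistic the package provides per-sample Gaussian p-values and group
Wilcoxon rank-sum tests (exact by enumeration for combined n ≤ 12),
significant-ISP selection with the stringent |PAS| ≥ 0.1 filter, Venn
partitions, PAS ratios, time profiles, hierarchical clustering, PCA,
correlation matrices, miRNA presence/exclusivity patterns, single-sample
rank-based enrichment scores, and a negative-binomial synthetic-study
generator with planted, role-respecting pathway activations.

## Worked example

```python
import paskit

table = paskit.load_hx68_alpps_table()           # bundled reference PAS table
ratio = paskit.pas_ratio(table, "Hypoxia pathway EMT 1", "pas_alpps", "pas_hx68")
print(f"{ratio:.1f}-fold")                        # -> 8.2-fold

sets = paskit.exclusive_sets()                   # procedure-exclusive ISPs
part = paskit.venn_partition(sets)
print({p: len(part.exclusive(p)) for p in sets})
# -> {'ALPPS': 4, 'PVL': 20, 'transection': 3}
```

The 8.2-fold value is the hypoxia/EMT branch PAS under ALPPS relative to
standard hepatectomy 4 h post-surgery — the strongest quantitative marker
of the accelerated response; the 4/20/3 split counts the signaling
pathways affected exclusively by each procedure at the same timepoint.
The `examples/` directory holds one short script per capability
(simulation + scoring, reference tables, significance selection, miRNA
patterns, enrichment), each printing the numbers it computes and a line on
what they mean.

## Command line

A thin CLI mirrors the library:

```sh
paskit simulate --out study/ --seed 1          # synthetic counts/design/DB
paskit run --config run.yaml --out results/    # full pipeline -> report bundle
```

`run` emits the PAS matrix (with YAML parameter sidecar), per-contrast
significance tables, Venn JSON, time profiles, PCA coordinates, cluster
order, miRNA patterns, enrichment scores and a manifest with input
checksums.  Stages are also available individually (`pas`, `stats`,
`compare`, `mirna`, `enrich`).

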