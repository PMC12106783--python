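# sclcmet

Computational pipeline for nominating metastasis-driver transcription
factors in small cell lung cancer (SCLC) and characterizing FOXA2 as a
metastasis-associated biomarker — for computational biologists who want the
analysis arms of such a study as reusable, tested building blocks.

SCLC is a high-grade neuroendocrine lung tumor that metastasizes early and
almost universally; tumors that never metastasize despite long follow-up
are rare natural experiments.  The package implements the analyses that
exploit that contrast:

* **Bulk nomination** — per-gene negative-binomial Wald differential
  expression (median-of-ratios size factors, log-link GLM with offset,
  method-of-moments dispersion), run for met-associated-primary vs
  never-met and metastasis vs never-met; genes with FC > 4 (or < 1/4) and
  P_adj < 0.05 in *both* contrasts, restricted to transcription factors,
  are the candidate drivers.
* **Pre-ranked GSEA** — genes ranked by `-log10(p) * sign(log2FC)`;
  weighted Kolmogorov–Smirnov running-sum ES, gene-set permutation null,
  NES = ES / mean |same-sign null ES|, add-one p-values, BH across sets.
* **Single-cell malignant-cell identification** — QC (≥200 genes, ≤40%
  mitochondrial), median-library log1p normalization, variance-trend HVGs,
  marker-score compartment assignment, a smoothed relative-expression CNV
  signal re-binned to 10 Mb, and cluster-level malignancy calls (PCA →
  cosine kNN → Louvain; burden > 3× reference and epithelial fraction
  ≥ 0.9).
* **FOXA2 association** — FOXA2± dichotomization (raw count > 0 in
  malignant cells), per-patient ridge regression of standardized FOXA2 on
  standardized HVGs, cross-patient Z-score
  `z = mean(beta) / (sd(beta)/sqrt(P))`, and re-ranking of the top 100
  genes by bulk Pearson correlation with FOXA2; binned-control signature
  scores with one-sided Mann–Whitney U comparisons.
* **Biomarker cutpoint and survival** — IHC H-score
  `sum(level × % cells)` (0–300), exhaustive sensitivity+specificity
  cutpoint search, Kaplan–Meier curves and the log-rank test.
* **Peak utilities** — 500 bp-gap peak merging, summit ±250 bp atlases,
  blacklist filtering, intragenic / nearest-TSS peak-to-gene assignment,
  and max-magnitude gene scores for pre-ranked enrichment.
* **Synthetic data** — seeded generators for every input above with
  planted ground truth (drivers, malignant clones, FOXA2 module, cutpoint),
  so each stage has a recovery oracle.

## Worked example

```python
from sclcmet.synthetic_data import SimConfig, simulate_bulk, simulate_tma
from sclcmet.bulk_nomination import nominate
from sclcmet.biomarker_survival import biomarker_analysis

cfg = SimConfig(seed=7)

bulk, anno, truth = simulate_bulk(cfg)
cands, de_mp, de_met = nominate(bulk, anno)
print("nominated TFs :", ", ".join(cands.tf_candidates))
print("planted TFs   :", ", ".join(sorted(truth.planted_driver_ids)))

tma = simulate_tma(cfg)
out = biomarker_analysis(tma)
cut = out["cutpoint"]
print(f"H-score cutpoint: {cut.cutpoint:.1f} "
      f"(sens {cut.sensitivity:.2f}, spec {cut.specificity:.2f})")
print(f"log-rank: chi2 = {out['logrank_chi2']:.2f}, p = {out['logrank_p']:.4f}")
```

prints

```
nominated TFs : G00822, G00886, G00813, G00312, G00945, G00125, G00452, G01276
planted TFs   : G00125, G00312, G00452, G00813, G00822, G00886, G00945, G01276
H-score cutpoint: 20.5 (sens 1.00, spec 1.00)
log-rank: chi2 = 12.00, p = 0.0005
```

The nomination pipeline recovers exactly the eight planted driver TFs
(ordering is by mean |Wald| across the two contrasts).  The tissue-
microarray arm finds a perfectly separating H-score cutpoint — the planted
risk threshold is 25, and 20.5 is the midpoint of the data gap containing
it — and the biomarker-high group shows significantly shorter relapse-free
survival (log-rank p = 0.0005).

The single-cell arm follows the same pattern: simulate with
`simulate_sc`, run `qc_filter` → `normalize_log1p` →
`assign_compartments` → `cnv_signal` → `call_malignant`, then
`ridge_association` and `crossref_bulk` to rank FOXA2 co-expression
partners.  See `docs/methods.md` for the models, parameter defaults and
the design rationale behind the generators.

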