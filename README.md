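# methmark

Genomic-region-aware analysis of DNA methylation patterns and histone
modification signals.

Whole-genome bisulfite sequencing yields per-CpG methylation levels that
segment naturally into contiguous unmethylated (U) and methylated (M)
regions.  How those patterns relate to chromatin marks and to sequence
context — and how the relationship shifts between promoters, gene bodies,
downstream windows and intergenic space, and between cell types — is a
central question in regulatory epigenomics.  `methmark` is a tested,
reusable pipeline for that analysis, aimed at computational biologists who
want the full chain from per-CpG counts to interpretable feature rankings:

* **Pattern calling** — U/M region segmentation from Bismark-coverage-style
  tables by a deterministic run scanner with explicit thresholds.
* **Genome partition** — promoter `[TSS−1000, TSS+500)`, gene body,
  downstream `[TTS−500, TTS+1000)` and intergenic categories with a
  CpG-island overlay; regions assigned by midpoint.
* **Features** — GC content `(N_C+N_G)/L`, CpG observed/expected
  `(N_CpG·L)/(N_C·N_G)`, and per-mark pseudocounted RPKM
  `(Reads + p)·10⁹/(N·Length)` with floor `1/Length`.
* **Classification** — balanced-sampling, 10×-repeated stratified 10-fold
  cross-validated random forest predicting U vs M; AUC/ACC/SE/SP from
  pooled out-of-fold probabilities; mean-decrease-Gini (MDG) importance
  ranking, cumulative top-n AUC curves and essential top-6 features.
* **DMR analysis** — U→M / M→U differential regions between paired cell
  types, per-mark log2 fold changes, Wilcoxon rank-sum selection of
  informative effectors (p < 0.001), and DMR-class prediction.
* **Co-variation** — quantile selection of DMR–gene sets co-varying with
  H3K4me2/H3K4me3 changes, plus generic hypergeometric gene-set and
  region-overlap enrichment.
* **Synthetic ground truth** — a first-class generator of two-cell-type
  epigenomes with planted segments, DMRs and state-coupled mark tracks,
  used throughout the test suite.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```python
import methmark as mm
from methmark.classify import ModelParams

cfg = mm.SyntheticConfig(n_chroms=2, chrom_length=600_000, n_genes=24, seed=1)
genome = mm.generate_genome(cfg)
prof1, prof2, truth = mm.generate_methylomes(cfg, genome)
marks = mm.generate_mark_reads(cfg, truth, cell=1)

regions = mm.call_patterns(prof1)
print(f"{len(regions)} regions "
      f"({(regions.pattern == 'U').sum()} U, {(regions.pattern == 'M').sum()} M)")

genes = [mm.GeneModel(r["name"], r.chrom, r.start, r.end, r.strand)
         for _, r in genome.genes.iterrows()]
rmap = mm.build_region_map(genes, genome.chrom_sizes())
regions["category"] = mm.classify_regions(regions, rmap)

fm = mm.feature_matrix(regions, genome.sequences, marks)
y = (fm["pattern"] == "M").to_numpy(int)
res = mm.compare_feature_sets(fm, y, list(cfg.mark_names),
                              model_params=ModelParams(n_estimators=150),
                              n_repeats=5, seed=0)
for name, cv in res.items():
    print(f"{name:6s} mean AUC {cv.mean_auc:.3f}  ACC {cv.mean_acc:.3f}")

ranking = mm.rank_importance(fm, y, list(cfg.mark_names) + ["gc_content", "cpg_oe"],
                             ModelParams(n_estimators=150), n_repeats=5, seed=0)
print("top features:", ", ".join(ranking["feature"].head(6)))
```

prints

```
1818 regions (732 U, 1086 M)
SF     mean AUC 0.509  ACC 0.512
HM     mean AUC 0.993  ACC 0.957
HM+SF  mean AUC 0.994  ACC 0.960
top features: H3K4me2, H3K4me3, H3K9ac, H3K9me3, H3K27ac, H3K4me1
```

Reading the numbers: on this 1.2 Mb planted genome the sequence features
alone (SF) are nearly uninformative because only CpG-island regions couple
sequence to state, the sixteen histone marks (HM) separate U from M almost
perfectly, and adding sequence features (HM+SF) changes little — the marks
planted with the largest effect sizes (H3K4me2/me3, H3K9ac) head the MDG
importance ranking, exactly the planted structure.

The same stages are available from the shell:

```sh
methmark synth --seed 7 --out bundle/
methmark call-patterns --coverage bundle/cell1.cov.tsv --out regions1.bed
methmark run-all --seed 7 --out run/     # full pipeline + report.json
```

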