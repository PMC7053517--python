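# tilquant

Single-cell functional analysis of tumour-infiltrating lymphocytes
(TILs) in multiplexed-immunofluorescence melanoma tissue.

Melanoma prognosis has classically leaned on the *morphology* of the
TIL infiltrate (brisk / non-brisk). `tilquant` implements a *functional*
readout instead: starting from a quantified single-cell table (one row
per segmented cell with per-marker mean fluorescence intensities), it

1. **normalizes** marker intensities to trimmed z-scores after QC
   filters (cells expressing < 3 markers; markers expressed in < 1% of
   cells);
2. **scores activation** of each CD8+ T cell in [−1, 1] along a
   PCA-derived gradient over CD69, OX40, LAG3 and TIM3 — PC2/PC3 are
   retained (PC1 is a common-mode staining axis), the CD69 loading
   direction anchors maximum activation (+1) and the TIM3 loading
   direction maximum exhaustion (−1), with scores linear in angle
   between the anchors;
3. **classifies cores and patients** as Active / Transition / Exhausted
   by one-tailed t-tests against the cohort background with BH-FDR at
   α = 0.001, including subsampling robustness curves and dichotomized
   Kaplan–Meier / log-rank survival;
4. **phenotypes cells** by consensus of three clusterings (K-means,
   kNN-Jaccard-Leiden graph communities, density peaks on a UMAP
   embedding) annotated through an explicit marker rulebook — a cell
   keeps a phenotype only when ≥ 2 methods agree — then subclusters each
   phenotype functionally (active / transition / exhausted /
   proliferating / anergic);
5. **tests spatial interactions** per image with a label-permutation
   null (radius 30 px, N = 1000, tri-state calls at α = 0.001) and
   integrates calls across images as

       P_ij = Σ_k c_ijk · N_ijk / Σ_k N_ijk ,

   N_ijk = geometric mean of the two phenotypes' counts in image k,
   with |P| > 0.75 / 0.5 / 0.25 as strong / moderate / weak, plus a
   nest-tolerant contact profile around melanoma cells;
6. provides **cohort statistics** (pooled-sd t-tests with Holm
   adjustment, rank tests for composition, the qPCR
   log(IFNg/CD45) / LAG3-TIM3 classification rule) and
   **correlation-based RNA deconvolution** utilities (Spearman
   assignment against LM22-style signatures, Active/Exhausted CD8
   signature construction, fraction-based patient labels).

A first-class synthetic-cohort generator (`tilquant.synthetic`) plants
known phenotypes, activation classes, core statuses and spatial
interactions, so the entire pipeline is testable end to end without any
external data. See `docs/methods.md` for the full model description.

## Worked example

```python
import tilquant as tq
from tilquant.synthetic import SyntheticConfig, generate_cohort

statuses = ["Active"] * 20 + ["Transition"] * 20 + ["Exhausted"] * 20
cfg = SyntheticConfig(n_patients=20, cores_per_patient=(3, 3),
                      cells_per_core=(800, 1200),
                      core_statuses=statuses, seed=42)
cells, truth = generate_cohort(cfg)              # 60 cores, ~60k cells

norm = tq.run_qc(cells)                          # filters + trimmed z-scores
norm = norm.merge(truth.cells[["cell_id", "phenotype"]], on="cell_id")
scored, model = tq.activation.score_table(norm)  # PCA gradient on Tcy cells

calls = tq.classify_cores(scored, alpha=0.001)
df = tq.status.status_frame(calls)
df["truth"] = df["unit_id"].map(truth.core_status)
print(df["status"].value_counts().to_dict())
print("recovery:", (df["status"] == df["truth"]).mean())
```

Output:

```
{'Active': 20, 'Transition': 20, 'Exhausted': 20}
recovery: 1.0
```

All 60 cores recover their planted status: the 20 cores generated with a
70% active CD8 mix are called Active, the 70%-exhausted ones Exhausted,
and the balanced ones stay Transition (their pooled mean matches the
background, so neither one-tailed test fires at α = 0.001).

The same stages are scriptable from a shell:

```bash
tilquant simulate --out sim/ --seed 3 --reduced
tilquant qc --in sim/cells.csv --out sim/cells.norm.csv
tilquant score --in sim/cells.norm.csv --out sim/cells.scored.csv
tilquant classify --in sim/cells.scored.csv --level core --out sim/status.csv
tilquant neighborhood --in sim/cells.pheno.csv --out sim/interactions.csv
```

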