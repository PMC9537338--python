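# avcycle

Links endothelial **cell-cycle state** to **arterial–venous identity** in
transcriptomic data. During vascular development, endothelial cells sit on a
continuum from venous to arterial phenotype, and their cell-cycle state —
read out by the two-channel FUCCI reporter as Negative (early G1),
Red (late G1, mCherry–Cdt1) or Green (S/G2/M, mVenus–Geminin) — tracks that
continuum: venous cells tend to be FUCCI-Negative, arterial cells
FUCCI-Red G1. `avcycle` implements the computational side of that analysis
as a tested, reusable pipeline for bulk RNA-seq of FACS-sorted FUCCI
populations and droplet scRNA-seq of endothelial cells, exercised end to
end on its own seeded synthetic-data generator.

## What it computes

1. **FUCCI gating** — threshold two reporter channels into
   Negative / Red-G1 / Green-S/G2/M (double positives default to Green,
   since Geminin marks S/G2/M), with per-group state fractions.
2. **Bulk state signatures** — log₂(CPM+1) normalization, per-gene one-way
   ANOVA across the three sorted states with Benjamini–Hochberg q-values,
   and extraction of genes *upregulated* in each state
   (q < 0.05 ∧ strict argmax mean ∧ log₂FC ≥ 0.5 vs the other two states).
3. **Diffusion imputation** — a row-stochastic Markov operator built from
   an adaptive Gaussian kNN kernel in PCA space (k = 15, kₐ = 4, 20
   components), powered t = 4 times: `X̂ = Mᵗ X`.
4. **Per-cell scores** —
   - module scores with expression-bin-matched control genes (24 bins,
     100 controls per gene): TGF/BMP signaling and the three cell-cycle
     state scores from the bulk signatures;
   - Arterial / Venous scores: mean per-gene z-scored expression of the
     arterial or venous program **after imputation**, with
     `S_av = S_art − S_ven`;
   - relative G1 score `ΔG1 = S_red − S_neg`, placing each cell between
     early- and late-G1 transcriptional states.
5. **Association statistics** — simple linear regression (two-sided t on
   the slope), one-way ANOVA with Tukey HSD post hoc (Tukey–Kramer for
   unequal n), Welch's t, ΔΔCt fold-changes and the nuclear-localization
   percentage (nuclear / total vessel fluorescence × 100).

The synthetic generator plants all of this structure: a latent
arterial–venous position `a ∈ [−1, 1]` per cell, a softmax coupling of
cell-cycle state to `a` (strength β), negative-binomial counts
(Var = μ + φμ²) with log-normal size factors, sorted-bulk replicates, and
log-normal two-channel fluorescence.

## Worked example

```python
from avcycle import PipelineConfig, SimConfig, analyze

cfg = PipelineConfig(
    sim=SimConfig(n_cells=1000, n_genes=2500, n_state_genes_per_state=50,
                  n_arterial_genes=25, n_venous_genes=25,
                  n_tgf_genes=10, n_bmp_genes=10),
    seed=1)
res = analyze(cfg)
print({k: len(v) for k, v in res.signatures.as_dict().items()})
for a in res.associations:
    print(f"{a['y']:>15} ~ relative_g1  slope={a['slope']:+.3f}  "
          f"R2={a['r_squared']:.3f}  p={a['p_value']:.3g}")
```

prints

```
{'NEGATIVE': 46, 'RED_G1': 48, 'GREEN_SG2M': 48}
 arterial_score ~ relative_g1  slope=+0.355  R2=0.391  p=9.74e-110
   venous_score ~ relative_g1  slope=-0.406  R2=0.475  p=1.03e-141
      tgf_score ~ relative_g1  slope=+0.190  R2=0.088  p=1.01e-21
      bmp_score ~ relative_g1  slope=-0.111  R2=0.031  p=2.17e-08
```

The bulk stage recovered ~46–48 of the 50 genes planted per state, and the
regressions recover the planted biology: cells transcriptionally in late G1
(high ΔG1) score arterial and TGF-high, cells in early G1 score venous and
BMP-high. The positive arterial and negative venous slopes are the
directions the analysis is designed to detect; their magnitudes depend on
the simulation's coupling strength β and fold-changes.

The same stages are available from the shell:

```bash
avcycle run --seed 1 --out runs/demo          # full pipeline + manifest
avcycle simulate --out data --seed 1          # just the synthetic datasets
avcycle gate --in data/truth.tsv --tau-red 12.2 --tau-green 12.2 --out gated
```

Every run writes a `manifest.json` with the config hash, derived per-stage
seeds and output checksums; identical configs reproduce identical
checksums.

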