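"""Per-cell gene-set and composite scores.

Module scores follow the binned-control convention: genes are binned by
mean expression, each signature gene is paired with control genes sampled
from its bin, and the score is the mean signature expression minus the mean
over the pooled control multiset.  Composite scores implemented here:

* TGF / BMP signaling scores (module scores of the pathway gene lists),
* cell-cycle-state scores from the bulk-derived FUCCI signatures,
* Arterial / Venous scores — mean per-gene z-scored (relative) expression
  over the program gene lists on the *imputed* matrix — and their
  difference, the Arterial-vs-Venous score S_av = S_art - S_ven,
* the relative G1 score, Red-G1 score minus Negative score per cell, which
  places a cell between early- and late-G1 transcriptional states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from avcycle.bulk import SignatureSet

__all__ = [
    "ModuleScoreParams",
    "TGF_GENES",
    "BMP_GENES",
    "TGF_GENES_RESULTS",
    "BMP_GENES_RESULTS",
    "module_score",
    "signaling_scores",
    "cellcycle_scores",
    "av_scores",
    "relative_g1",
]

#: Default TGF/BMP pathway gene lists (Methods variants).
TGF_GENES = ("Smad3", "Tgfbr1", "Tgfbr2", "Smad6", "Acvrl1", "Tgfb1", "Tgfb2")
BMP_GENES = ("Smad1", "Smad5", "Bmpr2")
#: Alternate (Results-section) variants of the same pathway lists.
TGF_GENES_RESULTS = ("Smad2", "Smad3", "Tgfbr1", "Tgfbr2", "Acrvl1", "Tgfb1",
                     "Tgfb2", "Smad7")
BMP_GENES_RESULTS = ("Smad1", "Smad5", "Bmpr2", "Bmpr1a", "Bmpr1b")


@dataclass(frozen=True)
class ModuleScoreParams:
    n_bins: int = 24
    n_ctrl: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.n_ctrl < 1:
            raise ValueError("n_ctrl must be >= 1")


def _present_genes(expr: pd.DataFrame, gene_set, what: str = "gene set"):
    genes = list(dict.fromkeys(gene_set))
    present = [g for g in genes if g in expr.columns]
    missing = [g for g in genes if g not in expr.columns]
    if not present:
        raise ValueError(f"{what}: no genes found in the matrix (missing: {missing})")
    if missing:
        warnings.warn(f"{what}: dropping {len(missing)} gene(s) absent from the matrix: {missing}")
    return present


def module_score(
    expr_lognorm: pd.DataFrame,
    gene_set,
    params: ModuleScoreParams = ModuleScoreParams(),
) -> pd.Series:
    """Binned-control module score of a gene set, per cell.

    Genes are ranked by mean expression across cells and cut into
    ``n_bins`` equal-frequency bins; for each signature gene, ``n_ctrl``
    control genes are drawn (seeded, without replacement, excluding the
    gene itself) from its bin.  The score is the per-cell mean over the
    signature genes minus the mean over the pooled control multiset, so a
    set indistinguishable from its bins scores 0 and adding a constant to
    the whole matrix changes nothing.
    """
    genes = _present_genes(expr_lognorm, gene_set, "module_score")
    n_genes = expr_lognorm.shape[1]
    if params.n_bins > n_genes:
        raise ValueError(f"n_bins ({params.n_bins}) exceeds gene count ({n_genes})")

    means = expr_lognorm.mean(axis=0).to_numpy()
    order = np.argsort(means, kind="stable")
    bin_of = np.empty(n_genes, dtype=int)
    for b, chunk in enumerate(np.array_split(order, params.n_bins)):
        bin_of[chunk] = b
    col_index = {g: j for j, g in enumerate(expr_lognorm.columns)}

    rng = np.random.default_rng(params.seed)
    control_cols = []
    for g in genes:
        j = col_index[g]
        pool = np.flatnonzero(bin_of == bin_of[j])
        pool = pool[pool != j]
        if pool.size == 0:
            continue
        size = min(params.n_ctrl, pool.size)
        control_cols.append(rng.choice(pool, size=size, replace=False))
    if not control_cols:
        raise ValueError("module_score: no control genes available")
    control_cols = np.concatenate(control_cols)

    X = expr_lognorm.to_numpy(dtype=float)
    sig = X[:, [col_index[g] for g in genes]].mean(axis=1)
    ctrl = X[:, control_cols].mean(axis=1)
    return pd.Series(sig - ctrl, index=expr_lognorm.index, name="module_score")


def signaling_scores(
    expr_lognorm: pd.DataFrame,
    tgf_genes=TGF_GENES,
    bmp_genes=BMP_GENES,
    params: ModuleScoreParams = ModuleScoreParams(),
):
    """TGF and BMP signaling module scores (returns two per-cell Series)."""
    tgf = module_score(expr_lognorm, tgf_genes, params).rename("tgf_score")
    bmp = module_score(expr_lognorm, bmp_genes, params).rename("bmp_score")
    return tgf, bmp


def cellcycle_scores(
    expr_lognorm: pd.DataFrame,
    signatures: SignatureSet,
    params: ModuleScoreParams = ModuleScoreParams(),
):
    """FUCCI-state module scores from the bulk-derived signatures.

    Returns (S_neg, S_red, S_green) per-cell Series.
    """
    named = [
        ("NEGATIVE", signatures.genes_negative, "score_negative"),
        ("RED_G1", signatures.genes_red, "score_red"),
        ("GREEN_SG2M", signatures.genes_green, "score_green"),
    ]
    out = []
    for state, genes, name in named:
        if not genes:
            raise ValueError(f"signature for state {state} is empty")
        out.append(module_score(expr_lognorm, genes, params).rename(name))
    return tuple(out)


def av_scores(expr_imputed: pd.DataFrame, arterial_genes, venous_genes):
    """Arterial / Venous scores and their difference on the imputed matrix.

    "Relative expression" is the per-gene z-score across cells (population
    sd; zero-variance genes contribute 0).  S_art and S_ven are the means
    of z over the arterial and venous lists, S_av = S_art - S_ven.
    Swapping the lists negates S_av exactly.
    """
    art = _present_genes(expr_imputed, arterial_genes, "arterial genes")
    ven = _present_genes(expr_imputed, venous_genes, "venous genes")

    def mean_z(genes):
        X = expr_imputed[genes].to_numpy(dtype=float)
        sd = X.std(axis=0, ddof=0)
        if np.all(sd == 0):
            raise ValueError("all listed genes have zero variance across cells")
        z = np.zeros_like(X)
        ok = sd > 0
        z[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
        return z.mean(axis=1)

    s_art = pd.Series(mean_z(art), index=expr_imputed.index, name="arterial_score")
    s_ven = pd.Series(mean_z(ven), index=expr_imputed.index, name="venous_score")
    s_av = (s_art - s_ven).rename("av_score")
    return s_art, s_ven, s_av


def relative_g1(s_red: pd.Series, s_neg: pd.Series) -> pd.Series:
    """Relative G1 score: Red-G1 score minus Negative score, per cell."""
    red = np.asarray(s_red, dtype=float)
    neg = np.asarray(s_neg, dtype=float)
    if red.shape != neg.shape:
        raise ValueError("score vectors must have the same length")
    out = red - neg
    if isinstance(s_red, pd.Series):
        return pd.Series(out, index=s_red.index, name="relative_g1")
    return out
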