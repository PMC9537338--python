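"""Bulk RNA-seq normalization, per-gene DE across FUCCI states, signature extraction.

The sorted-population bulk data carries three FUCCI states with replicate
samples.  Counts are normalized to log2(CPM+1), each gene is tested with a
one-way fixed-effects ANOVA across states, p-values are BH-adjusted, and a
gene joins the signature of the state where it is significantly and
strictly maximally expressed with a sufficient fold-change — the
"upregulated in state" sets that single-cell cell-cycle scoring consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from avcycle.simulate import STATES, BulkDataset

__all__ = [
    "SignatureSet",
    "normalize_cpm_log",
    "de_one_way",
    "bh_adjust",
    "extract_state_signatures",
]


@dataclass
class SignatureSet:
    """Per-state gene signatures with the thresholds that produced them."""

    genes_negative: tuple
    genes_red: tuple
    genes_green: tuple
    q_threshold: float = 0.05
    lfc_threshold: float = 0.5
    source: str = ""

    def as_dict(self) -> dict:
        return {
            "NEGATIVE": list(self.genes_negative),
            "RED_G1": list(self.genes_red),
            "GREEN_SG2M": list(self.genes_green),
        }

    def validate(self) -> None:
        lists = [self.genes_negative, self.genes_red, self.genes_green]
        names = [g for lst in lists for g in lst]
        if len(names) != len(set(names)):
            raise ValueError("state signatures must be disjoint")


def normalize_cpm_log(bulk) -> pd.DataFrame:
    """log2(1 + CPM) normalization of a genes x samples count matrix.

    Accepts a :class:`BulkDataset` or a plain DataFrame.  Scale-invariant in
    each sample's library size; a count of 0 maps to exactly 0.
    """
    counts = bulk.counts if isinstance(bulk, BulkDataset) else bulk
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero.index)}")
    cpm = counts / totals * 1e6
    return np.log2(1.0 + cpm)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, returned in the input
    order.  Permutation-equivariant and monotone in sorted-p order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def de_one_way(norm: pd.DataFrame, states) -> pd.DataFrame:
    """Per-gene one-way ANOVA of log2-CPM across the three FUCCI states.

    Parameters
    ----------
    norm : genes x samples log2-CPM matrix.
    states : per-sample state labels aligned with the columns.

    Returns a DataFrame indexed by gene with the state means, the log2
    fold-change of each state against the mean of the other two, the F
    statistic, the p-value (F distribution, fixed effects) and the BH
    q-value over all tested genes.  Genes with zero total variance get
    F = 0, p = 1.
    """
    states = pd.Series(np.asarray(states), index=norm.columns)
    present = list(pd.unique(states))
    if sorted(present) != sorted(STATES):
        raise ValueError(f"need exactly the three states {STATES}, got {present}")
    sizes = states.value_counts()
    if (sizes < 2).any():
        low = sizes[sizes < 2].index.tolist()
        raise ValueError(f"state(s) with fewer than 2 replicates: {low}")

    X = norm.to_numpy(dtype=float)
    G, N = X.shape
    k = len(STATES)
    group_means = {}
    ssb = np.zeros(G)
    ssw = np.zeros(G)
    grand = X.mean(axis=1)
    for s in STATES:
        cols = np.flatnonzero((states == s).to_numpy())
        sub = X[:, cols]
        mu = sub.mean(axis=1)
        group_means[s] = mu
        ssb += cols.size * (mu - grand) ** 2
        ssw += ((sub - mu[:, None]) ** 2).sum(axis=1)

    df_b, df_w = k - 1, N - k
    msb = ssb / df_b
    msw = ssw / df_w
    with np.errstate(divide="ignore", invalid="ignore"):
        F = msb / msw
    p = np.empty(G)
    finite = np.isfinite(F)
    p[finite] = sps.f.sf(F[finite], df_b, df_w)
    # within-group variance exactly zero: perfect separation unless the gene
    # is constant overall, in which case there is nothing to test
    degenerate = ~finite
    sep = degenerate & (ssb > 0)
    flat = (ssb + ssw) == 0
    F = np.where(degenerate, np.inf, F)
    p[sep] = 0.0
    F[flat] = 0.0
    p[flat] = 1.0

    out = pd.DataFrame(index=norm.index)
    for s in STATES:
        out[f"mean_{s}"] = group_means[s]
    for s in STATES:
        others = [t for t in STATES if t != s]
        rest = np.mean([group_means[t] for t in others], axis=0)
        out[f"lfc_{s}"] = group_means[s] - rest
    out["F"] = F
    out["p"] = p
    out["q"] = bh_adjust(p)
    return out


def extract_state_signatures(
    de: pd.DataFrame,
    q_threshold: float = 0.05,
    lfc_threshold: float = 0.5,
    source: str = "bulk one-way ANOVA",
) -> SignatureSet:
    """Genes upregulated in each FUCCI state.

    A gene enters the signature of state ``s`` iff its q-value is below
    ``q_threshold``, its mean in ``s`` is the strict maximum over the three
    states, and its log2 fold-change versus the mean of the other two
    states is at least ``lfc_threshold``.  Assigning each gene to its
    argmax state makes the lists disjoint by construction.
    """
    if de.empty:
        raise ValueError("DE table is empty")
    means = de[[f"mean_{s}" for s in STATES]].to_numpy()
    argmax = means.argmax(axis=1)
    strict = (means == means.max(axis=1, keepdims=True)).sum(axis=1) == 1
    sig = de["q"].to_numpy() < q_threshold

    lists = {s: [] for s in STATES}
    for i, gene in enumerate(de.index):
        if not (sig[i] and strict[i]):
            continue
        s = STATES[argmax[i]]
        if de[f"lfc_{s}"].iloc[i] >= lfc_threshold:
            lists[s].append(gene)
    for s in STATES:
        if not lists[s]:
            warnings.warn(f"signature for state {s} is empty at q<{q_threshold}, lfc>={lfc_threshold}")
    out = SignatureSet(
        genes_negative=tuple(lists["NEGATIVE"]),
        genes_red=tuple(lists["RED_G1"]),
        genes_green=tuple(lists["GREEN_SG2M"]),
        q_threshold=q_threshold,
        lfc_threshold=lfc_threshold,
        source=source,
    )
    out.validate()
    return out
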