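"""FUCCI reporter gating: two-channel thresholding into cell-cycle states.

Mirrors FACS gating of a dual-reporter system: mCherry (Cdt1 fragment)
marks late G1, mVenus (Geminin fragment) marks S/G2/M, neither reporter
means early G1 ("Negative").  Cells above both thresholds — the brief
G1/S overlap of FUCCI systems — are handled by a configurable policy and
default to S/G2/M because Geminin is present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "FucciLabel",
    "DoublePositivePolicy",
    "GatingThresholds",
    "assign_fucci_state",
    "auto_thresholds",
    "state_fractions",
]


class FucciLabel(str, Enum):
    NEGATIVE = "NEGATIVE"
    RED_G1 = "RED_G1"
    GREEN_SG2M = "GREEN_SG2M"
    DOUBLE_POSITIVE = "DOUBLE_POSITIVE"


class DoublePositivePolicy(str, Enum):
    AS_GREEN = "AS_GREEN"      # Geminin present -> call S/G2/M (default)
    SEPARATE = "SEPARATE"      # keep a fourth DOUBLE_POSITIVE class
    EXCLUDE = "EXCLUDE"        # label DOUBLE_POSITIVE; drop from fractions


@dataclass(frozen=True)
class GatingThresholds:
    tau_red: float
    tau_green: float
    double_positive_policy: DoublePositivePolicy = DoublePositivePolicy.AS_GREEN

    def __post_init__(self):
        if not (self.tau_red > 0 and self.tau_green > 0):
            raise ValueError("gating thresholds must be > 0")


def assign_fucci_state(mcherry, mvenus, thresholds: GatingThresholds):
    """Gate cells into FUCCI states from the two reporter channels.

    Accepts scalars or arrays; returns a single label or an object array of
    labels.  Every cell receives exactly one label (gating is total).
    """
    mc = np.asarray(mcherry, dtype=float)
    mv = np.asarray(mvenus, dtype=float)
    if np.any(mc < 0) or np.any(mv < 0):
        raise ValueError("fluorescence intensities must be >= 0")
    red = mc >= thresholds.tau_red
    green = mv >= thresholds.tau_green

    labels = np.empty(mc.shape, dtype=object)
    labels[...] = FucciLabel.NEGATIVE
    labels[red & ~green] = FucciLabel.RED_G1
    labels[~red & green] = FucciLabel.GREEN_SG2M
    if thresholds.double_positive_policy is DoublePositivePolicy.AS_GREEN:
        labels[red & green] = FucciLabel.GREEN_SG2M
    else:
        labels[red & green] = FucciLabel.DOUBLE_POSITIVE
    if labels.ndim == 0:
        return labels.item()
    return labels


def auto_thresholds(
    negative_control_mcherry,
    negative_control_mvenus,
    quantile: float = 0.99,
    double_positive_policy: DoublePositivePolicy = DoublePositivePolicy.AS_GREEN,
) -> GatingThresholds:
    """Derive gates from a reporter-negative control sample.

    Each channel's threshold is the nearest-rank empirical ``quantile`` of
    the control intensities (q = 0 gives the sample minimum).
    """
    taus = []
    for ctrl in (negative_control_mcherry, negative_control_mvenus):
        x = np.sort(np.asarray(ctrl, dtype=float))
        if x.size == 0:
            raise ValueError("negative control sample is empty")
        if not 0.0 <= quantile <= 1.0:
            raise ValueError("quantile must lie in [0, 1]")
        rank = max(int(np.ceil(quantile * x.size)), 1)  # nearest-rank, 1-based
        taus.append(float(x[rank - 1]))
    return GatingThresholds(taus[0], taus[1], double_positive_policy)


def state_fractions(labels, groups) -> pd.DataFrame:
    """Per-group percentage of cells in each FUCCI state.

    DOUBLE_POSITIVE labels are excluded from the percentage denominator
    (they only arise under the SEPARATE/EXCLUDE policies) but their counts
    are still reported.  Percentages within a group sum to 100.
    """
    labels = np.asarray([l.value if isinstance(l, FucciLabel) else str(l) for l in labels])
    groups = np.asarray(groups)
    if labels.shape != groups.shape:
        raise ValueError("labels and groups must have the same length")

    records = []
    for g in pd.unique(groups):
        sel = labels[groups == g]
        if sel.size == 0:
            warnings.warn(f"group {g!r} is empty; omitted")
            continue
        kept = sel[sel != FucciLabel.DOUBLE_POSITIVE.value]
        denom = kept.size
        for s in ("NEGATIVE", "RED_G1", "GREEN_SG2M", "DOUBLE_POSITIVE"):
            count = int((sel == s).sum())
            if s == "DOUBLE_POSITIVE" and count == 0:
                continue
            pct = 100.0 * count / denom if (denom and s != "DOUBLE_POSITIVE") else (
                np.nan if s == "DOUBLE_POSITIVE" else 0.0)
            records.append({"group": g, "state": s, "count": count, "percent": pct})
    return pd.DataFrame.from_records(records, columns=["group", "state", "count", "percent"])
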