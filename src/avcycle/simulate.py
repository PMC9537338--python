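"""Seeded synthetic bulk and single-cell datasets with FUCCI / arterial-venous structure.

The generator emulates the data layout of the study system this package
analyses: droplet scRNA-seq of retinal endothelial cells spread along a
venous -> capillary -> arterial continuum, and bulk RNA-seq of FACS-sorted
FUCCI reporter populations (Negative, Red-G1, Green-S/G2/M; three
replicates per state, nine samples).

Model
-----
* Each cell carries a latent arterial-venous position ``a`` drawn uniformly
  on [-1, +1] (venous = -1, arterial = +1).
* Cell-cycle state is drawn from a three-way softmax whose logits couple to
  ``a`` with strength ``beta_coupling``: late-G1 (Red) propensity rises
  toward the arterial side, early-G1 (Negative) toward the venous side, and
  S/G2/M keeps a configurable baseline, also venous-shifted.
* Gene means start flat across genes; arterial-program genes scale as
  ``2**(delta_av * max(a, 0))``, venous-program genes as
  ``2**(delta_av * max(-a, 0))``; TGF genes ride the arterial program and
  BMP genes the venous program; each planted state-signature gene gains
  ``2**delta_state`` in cells of its own state.
* Counts are negative binomial with dispersion ``phi`` (Var = mu + phi*mu^2)
  around per-cell log-normal size factors; dropout arises from low means,
  with no extra zero-inflation.
* Reporter fluorescence (mCherry, mVenus) is log-normal per state with
  configurable channel separation, so gating difficulty is tunable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STATES",
    "SimConfig",
    "GenePanel",
    "SingleCellDataset",
    "BulkDataset",
    "NuclearImage",
    "make_gene_panel",
    "simulate_single_cells",
    "simulate_bulk_sorted",
    "simulate_nuclear_image",
]

#: FUCCI cell-cycle states, in fixed canonical order.
STATES = ("NEGATIVE", "RED_G1", "GREEN_SG2M")

# In-text cluster markers used as the leading real-gene names of the
# arterial / venous / signaling panels.
_ARTERIAL_MARKERS = ("Efnb2", "Gja4", "Gja5", "Sox17", "Bmx", "Jag1", "Hey1")
_VENOUS_MARKERS = ("Ephb4", "Nrp2", "Nr2f2", "Ptgs1", "Apoe", "Slc38a5")
_TGF_MARKERS = ("Smad3", "Tgfbr1", "Tgfbr2", "Smad6", "Acvrl1", "Tgfb1", "Tgfb2")
_BMP_MARKERS = ("Smad1", "Smad5", "Bmpr2")


def _default_fluor_logmeans() -> dict:
    # (log mCherry, log mVenus) per state: Red-G1 = high/low, Green = low/high,
    # Negative = low/low.  With log-sd 0.35 the default separation is ~8.6 sd.
    return {
        "NEGATIVE": (1.0, 1.0),
        "RED_G1": (4.0, 1.0),
        "GREEN_SG2M": (1.0, 4.0),
    }


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults are the conditions the downstream analyses are exercised under:
    2000 cells x 5000 genes, 100 planted signature genes per cell-cycle
    state, 50 arterial / 50 venous program genes, 20 TGF / 20 BMP genes.
    """

    n_cells: int = 2000
    n_genes: int = 5000
    n_arterial_genes: int = 50
    n_venous_genes: int = 50
    n_state_genes_per_state: int = 100
    n_tgf_genes: int = 20
    n_bmp_genes: int = 20
    #: log2 fold-change of each planted state-signature gene in its own state.
    delta_state: float = 1.0
    #: log2 fold-change span of the arterial/venous programs across the axis.
    delta_av: float = 1.0
    #: coupling between AV position and late-G1 propensity (softmax logits).
    beta_coupling: float = 1.5
    #: NB dispersion phi of single-cell counts (Var = mu + phi mu^2).
    nb_dispersion: float = 0.5
    #: NB dispersion of sorted-bulk replicate counts (far lower than droplet).
    bulk_dispersion: float = 0.01
    libsize_logmean: float = math.log(1e4)
    libsize_logsd: float = 0.3
    bulk_replicates: int = 3
    bulk_depth: float = 1e6
    fluor_logmeans: Mapping[str, tuple] = field(default_factory=_default_fluor_logmeans)
    fluor_logsd: float = 0.35
    #: baseline probability of the S/G2/M state at a = 0.
    p_green_base: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_cells": self.n_cells,
            "n_genes": self.n_genes,
            "bulk_replicates": self.bulk_replicates,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if self.bulk_replicates < 2:
            raise ValueError("bulk_replicates must be >= 2")
        for name in ("n_arterial_genes", "n_venous_genes", "n_state_genes_per_state",
                     "n_tgf_genes", "n_bmp_genes"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if not (self.nb_dispersion > 0 and self.bulk_dispersion > 0):
            raise ValueError("NB dispersions must be > 0")
        if self.bulk_depth <= 0:
            raise ValueError("bulk_depth must be > 0")
        if not 0.0 <= self.p_green_base <= 1.0:
            raise ValueError("p_green_base must lie in [0, 1]")
        scalars = (self.delta_state, self.delta_av, self.beta_coupling,
                   self.libsize_logmean, self.libsize_logsd, self.fluor_logsd)
        if not all(np.isfinite(scalars)):
            raise ValueError("all scalar parameters must be finite")
        if self.libsize_logsd < 0 or self.fluor_logsd <= 0:
            raise ValueError("scale parameters must be positive")
        if set(self.fluor_logmeans) != set(STATES):
            raise ValueError(f"fluor_logmeans must have keys {STATES}")
        self._panel_total()  # raises on overflow

    def _panel_total(self) -> int:
        sizes = {
            "n_arterial_genes": self.n_arterial_genes,
            "n_venous_genes": self.n_venous_genes,
            "n_state_genes_per_state": 3 * self.n_state_genes_per_state,
            "n_tgf_genes": self.n_tgf_genes,
            "n_bmp_genes": self.n_bmp_genes,
        }
        total = sum(sizes.values())
        if total > self.n_genes:
            offenders = ", ".join(f"{k}={v}" for k, v in sizes.items() if v > 0)
            raise ValueError(
                f"gene panels need {total} genes but n_genes={self.n_genes} "
                f"(panel sizes: {offenders})"
            )
        return total

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class GenePanel:
    """Disjoint gene-name lists defining the planted programs."""

    arterial: tuple
    venous: tuple
    state_negative: tuple
    state_red: tuple
    state_green: tuple
    tgf: tuple
    bmp: tuple
    housekeeping: tuple

    def all_genes(self) -> tuple:
        return (self.arterial + self.venous + self.state_negative + self.state_red
                + self.state_green + self.tgf + self.bmp + self.housekeeping)

    def state_genes(self, state: str) -> tuple:
        return {
            "NEGATIVE": self.state_negative,
            "RED_G1": self.state_red,
            "GREEN_SG2M": self.state_green,
        }[state]

    def validate(self) -> None:
        lists = [self.arterial, self.venous, self.state_negative, self.state_red,
                 self.state_green, self.tgf, self.bmp, self.housekeeping]
        names = [g for lst in lists for g in lst]
        if len(names) != len(set(names)):
            raise ValueError("gene panel lists must be pairwise disjoint and unique")


@dataclass
class SingleCellDataset:
    """Simulated droplet scRNA-seq dataset with per-cell ground truth."""

    counts: pd.DataFrame            # cells x genes, nonnegative integers
    truth_av_position: np.ndarray   # latent a in [-1, +1]
    truth_state: np.ndarray         # FUCCI state names
    mcherry: np.ndarray
    mvenus: np.ndarray

    @property
    def gene_names(self):
        return self.counts.columns

    @property
    def cell_ids(self):
        return self.counts.index

    def validate(self) -> None:
        n = self.counts.shape[0]
        for name in ("truth_av_position", "truth_state", "mcherry", "mvenus"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match cell count {n}")
        if np.any(self.counts.to_numpy() < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(np.abs(self.truth_av_position) > 1):
            raise ValueError("truth_av_position must lie in [-1, 1]")
        if np.any(self.mcherry < 0) or np.any(self.mvenus < 0):
            raise ValueError("fluorescence intensities must be nonnegative")

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.counts.index,
                "av_position": self.truth_av_position,
                "state": self.truth_state,
                "mcherry": self.mcherry,
                "mvenus": self.mvenus,
            }
        ).set_index("cell_id")


@dataclass
class BulkDataset:
    """Sorted-population bulk RNA-seq: genes x samples with state labels."""

    counts: pd.DataFrame        # genes x samples
    sample_state: pd.Series     # per sample, one of STATES
    replicate: pd.Series        # per sample replicate id

    def validate(self) -> None:
        if list(self.counts.columns) != list(self.sample_state.index):
            raise ValueError("sample_state index must match counts columns")
        present = set(self.sample_state)
        if present != set(STATES):
            raise ValueError(f"sample states must cover exactly {STATES}, got {sorted(present)}")
        vc = self.sample_state.value_counts()
        if (vc < 2).any():
            raise ValueError("every state needs >= 2 replicates")


@dataclass
class NuclearImage:
    """Toy fluorescence image with nuclear/vessel masks and known truth."""

    image: np.ndarray
    nuclear_mask: np.ndarray
    vessel_mask: np.ndarray
    truth_fraction: float = None  # percent, filled in __post_init__ if None

    def __post_init__(self):
        if self.image.shape != self.nuclear_mask.shape or self.image.shape != self.vessel_mask.shape:
            raise ValueError("image and mask shapes must match")
        if np.any(self.image < 0):
            raise ValueError("image intensities must be nonnegative")
        if np.any(self.nuclear_mask & ~self.vessel_mask):
            raise ValueError("nuclear_mask must be contained in vessel_mask")
        vessel_total = float(self.image[self.vessel_mask].sum())
        if vessel_total <= 0:
            raise ValueError("total vessel intensity is zero; nuclear fraction undefined")
        truth = 100.0 * float(self.image[self.nuclear_mask].sum()) / vessel_total
        if self.truth_fraction is None:
            self.truth_fraction = truth


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # Independent, reproducible streams per generator operation.
    return np.random.default_rng([int(config.seed), stream])


def make_gene_panel(config: SimConfig) -> GenePanel:
    """Build the disjoint gene panels for a configuration.

    Arterial/venous/TGF/BMP lists lead with the field's marker gene names
    (Efnb2... / Ephb4... / Smad3... / Smad1...) and continue with synthetic
    names; remaining genes are housekeeping.  Deterministic.
    """
    config.validate()

    def named(markers: Sequence[str], n: int, prefix: str) -> tuple:
        out = list(markers[:n])
        out += [f"{prefix}{i:04d}" for i in range(1, n - len(out) + 1)]
        return tuple(out)

    arterial = named(_ARTERIAL_MARKERS, config.n_arterial_genes, "Art")
    venous = named(_VENOUS_MARKERS, config.n_venous_genes, "Ven")
    tgf = named(_TGF_MARKERS, config.n_tgf_genes, "Tgfx")
    bmp = named(_BMP_MARKERS, config.n_bmp_genes, "Bmpx")
    m = config.n_state_genes_per_state
    state_negative = tuple(f"Sneg{i:04d}" for i in range(1, m + 1))
    state_red = tuple(f"Sred{i:04d}" for i in range(1, m + 1))
    state_green = tuple(f"Sgrn{i:04d}" for i in range(1, m + 1))
    used = (len(arterial) + len(venous) + len(tgf) + len(bmp) + 3 * m)
    housekeeping = tuple(f"Hk{i:05d}" for i in range(1, config.n_genes - used + 1))
    panel = GenePanel(arterial, venous, state_negative, state_red, state_green,
                      tgf, bmp, housekeeping)
    panel.validate()
    return panel


def _softmax_state_probs(a: np.ndarray, beta: float, p_green_base: float) -> np.ndarray:
    """State probabilities (cells x 3, column order = STATES) from AV position."""
    p = np.clip(p_green_base, 1e-12, 1 - 1e-12)
    logit_green = math.log(p / (1 - p))
    logits = np.stack(
        [-beta * a,                    # NEGATIVE: venous side
         beta * a,                     # RED_G1: arterial side
         logit_green - beta * a],      # GREEN: baseline, venous-shifted
        axis=1,
    )
    logits -= logits.max(axis=1, keepdims=True)
    w = np.exp(logits)
    return w / w.sum(axis=1, keepdims=True)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, Var = mean + phi mean^2) via the gamma-Poisson mixture."""
    r = 1.0 / phi
    lam = rng.gamma(shape=r, scale=mean / r)
    return rng.poisson(lam)


def simulate_single_cells(config: SimConfig, panel: GenePanel = None) -> SingleCellDataset:
    """Simulate a single-cell dataset under the latent AV-axis model."""
    config.validate()
    if panel is None:
        panel = make_gene_panel(config)
    genes = list(panel.all_genes())
    if len(genes) != config.n_genes:
        raise ValueError("panel does not match config.n_genes")
    col = {g: j for j, g in enumerate(genes)}
    n, G = config.n_cells, config.n_genes

    rng = _rng(config, 1)
    a = rng.uniform(-1.0, 1.0, size=n)
    probs = _softmax_state_probs(a, config.beta_coupling, config.p_green_base)
    u = rng.random(n)
    state_idx = (u[:, None] >= probs.cumsum(axis=1)).sum(axis=1)
    state = np.asarray(STATES)[state_idx]

    libsize = rng.lognormal(config.libsize_logmean, config.libsize_logsd, size=n)

    # Flat baseline across genes; programs multiply on top.
    mod = np.ones((n, G))
    art_factor = 2.0 ** (config.delta_av * np.maximum(a, 0.0))
    ven_factor = 2.0 ** (config.delta_av * np.maximum(-a, 0.0))
    for g in panel.arterial + panel.tgf:
        mod[:, col[g]] *= art_factor
    for g in panel.venous + panel.bmp:
        mod[:, col[g]] *= ven_factor
    state_gain = 2.0 ** config.delta_state
    for s in STATES:
        in_state = state == s
        idx = [col[g] for g in panel.state_genes(s)]
        if idx:
            mod[np.ix_(in_state, idx)] *= state_gain

    mean = libsize[:, None] * mod / mod.sum(axis=1, keepdims=True)
    counts = _nb_counts(rng, mean, config.nb_dispersion)

    mcherry = np.empty(n)
    mvenus = np.empty(n)
    for s in STATES:
        mask = state == s
        mu_r, mu_g = config.fluor_logmeans[s]
        mcherry[mask] = rng.lognormal(mu_r, config.fluor_logsd, size=mask.sum())
        mvenus[mask] = rng.lognormal(mu_g, config.fluor_logsd, size=mask.sum())

    cell_ids = [f"cell{i:05d}" for i in range(1, n + 1)]
    ds = SingleCellDataset(
        counts=pd.DataFrame(counts, index=cell_ids, columns=genes),
        truth_av_position=a,
        truth_state=state,
        mcherry=mcherry,
        mvenus=mvenus,
    )
    ds.validate()
    return ds


def simulate_bulk_sorted(config: SimConfig, panel: GenePanel = None) -> BulkDataset:
    """Simulate FACS-sorted bulk RNA-seq: three FUCCI states x replicates."""
    config.validate()
    if panel is None:
        panel = make_gene_panel(config)
    genes = list(panel.all_genes())
    col = {g: j for j, g in enumerate(genes)}
    G = len(genes)
    rng = _rng(config, 2)

    profiles = {}
    for s in STATES:
        prof = np.ones(G)
        for g in panel.state_genes(s):
            prof[col[g]] *= 2.0 ** config.delta_state
        profiles[s] = prof / prof.sum()

    columns, states, reps, data = [], [], [], []
    for s in STATES:
        for r in range(1, config.bulk_replicates + 1):
            mean = config.bulk_depth * profiles[s]
            data.append(_nb_counts(rng, mean, config.bulk_dispersion))
            columns.append(f"{s}_rep{r}")
            states.append(s)
            reps.append(r)

    counts = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)
    ds = BulkDataset(
        counts=counts,
        sample_state=pd.Series(states, index=columns, name="state"),
        replicate=pd.Series(reps, index=columns, name="replicate"),
    )
    ds.validate()
    return ds


def simulate_nuclear_image(config: SimConfig, shape=(64, 64)) -> NuclearImage:
    """Toy vessel image: speckled intensity in a vessel band, disk nuclei inside.

    The ground-truth nuclear fraction (percent of vessel intensity inside
    nuclei) is computed by direct pixel summation and stored on the result.
    """
    config.validate()
    rng = _rng(config, 3)
    h, w = shape
    vessel = np.zeros(shape, dtype=bool)
    vessel[h // 4: 3 * h // 4, :] = True

    nuclear = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    n_nuclei = 5
    for _ in range(n_nuclei):
        cy = rng.integers(h // 4 + 3, 3 * h // 4 - 3)
        cx = rng.integers(3, w - 3)
        r = rng.integers(2, 4)
        nuclear |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
    nuclear &= vessel

    image = np.zeros(shape)
    image[vessel] = rng.gamma(shape=2.0, scale=1.0, size=int(vessel.sum()))
    return NuclearImage(image=image, nuclear_mask=nuclear, vessel_mask=vessel)
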