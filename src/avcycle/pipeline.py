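"""End-to-end orchestration: simulate -> gate -> signatures -> impute -> score -> associate.

:func:`analyze` runs the whole analysis in memory and returns every
intermediate; :func:`run_end_to_end` wraps it with file I/O, per-stage
timing, and a reproducibility manifest (config hash, derived seeds, output
checksums).  Per-stage seeds are derived from the global seed and a fixed
stage tag via SHA-256, so adding stages never perturbs earlier streams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from avcycle import io as avio
from avcycle.bulk import de_one_way, extract_state_signatures, normalize_cpm_log
from avcycle.gating import (
    DoublePositivePolicy,
    GatingThresholds,
    assign_fucci_state,
    auto_thresholds,
    state_fractions,
)
from avcycle.imputation import build_operator, impute
from avcycle.scoring import (
    ModuleScoreParams,
    av_scores,
    cellcycle_scores,
    module_score,
    relative_g1,
)
from avcycle.simulate import (
    SimConfig,
    make_gene_panel,
    simulate_bulk_sorted,
    simulate_single_cells,
)
from avcycle.stats import ols_simple

__all__ = ["PipelineConfig", "RunManifest", "PipelineError", "analyze",
           "run_end_to_end", "stage_seed"]

logger = logging.getLogger("avcycle")

_DEFAULT_ASSOCIATIONS = (
    ("relative_g1", "arterial_score"),
    ("relative_g1", "venous_score"),
    ("relative_g1", "tgf_score"),
    ("relative_g1", "bmp_score"),
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""


def stage_seed(global_seed: int, tag: str) -> int:
    """Stable per-stage seed below 2**31 derived from the global seed."""
    digest = hashlib.sha256(f"{int(global_seed)}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Config-file-level view of the whole run."""

    sim: SimConfig = field(default_factory=SimConfig)
    tau_red: float = None            # None -> derive from reporter-negative cells
    tau_green: float = None
    control_quantile: float = 0.99
    double_positive_policy: str = "AS_GREEN"
    q_threshold: float = 0.05
    lfc_threshold: float = 0.5
    t: int = 4
    k: int = 15
    ka: int = 4
    embedding_dims: int = 20
    n_bins: int = 24
    n_ctrl: int = 100
    associations: tuple = _DEFAULT_ASSOCIATIONS
    seed: int = 0

    def __post_init__(self):
        if self.t < 0:
            raise ValueError("diffusion time t must be >= 0")
        valid = {"relative_g1", "arterial_score", "venous_score", "av_score",
                 "tgf_score", "bmp_score", "score_negative", "score_red",
                 "score_green"}
        for x, y in self.associations:
            for v in (x, y):
                if v not in valid:
                    raise ValueError(f"unknown score variable {v!r} in associations")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        assoc = raw.pop("associations", None)
        kwargs = dict(raw, sim=sim)
        if assoc is not None:
            kwargs["associations"] = tuple(tuple(pair) for pair in assoc)
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["sim"]["fluor_logmeans"] = {
            k: list(v) for k, v in payload["sim"]["fluor_logmeans"].items()
        }
        blob = json.dumps(payload, sort_keys=True, default=list).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict
    checksums: dict
    version: str
    timings: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class AnalysisResult:
    """Every intermediate of one end-to-end analysis."""

    panel: object
    sc: object
    bulk: object
    thresholds: GatingThresholds
    labels: np.ndarray
    fractions: pd.DataFrame
    de: pd.DataFrame
    signatures: object
    lognorm: pd.DataFrame
    imputed: pd.DataFrame
    scores: pd.DataFrame
    associations: list


def _lognorm_cells(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-cell log2(CPM + 1) on expressed genes (nonzero in >= 1 cell)."""
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        bad = list(counts.index[totals <= 0])
        raise ValueError(f"cell(s) with zero total counts: {bad[:5]}")
    expressed = counts.columns[(counts > 0).any(axis=0)]
    cpm = counts[expressed].div(totals, axis=0) * 1e6
    return np.log2(1.0 + cpm)


def analyze(config: PipelineConfig) -> AnalysisResult:
    """Run the full analysis in memory on synthetic data."""
    seeds = {tag: stage_seed(config.seed, tag)
             for tag in ("simulate", "scoring")}
    sim = replace(config.sim, seed=seeds["simulate"])

    panel = make_gene_panel(sim)
    sc = simulate_single_cells(sim, panel)
    bulk = simulate_bulk_sorted(sim, panel)

    # gating: thresholds from config, else from simulated reporter-negative cells
    if config.tau_red is not None and config.tau_green is not None:
        thresholds = GatingThresholds(
            config.tau_red, config.tau_green,
            DoublePositivePolicy(config.double_positive_policy))
    else:
        neg = sc.truth_state == "NEGATIVE"
        if not neg.any():
            raise ValueError("no reporter-negative cells to derive thresholds from")
        thresholds = auto_thresholds(
            sc.mcherry[neg], sc.mvenus[neg], config.control_quantile,
            DoublePositivePolicy(config.double_positive_policy))
    labels = assign_fucci_state(sc.mcherry, sc.mvenus, thresholds)
    side = np.where(sc.truth_av_position >= 0, "arterial_side", "venous_side")
    fractions = state_fractions(labels, side)

    norm = normalize_cpm_log(bulk)
    de = de_one_way(norm, bulk.sample_state)
    signatures = extract_state_signatures(de, config.q_threshold, config.lfc_threshold)

    lognorm = _lognorm_cells(sc.counts)
    op = build_operator(lognorm, k=config.k, ka=config.ka,
                        embedding_dims=config.embedding_dims, t=config.t)
    imputed = impute(lognorm, op)

    params = ModuleScoreParams(n_bins=config.n_bins, n_ctrl=config.n_ctrl,
                               seed=seeds["scoring"])
    s_neg, s_red, s_green = cellcycle_scores(lognorm, signatures, params)
    tgf = module_score(lognorm, panel.tgf, params).rename("tgf_score")
    bmp = module_score(lognorm, panel.bmp, params).rename("bmp_score")
    s_art, s_ven, s_av = av_scores(imputed, panel.arterial, panel.venous)
    dg1 = relative_g1(s_red, s_neg)
    scores = pd.concat([s_neg, s_red, s_green, tgf, bmp, s_art, s_ven, s_av, dg1],
                       axis=1)

    associations = []
    for x, y in config.associations:
        res = ols_simple(scores[x], scores[y])
        associations.append({
            "x": x, "y": y, "slope": res.slope, "intercept": res.intercept,
            "r_squared": res.r_squared, "t_statistic": res.t_statistic,
            "p_value": res.p_value, "n": res.n,
        })

    return AnalysisResult(panel=panel, sc=sc, bulk=bulk, thresholds=thresholds,
                          labels=labels, fractions=fractions, de=de,
                          signatures=signatures, lognorm=lognorm, imputed=imputed,
                          scores=scores, associations=associations)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_end_to_end(config: PipelineConfig, outdir, seed: int = None) -> RunManifest:
    """Run the pipeline and persist every artifact plus a manifest.

    Any stage failure writes a FAILED marker (partial outputs are kept) and
    re-raises as :class:`PipelineError` naming the stage.
    """
    from avcycle import __version__

    if seed is not None:
        config = replace(config, seed=int(seed))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    timings = {}
    t0 = time.perf_counter()
    stage = "analyze"
    try:
        result = analyze(config)
        timings["analyze"] = time.perf_counter() - t0

        stage = "write_outputs"
        t1 = time.perf_counter()
        avio.write_expression(outdir / "matrix.mtx", result.sc.counts)
        result.sc.truth_frame().to_csv(outdir / "truth.tsv", sep="\t")
        result.bulk.counts.to_csv(outdir / "bulk_counts.tsv", sep="\t", index_label="gene")
        pd.DataFrame({"sample": result.bulk.sample_state.index,
                      "state": result.bulk.sample_state.values,
                      "replicate": result.bulk.replicate.values}
                     ).to_csv(outdir / "bulk_samples.tsv", sep="\t", index=False)
        panel = result.panel
        avio.write_gmt(outdir / "panels.gmt", {
            "ARTERIAL": panel.arterial, "VENOUS": panel.venous,
            "TGF_SIGNALING": panel.tgf, "BMP_SIGNALING": panel.bmp,
        })
        pd.DataFrame({"cell_id": result.sc.counts.index,
                      "label": [l.value for l in result.labels]}
                     ).to_csv(outdir / "labels.tsv", sep="\t", index=False)
        result.fractions.to_csv(outdir / "fractions.tsv", sep="\t", index=False)
        result.de.to_csv(outdir / "de_results.tsv", sep="\t", index_label="gene")
        avio.write_gmt(outdir / "signatures.gmt", {
            f"FUCCI_{k}": v for k, v in result.signatures.as_dict().items()
        })
        result.imputed.round(6).to_csv(outdir / "imputed.tsv", sep="\t",
                                       index_label="cell_id")
        result.scores.to_csv(outdir / "scores.tsv", sep="\t", index_label="cell_id")
        with open(outdir / "associations.json", "w", encoding="utf-8") as fh:
            json.dump(result.associations, fh, indent=2)
        timings["write_outputs"] = time.perf_counter() - t1
    except Exception as e:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {e}\n")
        raise PipelineError(f"pipeline stage {stage!r} failed: {e}") from e

    checksums = {p.name: _sha256(p) for p in sorted(outdir.iterdir())
                 if p.is_file() and p.name not in {"manifest.json", "FAILED"}}
    manifest = RunManifest(
        config_hash=config.config_hash(),
        seeds={tag: stage_seed(config.seed, tag) for tag in ("simulate", "scoring")},
        checksums=checksums,
        version=__version__,
        timings=timings,
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    logger.info("pipeline finished: %s", outdir)
    return manifest
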