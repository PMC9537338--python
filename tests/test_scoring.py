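"""Module scores, signaling/cell-cycle scores, arterial-venous scores."""

import numpy as np
import pandas as pd
import pytest

from avcycle.bulk import SignatureSet
from avcycle.scoring import (
    BMP_GENES,
    TGF_GENES,
    ModuleScoreParams,
    av_scores,
    cellcycle_scores,
    module_score,
    relative_g1,
    signaling_scores,
)
from avcycle.simulate import simulate_single_cells
from tests.conftest import scaled_config

PARAMS = ModuleScoreParams(n_bins=4, n_ctrl=10, seed=0)


def _matrix(rng, n_cells=30, n_genes=40):
    genes = [f"g{i}" for i in range(n_genes)]
    return pd.DataFrame(rng.normal(size=(n_cells, n_genes)),
                        index=[f"c{i}" for i in range(n_cells)], columns=genes)


def _lognorm(ds):
    counts = ds.counts
    cpm = counts.div(counts.sum(axis=1), axis=0) * 1e6
    return np.log2(1 + cpm)


class TestModuleScore:
    def test_bin_identical_genes_score_zero(self, rng):
        # every gene identical -> controls cancel the signature exactly
        col = rng.normal(size=30)
        expr = pd.DataFrame(np.tile(col[:, None], (1, 40)),
                            columns=[f"g{i}" for i in range(40)])
        s = module_score(expr, ["g3", "g7"], PARAMS)
        assert np.all(np.abs(s) < 1e-12)

    def test_constant_shift_invariance(self, rng):
        expr = _matrix(rng)
        s1 = module_score(expr, ["g0", "g5", "g9"], PARAMS)
        s2 = module_score(expr + 3.7, ["g0", "g5", "g9"], PARAMS)
        assert np.allclose(s1, s2)

    def test_seed_determinism_and_cell_permutation(self, rng):
        expr = _matrix(rng)
        s1 = module_score(expr, ["g1", "g2"], PARAMS)
        s2 = module_score(expr, ["g1", "g2"], PARAMS)
        assert s1.equals(s2)
        perm = rng.permutation(expr.index)
        s3 = module_score(expr.loc[perm], ["g1", "g2"], PARAMS)
        assert np.allclose(s3.loc[s1.index], s1)

    def test_missing_genes_dropped_with_warning(self, rng):
        expr = _matrix(rng)
        with pytest.warns(UserWarning, match="dropping"):
            module_score(expr, ["g0", "nope"], PARAMS)
        with pytest.raises(ValueError, match="no genes"):
            module_score(expr, ["nope"], PARAMS)

    def test_planted_program_scores_higher_in_state(self):
        cfg = scaled_config(seed=1)
        ds = simulate_single_cells(cfg)
        expr = _lognorm(ds)
        from avcycle.simulate import make_gene_panel

        panel = make_gene_panel(cfg)
        s = module_score(expr, panel.state_red, ModuleScoreParams(seed=1))
        in_state = s[ds.truth_state == "RED_G1"].mean()
        out_state = s[ds.truth_state != "RED_G1"].mean()
        assert in_state - out_state > 0.2


class TestSignaling:
    def test_default_list_sizes(self):
        assert len(TGF_GENES) == 7 and len(BMP_GENES) == 3

    def test_constant_matrix_scores_zero(self):
        expr = pd.DataFrame(np.ones((10, 30)),
                            columns=list(TGF_GENES) + list(BMP_GENES)
                            + [f"g{i}" for i in range(20)])
        tgf, bmp = signaling_scores(expr, params=ModuleScoreParams(n_bins=3, n_ctrl=5, seed=0))
        assert np.all(tgf == 0) and np.all(bmp == 0)

    def test_tgf_tracks_arterial_axis(self):
        cfg = scaled_config(n_cells=1000, seed=1)
        ds = simulate_single_cells(cfg)
        from avcycle.simulate import make_gene_panel

        panel = make_gene_panel(cfg)
        tgf, bmp = signaling_scores(_lognorm(ds), panel.tgf, panel.bmp,
                                    ModuleScoreParams(seed=1))
        r_tgf = np.corrcoef(tgf, ds.truth_av_position)[0, 1]
        r_bmp = np.corrcoef(bmp, ds.truth_av_position)[0, 1]
        assert r_tgf > 0.3 and r_bmp < -0.3


class TestCellCycleScores:
    def test_empty_signature_names_state(self, rng):
        sigs = SignatureSet(("g0",), (), ("g1",))
        with pytest.raises(ValueError, match="RED_G1"):
            cellcycle_scores(_matrix(rng), sigs, PARAMS)

    def test_truth_red_cells_score_higher(self):
        cfg = scaled_config(seed=1)
        ds = simulate_single_cells(cfg)
        from avcycle.simulate import make_gene_panel

        panel = make_gene_panel(cfg)
        sigs = SignatureSet(panel.state_negative, panel.state_red, panel.state_green)
        s_neg, s_red, _ = cellcycle_scores(_lognorm(ds), sigs, ModuleScoreParams(seed=1))
        gap = (s_red[ds.truth_state == "RED_G1"].mean()
               - s_red[ds.truth_state == "NEGATIVE"].mean())
        assert gap > 0.1


class TestAvScores:
    def test_identical_profiles_give_zero_av(self, rng):
        base = rng.normal(size=(20, 1))
        expr = pd.DataFrame(np.hstack([base, base]), columns=["a1", "v1"])
        _, _, s_av = av_scores(expr, ["a1"], ["v1"])
        assert np.allclose(s_av, 0)

    def test_one_sd_contrast_gives_av_two(self, rng):
        # one cell at +1 sd on arterial and -1 sd on venous genes
        n = 16
        art = np.zeros((n, 2))
        ven = np.zeros((n, 2))
        art[:: 2] = 1.0   # half the cells high -> sd 0.5, mean 0.5
        ven[1:: 2] = 1.0
        expr = pd.DataFrame(np.hstack([art, ven]), columns=["a1", "a2", "v1", "v2"])
        _, _, s_av = av_scores(expr, ["a1", "a2"], ["v1", "v2"])
        assert s_av.iloc[0] == pytest.approx(2.0)

    def test_antisymmetry_under_list_swap(self, rng):
        expr = _matrix(rng)
        _, _, fwd = av_scores(expr, ["g0", "g1"], ["g2", "g3"])
        _, _, rev = av_scores(expr, ["g2", "g3"], ["g0", "g1"])
        assert np.allclose(fwd, -rev)

    def test_zscores_standardized(self, rng):
        expr = _matrix(rng)
        s_art, _, _ = av_scores(expr, ["g0"], ["g1"])
        assert s_art.mean() == pytest.approx(0, abs=1e-12)
        assert s_art.std(ddof=0) == pytest.approx(1, abs=1e-12)

    def test_all_zero_variance_rejected(self):
        expr = pd.DataFrame(np.ones((5, 2)), columns=["a", "v"])
        with pytest.raises(ValueError, match="zero variance"):
            av_scores(expr, ["a"], ["v"])

    def test_recovers_av_axis_on_simulated_cells(self):
        from avcycle.imputation import build_operator, impute
        from avcycle.simulate import make_gene_panel

        cfg = scaled_config(seed=1)
        panel = make_gene_panel(cfg)
        ds = simulate_single_cells(cfg, panel)
        expr = _lognorm(ds)
        op = build_operator(expr, k=15, ka=4, embedding_dims=20, t=4)
        _, _, s_av = av_scores(impute(expr, op), panel.arterial, panel.venous)
        assert np.corrcoef(s_av, ds.truth_av_position)[0, 1] > 0.5


class TestRelativeG1:
    def test_subtraction_and_antisymmetry(self):
        red = pd.Series([0.5, 0.2])
        neg = pd.Series([0.2, 0.2])
        d = relative_g1(red, neg)
        assert d.iloc[0] == pytest.approx(0.3) and d.iloc[1] == 0
        assert np.allclose(relative_g1(neg, red), -d)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            relative_g1(pd.Series([1.0]), pd.Series([1.0, 2.0]))
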