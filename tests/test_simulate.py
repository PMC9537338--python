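"""Synthetic-data generator: panels, count model, coupling, fixtures."""

import numpy as np
import pytest
from scipy import stats as sps

from avcycle.simulate import (
    STATES,
    NuclearImage,
    SimConfig,
    make_gene_panel,
    simulate_bulk_sorted,
    simulate_nuclear_image,
    simulate_single_cells,
)
from tests.conftest import scaled_config


class TestGenePanel:
    def test_marker_names_lead_the_program_lists(self):
        cfg = SimConfig(n_cells=10, n_genes=100, n_arterial_genes=7, n_venous_genes=6,
                        n_state_genes_per_state=5, n_tgf_genes=7, n_bmp_genes=3)
        panel = make_gene_panel(cfg)
        assert panel.arterial[0] == "Efnb2"
        assert panel.venous[0] == "Ephb4"
        assert panel.tgf == ("Smad3", "Tgfbr1", "Tgfbr2", "Smad6", "Acvrl1", "Tgfb1", "Tgfb2")
        assert panel.bmp == ("Smad1", "Smad5", "Bmpr2")

    def test_empty_panels_leave_all_genes_housekeeping(self):
        cfg = SimConfig(n_cells=10, n_genes=50, n_arterial_genes=0, n_venous_genes=0,
                        n_state_genes_per_state=0, n_tgf_genes=0, n_bmp_genes=0)
        panel = make_gene_panel(cfg)
        assert panel.arterial == () and panel.venous == ()
        assert len(panel.housekeeping) == 50

    def test_panel_lists_disjoint_and_cover_gene_index(self):
        panel = make_gene_panel(scaled_config())
        genes = panel.all_genes()
        assert len(genes) == len(set(genes)) == 1500

    def test_panel_overflow_names_the_sizes(self):
        cfg = SimConfig(n_cells=10, n_genes=50, n_arterial_genes=40, n_venous_genes=40)
        with pytest.raises(ValueError, match="n_arterial_genes"):
            make_gene_panel(cfg)

    def test_deterministic_given_seed(self):
        cfg = scaled_config(seed=7)
        assert make_gene_panel(cfg) == make_gene_panel(cfg)


def _softmax_oracle_spearman(beta, p_green_base, n, seed):
    """Monte-Carlo Spearman(a, 1[state=RED_G1]) straight from the softmax link."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(-1, 1, n)
    logit_g = np.log(p_green_base / (1 - p_green_base))
    logits = np.stack([-beta * a, beta * a, logit_g - beta * a], axis=1)
    w = np.exp(logits - logits.max(axis=1, keepdims=True))
    p = w / w.sum(axis=1, keepdims=True)
    state = (rng.random(n)[:, None] >= p.cumsum(axis=1)).sum(axis=1)
    return sps.spearmanr(a, state == 1).statistic


class TestSingleCells:
    def test_no_coupling_makes_state_independent_of_av_side(self):
        cfg = scaled_config(n_cells=5000, beta_coupling=0.0, seed=3)
        ds = simulate_single_cells(cfg)
        side = ds.truth_av_position >= 0
        table = [[np.sum((ds.truth_state == s) & (side == v)) for s in STATES]
                 for v in (False, True)]
        p = sps.chi2_contingency(np.array(table)).pvalue
        assert p > 0.01

    def test_null_model_gene_means_flat(self):
        cfg = scaled_config(n_cells=5000, delta_state=0.0, delta_av=0.0, seed=4)
        ds = simulate_single_cells(cfg)
        per_gene = ds.counts.mean(axis=0).to_numpy()
        ratio = per_gene / per_gene.mean()
        assert ratio.min() > 0.9 and ratio.max() < 1.1

    def test_av_state_coupling_matches_softmax_oracle(self):
        # oracle first: the stated softmax alone produces this association level
        oracle = _softmax_oracle_spearman(beta=1.5, p_green_base=0.2, n=20000, seed=0)
        assert oracle > 0.3
        cfg = scaled_config(n_cells=2000, beta_coupling=1.5, seed=1)
        ds = simulate_single_cells(cfg)
        rho = sps.spearmanr(ds.truth_av_position, ds.truth_state == "RED_G1").statistic
        assert rho > 0.3
        assert abs(rho - oracle) < 0.1

    def test_nb_dispersion_recovered_from_moments(self):
        # fixed size factors isolate the NB law Var = mu + phi mu^2
        cfg = scaled_config(n_cells=5000, delta_state=0.0, delta_av=0.0,
                            libsize_logsd=0.0, seed=5)
        ds = simulate_single_cells(cfg)
        X = ds.counts.to_numpy(dtype=float)
        mu = X.mean(axis=0)
        var = X.var(axis=0, ddof=1)
        phi_hat = np.sum((var - mu) * mu**2) / np.sum(mu**4)
        assert phi_hat == pytest.approx(cfg.nb_dispersion, rel=0.2)

    def test_reproducible_bitwise(self):
        cfg = scaled_config(seed=11)
        d1 = simulate_single_cells(cfg)
        d2 = simulate_single_cells(cfg)
        assert d1.counts.equals(d2.counts)
        assert np.array_equal(d1.truth_av_position, d2.truth_av_position)
        assert np.array_equal(d1.mcherry, d2.mcherry)

    def test_fluorescence_state_separation(self, small_sim):
        _, _, ds = small_sim
        red = ds.truth_state == "RED_G1"
        assert np.median(ds.mcherry[red]) > 10 * np.median(ds.mcherry[~red])


class TestBulk:
    def test_nine_samples_three_per_state(self):
        ds = simulate_bulk_sorted(scaled_config(bulk_replicates=3))
        assert ds.counts.shape[1] == 9
        assert (ds.sample_state.value_counts() == 3).all()

    def test_null_log_ratios_centered_at_zero(self):
        cfg = SimConfig(n_cells=10, n_genes=5000, delta_state=0.0, bulk_depth=1e6, seed=2)
        ds = simulate_bulk_sorted(cfg)
        by_state = ds.counts.T.groupby(ds.sample_state).mean().T
        lr = np.log2((by_state["RED_G1"] + 0.5) / (by_state["NEGATIVE"] + 0.5))
        assert abs(np.median(lr)) < 0.05

    def test_planted_gene_fold_change(self):
        cfg = SimConfig(n_cells=10, n_genes=5000, delta_state=1.0, bulk_depth=1e6, seed=7)
        panel = make_gene_panel(cfg)
        ds = simulate_bulk_sorted(cfg, panel)
        g = panel.state_red[0]
        red = ds.sample_state == "RED_G1"
        ratio = ds.counts.loc[g, red.values].mean() / ds.counts.loc[g, ~red.values].mean()
        assert 1.7 <= ratio <= 2.3

    def test_bad_depth_rejected(self):
        with pytest.raises(ValueError, match="bulk_depth"):
            simulate_bulk_sorted(scaled_config(bulk_depth=0))


class TestNuclearImage:
    def test_uniform_field_fraction_is_mask_area_ratio(self):
        vessel = np.zeros((8, 8), dtype=bool)
        vessel[2:6, :] = True
        nuclear = np.zeros_like(vessel)
        nuclear[2:3, 0:8] = True  # 8 of 32 vessel pixels
        img = NuclearImage(np.ones((8, 8)), nuclear, vessel)
        assert img.truth_fraction == pytest.approx(25.0)

    def test_zero_image_refused(self):
        vessel = np.ones((4, 4), dtype=bool)
        with pytest.raises(ValueError, match="zero"):
            NuclearImage(np.zeros((4, 4)), vessel, vessel)

    def test_nucleus_outside_vessel_refused(self):
        vessel = np.zeros((4, 4), dtype=bool)
        vessel[0] = True
        nuclear = np.zeros_like(vessel)
        nuclear[3] = True
        with pytest.raises(ValueError, match="contained"):
            NuclearImage(np.ones((4, 4)), nuclear, vessel)

    def test_speckle_truth_matches_direct_summation(self):
        img = simulate_nuclear_image(scaled_config(seed=5))
        direct = 100.0 * img.image[img.nuclear_mask].sum() / img.image[img.vessel_mask].sum()
        assert img.truth_fraction == pytest.approx(direct, abs=1e-12)
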