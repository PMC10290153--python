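"""Chemometric primitives: filtering, scaling, PCA, PLS-DA VIP, screen."""

import warnings

import numpy as np
import pandas as pd
import pytest

from trfscan import metabolomics as mb
from trfscan import simulate
from trfscan.config import SimConfig
from trfscan.errors import ConfigError, DataError


def _table(rows, cols):
    return pd.DataFrame(rows, index=[f"m{i}" for i in range(len(rows))],
                        columns=cols)


class TestPrevalenceFilter:
    COLS = [f"coarse_{i}" for i in range(5)] + [f"fine_{i}" for i in range(5)]
    ROLES = {c: c.rsplit("_", 1)[0] for c in COLS}

    def test_kept_when_majority_nonzero_in_one_group(self):
        row = [1, 1, 1, 0, 0] + [0] * 5  # 3/5 in coarse, 0/5 in fine
        out = mb.prevalence_filter(_table([row], self.COLS), self.ROLES)
        assert len(out) == 1

    def test_exactly_half_dropped(self):
        # strict >0.5 gate: use even group sizes so 50% is attainable
        cols = [f"coarse_{i}" for i in range(4)] + [f"fine_{i}" for i in range(4)]
        roles = {c: c.rsplit("_", 1)[0] for c in cols}
        half = [1, 1, 0, 0] + [1, 1, 0, 0]
        out = mb.prevalence_filter(_table([half], cols), roles)
        assert len(out) == 0

    def test_all_zero_dropped(self):
        out = mb.prevalence_filter(_table([[0] * 10], self.COLS), self.ROLES)
        assert len(out) == 0

    def test_qc_excluded_from_test(self):
        cols = self.COLS + ["QC_1", "QC_2"]
        roles = {**self.ROLES, "QC_1": "QC", "QC_2": "QC"}
        row = [0] * 10 + [5, 5]  # nonzero only in QC
        out = mb.prevalence_filter(_table([row], cols), roles)
        assert len(out) == 0


class TestNormalizeTotalIntensity:
    def test_doubled_column_restored(self):
        base = np.array([1.0, 2.0, 3.0])
        t = _table(np.column_stack([base, 2 * base, base]).tolist(),
                   ["a", "b", "c"])
        out = mb.normalize_total_intensity(t)
        assert np.allclose(out["a"], out["b"])

    def test_column_sums_equal_after(self):
        rng = np.random.default_rng(1)
        t = _table(rng.uniform(0.1, 5, size=(20, 6)).tolist(),
                   [f"s{i}" for i in range(6)])
        out = mb.normalize_total_intensity(t)
        sums = out.sum(axis=0)
        assert np.allclose(sums, sums.iloc[0])

    def test_zero_sum_column_rejected(self):
        t = _table([[0.0, 1.0]], ["a", "b"])
        with pytest.raises(DataError):
            mb.normalize_total_intensity(t)


class TestParetoScale:
    def test_closed_form_two_samples(self):
        t = _table([[1.0, 3.0]], ["a", "b"])
        out = mb.pareto_scale(t)
        expected = 1.0 / 2 ** 0.25  # (x - 2) / sqrt(sqrt(2))
        assert out.iloc[0].tolist() == pytest.approx([-expected, expected])

    def test_constant_row_zeroed_with_warning(self):
        t = _table([[5.0, 5.0, 5.0]], ["a", "b", "c"])
        with pytest.warns(UserWarning):
            out = mb.pareto_scale(t)
        assert (out.values == 0).all()

    def test_row_means_zero(self):
        rng = np.random.default_rng(2)
        t = _table(rng.uniform(1, 9, size=(10, 5)).tolist(),
                   [f"s{i}" for i in range(5)])
        out = mb.pareto_scale(t)
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-12)


class TestPca:
    def test_rank_one_matrix_single_component(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([1.0, -1.0, 0.5])
        t = pd.DataFrame(np.outer(u - u.mean(), v),
                         columns=["s1", "s2", "s3"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, _, vf = mb.pca_scores(t, 2)
        assert vf[0] == pytest.approx(1.0)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(3)
        t = pd.DataFrame(rng.normal(size=(12, 6)),
                         columns=[f"s{i}" for i in range(6)])
        t = t.sub(t.mean(axis=1), axis=0)
        scores, loadings, _ = mb.pca_scores(t, 6)
        k = scores.shape[1]
        recon = scores.to_numpy() @ loadings.to_numpy().T
        assert np.max(np.abs(recon - t.to_numpy().T)) < 1e-8

    def test_orthonormal_loadings_and_ordered_variance(self):
        rng = np.random.default_rng(4)
        t = pd.DataFrame(rng.normal(size=(15, 8)),
                         columns=[f"s{i}" for i in range(8)])
        _, loadings, vf = mb.pca_scores(t, 4)
        L = loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(4), atol=1e-10)
        assert all(vf[i] >= vf[i + 1] for i in range(len(vf) - 1))

    def test_qc_clusters_tighter_than_groups(self):
        cfg = SimConfig(seed=6, n_per_group=10)
        table, roles, _ = simulate.simulate_metabolome(cfg)
        kept = mb.prevalence_filter(table, roles)
        norm = mb.normalize_total_intensity(kept)
        scaled = mb.pareto_scale(norm)
        scores, _, _ = mb.pca_scores(scaled, 2)
        d = mb.qc_tightness(scores, roles)
        assert d["qc_mean_distance"] < d["between_group_mean_distance"]


class TestPlsdaVip:
    def _roles(self, n):
        cols = [f"coarse_{i}" for i in range(n)] + [f"fine_{i}" for i in range(n)]
        return cols, {c: c.rsplit("_", 1)[0] for c in cols}

    def test_single_informative_variable_limit(self):
        """Noiseless one-informative-variable design: VIP -> sqrt(p) for the
        informative variable, ~0 elsewhere."""
        cols, roles = self._roles(5)
        p = 8
        rows = np.zeros((p, 10))
        rows[0] = [1.0] * 5 + [-1.0] * 5
        rng = np.random.default_rng(0)
        rows[1:] += rng.normal(0, 1e-9, size=(p - 1, 10))  # break degeneracy
        vip = mb.plsda_vip(pd.DataFrame(rows, columns=cols), roles, 1)
        assert vip.scores.iloc[0] == pytest.approx(np.sqrt(p), rel=1e-6)
        assert (vip.scores.iloc[1:] < 1e-3).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_mean_squared_vip_is_one(self, seed):
        cols, roles = self._roles(6)
        rng = np.random.default_rng(seed)
        t = pd.DataFrame(rng.normal(size=(30, 12)), columns=cols)
        vip = mb.plsda_vip(t, roles, 2)
        assert float((vip.scores ** 2).mean()) == pytest.approx(1.0, abs=1e-9)
        assert (vip.scores >= 0).all()

    def test_single_sample_group_rejected(self):
        cols = ["coarse_1", "fine_1", "fine_2"]
        roles = {c: c.rsplit("_", 1)[0] for c in cols}
        t = pd.DataFrame(np.ones((4, 3)), columns=cols)
        with pytest.raises(ConfigError):
            mb.plsda_vip(t, roles, 1)

    def test_permuted_labels_suppress_planted_vip(self):
        """Permuting class labels destroys the planted VIP signal."""
        cfg = SimConfig(seed=8, n_per_group=10)
        table, roles, truth = simulate.simulate_metabolome(cfg)
        kept = mb.prevalence_filter(table, roles)
        scaled = mb.pareto_scale(mb.normalize_total_intensity(kept))
        vip_true = mb.plsda_vip(scaled, roles, 2)
        rng = np.random.default_rng(0)
        planted = [m for m in truth["discriminators"] if m in scaled.index]
        perm_means = []
        for _ in range(20):
            roles_perm = mb.permuted_roles(roles, rng)
            vip_perm = mb.plsda_vip(scaled, roles_perm, 2)
            perm_means.append(vip_perm.scores[planted].mean())
        assert vip_true.scores[planted].mean() > np.quantile(perm_means, 0.95)


class TestScreen:
    def test_sequential_gates(self):
        vip = mb.VipScores(pd.Series({"m0": 1.5, "m1": 0.9, "m2": 1.2}), 1)
        stats = pd.DataFrame({"fold": [2.0, 3.0, 1.1],
                              "t_stat": [5.0, 9.0, 0.1],
                              "p_value": [0.01, 1e-6, 0.6]},
                             index=["m0", "m1", "m2"])
        sig = mb.screen_metabolites(vip, stats)
        assert list(sig.index) == ["m0"]  # m1 fails VIP gate, m2 fails p gate


def test_pipeline_stage_order(tmp_path):
    """The staged metabolome run must equal the documented processing order:
    filter -> normalize -> Pareto -> PLS/t-test -> screen."""
    from trfscan.config import PipelineConfig
    from trfscan.pipeline import run_stage

    cfg = PipelineConfig.from_dict({
        "seed": 5, "outdir": str(tmp_path / "run"),
        "sim": {"read_depth": 2000, "protein_count": 50,
                "n_up_proteins": 5, "n_down_proteins": 5,
                "n_extra_targets": 5}})
    run_stage("simulate", cfg)
    run_stage("metabolome", cfg)
    sig_stage = pd.read_csv(tmp_path / "run" / "significant_metabolites.tsv",
                            sep="\t", index_col=0)
    table = pd.read_csv(tmp_path / "run" / "metabolome.tsv", sep="\t",
                        index_col=0).fillna(0.0)
    roles = {c: ("QC" if c.startswith("QC") else c.rsplit("_", 1)[0])
             for c in table.columns}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm = mb.normalize_total_intensity(mb.prevalence_filter(table, roles))
        scaled = mb.pareto_scale(norm)
        vip = mb.plsda_vip(scaled, roles, 2, group_pair=("coarse", "fine"))
        stats = mb.group_ttest_table(norm, roles, group_pair=("coarse", "fine"))
        manual = mb.screen_metabolites(vip, stats)
    assert list(sig_stage.index) == list(manual.index)
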