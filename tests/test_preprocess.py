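import numpy as np
import pandas as pd
import pytest
from scipy import stats

from avmeth.data_model import AnalysisConfig, ArrayDataset
from avmeth.preprocess import (
    compute_beta_m,
    compute_detection_p,
    global_methylation,
    hierarchical_cluster,
    normalize_type2,
    probe_cv,
    qc_filter,
    select_variable_probes,
    top_variable,
)
from avmeth.simulate import TruthSpec, simulate_dataset, simulate_manifest

from conftest import make_manifest, make_sheet, matrices_from_beta


def build_dataset(meth, unmeth, detp=None, negctrl=None, manifest_specs=None, n_pairs=None):
    probes = list(meth.index)
    n_pairs = n_pairs or len(meth.columns) // 2
    sheet = make_sheet(n_pairs)
    manifest = make_manifest(
        manifest_specs or [{"probe_id": p} for p in probes]
    )
    return ArrayDataset(
        annotation=manifest,
        meth=meth,
        unmeth=unmeth,
        detection_p=detp,
        samples=sheet,
        negctrl=negctrl,
    )


class TestDetectionP:
    def _dataset(self, probe_totals, ctrl_mu=100.0, ctrl_sd=10.0, n_ctrl=20):
        samples = ["A1", "V1"]
        n = len(probe_totals)
        meth = pd.DataFrame(
            {s: np.asarray(probe_totals) / 2 for s in samples},
            index=[f"cg{i:06d}" for i in range(n)],
        )
        unmeth = meth.copy()
        rng = np.random.default_rng(1)
        ctrl = pd.DataFrame(
            rng.normal(ctrl_mu, ctrl_sd, size=(n_ctrl, 2)),
            index=[f"nc{i}" for i in range(n_ctrl)],
            columns=samples,
        )
        return build_dataset(meth, unmeth, negctrl=ctrl, n_pairs=1), ctrl

    def test_probe_at_background_mean_has_p_half(self):
        ds, ctrl = self._dataset([1000.0])
        mu = ctrl["A1"].mean()
        ds.meth.iloc[0, 0] = mu / 2
        ds.unmeth.iloc[0, 0] = mu / 2
        p = compute_detection_p(ds)
        assert p.iloc[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_bright_probe_has_negligible_p(self):
        ds, ctrl = self._dataset([1000.0])
        mu, sd = ctrl["A1"].mean(), ctrl["A1"].std(ddof=1)
        ds.meth.iloc[0, 0] = (mu + 10 * sd) / 2
        ds.unmeth.iloc[0, 0] = (mu + 10 * sd) / 2
        p = compute_detection_p(ds)
        assert p.iloc[0, 0] < 1e-15

    def test_matches_closed_form_normal_tail(self):
        ds, ctrl = self._dataset([150.0, 300.0, 1000.0])
        p = compute_detection_p(ds)
        for col in p.columns:
            mu = ctrl[col].mean()
            sd = ctrl[col].std(ddof=1)
            total = (ds.meth[col] + ds.unmeth[col]).to_numpy()
            expected = stats.norm.sf((total - mu) / sd)
            assert np.allclose(p[col].to_numpy(), expected, atol=1e-12)

    def test_too_few_controls_is_error(self):
        ds, _ = self._dataset([100.0], n_ctrl=5)
        with pytest.raises(ValueError, match="negative-control"):
            compute_detection_p(ds)


class TestQcFilter:
    def test_single_sample_failure_removes_probe(self, config):
        n = 5
        probes = [f"cg{i:06d}" for i in range(n)]
        samples = make_sheet(9).sample_ids
        meth = pd.DataFrame(500.0, index=probes, columns=samples)
        detp = pd.DataFrame(1e-6, index=probes, columns=samples)
        detp.iloc[2, 7] = 0.06  # fails in exactly 1 of 18 samples
        ds = build_dataset(meth, meth.copy(), detp=detp, n_pairs=9)
        out = qc_filter(ds, config)
        assert probes[2] not in out.probe_ids
        assert len(out.probe_ids) == n - 1

    def test_sex_probe_removed_despite_perfect_detection(self, config):
        probes = ["cg000000", "cg000001"]
        samples = make_sheet(2).sample_ids
        meth = pd.DataFrame(500.0, index=probes, columns=samples)
        detp = pd.DataFrame(1e-6, index=probes, columns=samples)
        specs = [{"probe_id": probes[0], "chromosome": "X"}, {"probe_id": probes[1]}]
        ds = build_dataset(meth, meth.copy(), detp=detp, manifest_specs=specs)
        out = qc_filter(ds, config)
        assert out.probe_ids == [probes[1]]

    def test_counting_oracle_on_mixed_fixture(self, config):
        # 100 probes: 7 fail detection, 5 sex-chromosomal, 1 in both -> 89 left
        n = 100
        probes = [f"cg{i:06d}" for i in range(n)]
        samples = make_sheet(3).sample_ids
        meth = pd.DataFrame(500.0, index=probes, columns=samples)
        detp = pd.DataFrame(1e-6, index=probes, columns=samples)
        failing = list(range(7))
        sex = list(range(6, 11))  # probe 6 fails both
        for i in failing:
            detp.iloc[i, 0] = 0.2
        specs = [
            {"probe_id": p, "chromosome": "X" if i in sex else "1"}
            for i, p in enumerate(probes)
        ]
        ds = build_dataset(meth, meth.copy(), detp=detp, manifest_specs=specs)
        out = qc_filter(ds, config)
        log = out.qc_meta["qc_log"]
        assert log["n_failed_detection"] == 7
        assert log["n_sex_chromosome"] == 5
        assert log["n_failed_both"] == 1
        assert log["n_kept"] == 89

    def test_clean_fixture_loses_nothing(self, config):
        probes = [f"cg{i:06d}" for i in range(10)]
        samples = make_sheet(2).sample_ids
        meth = pd.DataFrame(500.0, index=probes, columns=samples)
        detp = pd.DataFrame(1e-6, index=probes, columns=samples)
        ds = build_dataset(meth, meth.copy(), detp=detp)
        assert qc_filter(ds, config).probe_ids == probes

    def test_everything_removed_is_error(self, config):
        probes = ["cg000000"]
        samples = make_sheet(2).sample_ids
        meth = pd.DataFrame(500.0, index=probes, columns=samples)
        detp = pd.DataFrame(0.5, index=probes, columns=samples)
        ds = build_dataset(meth, meth.copy(), detp=detp)
        with pytest.raises(ValueError, match="every probe"):
            qc_filter(ds, config)


class TestBetaM:
    def _dataset(self, meth_val, unmeth_val):
        probes = ["cg000000"]
        samples = make_sheet(1).sample_ids
        meth = pd.DataFrame(float(meth_val), index=probes, columns=samples)
        unmeth = pd.DataFrame(float(unmeth_val), index=probes, columns=samples)
        detp = pd.DataFrame(1e-6, index=probes, columns=samples)
        return build_dataset(meth, unmeth, detp=detp, n_pairs=1)

    def test_symmetric_intensities(self):
        mm = compute_beta_m(self._dataset(500, 500))
        assert mm.beta.iloc[0, 0] == pytest.approx(0.5)
        assert mm.mvalue.iloc[0, 0] == pytest.approx(0.0)

    def test_direct_formula(self):
        mm = compute_beta_m(self._dataset(900, 100), alpha_beta=0.0, alpha_m=0.0)
        assert mm.beta.iloc[0, 0] == pytest.approx(0.9, abs=1e-12)
        assert mm.mvalue.iloc[0, 0] == pytest.approx(np.log2(9), abs=1e-12)
        mm1 = compute_beta_m(self._dataset(900, 100))  # default alpha_m=1
        assert mm1.mvalue.iloc[0, 0] == pytest.approx(np.log2(901 / 101), abs=1e-12)

    def test_logit_identity_with_zero_alphas(self):
        rng = np.random.default_rng(0)
        probes = [f"cg{i:06d}" for i in range(50)]
        samples = make_sheet(2).sample_ids
        meth = pd.DataFrame(rng.uniform(10, 1000, (50, 4)), index=probes, columns=samples)
        unmeth = pd.DataFrame(rng.uniform(10, 1000, (50, 4)), index=probes, columns=samples)
        detp = pd.DataFrame(1e-6, index=probes, columns=samples)
        ds = build_dataset(meth, unmeth, detp=detp)
        mm = compute_beta_m(ds, alpha_beta=0.0, alpha_m=0.0)
        b = mm.beta.to_numpy()
        assert np.allclose(mm.mvalue.to_numpy(), np.log2(b / (1 - b)), atol=1e-12)

    def test_zero_total_intensity_yields_missing_beta(self):
        mm = compute_beta_m(self._dataset(0, 0))
        assert np.isnan(mm.beta.iloc[0, 0])
        assert mm.qc_log["n_zero_intensity_cells"] == 2


class TestNormalizeType2:
    def _matrices(self, t1_values, t2_values):
        n1, n2 = len(t1_values), len(t2_values)
        probes = [f"cg{i:06d}" for i in range(n1 + n2)]
        specs = [
            {"probe_id": p, "design_type": "I" if i < n1 else "II"}
            for i, p in enumerate(probes)
        ]
        manifest = make_manifest(specs)
        beta = pd.DataFrame(
            {"A1": np.concatenate([t1_values, t2_values]),
             "V1": np.concatenate([t1_values, t2_values])},
            index=probes,
        )
        return matrices_from_beta(beta), manifest

    def test_identical_distributions_are_left_alone(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0.05, 0.95, 150)
        mm, manifest = self._matrices(values, values)
        out = normalize_type2(mm, manifest)
        assert np.allclose(out.beta.to_numpy(), mm.beta.to_numpy(), atol=1e-9)
        assert out.qc_log["type2_normalization"] == "quantile_substitute"

    def test_uniform_shift_removed(self):
        rng = np.random.default_rng(1)
        t1 = rng.uniform(0.1, 0.7, 2000)
        t2 = rng.uniform(0.1, 0.7, 2000) + 0.1
        mm, manifest = self._matrices(t1, t2)
        out = normalize_type2(mm, manifest)
        is2 = np.array([manifest[p].design_type == "II" for p in out.beta.index])
        diff = out.beta.loc[is2, "A1"].mean() - out.beta.loc[~is2, "A1"].mean()
        assert abs(diff) < 0.01

    def test_monotone_within_type2(self):
        rng = np.random.default_rng(2)
        t1 = rng.uniform(0, 1, 300)
        t2 = rng.uniform(0, 1, 300)
        mm, manifest = self._matrices(t1, t2)
        out = normalize_type2(mm, manifest)
        is2 = np.array([manifest[p].design_type == "II" for p in out.beta.index])
        before = mm.beta.loc[is2, "A1"].to_numpy()
        after = out.beta.loc[is2, "A1"].to_numpy()
        order = np.argsort(before)
        assert (np.diff(after[order]) >= -1e-12).all()

    def test_samples_processed_independently(self):
        rng = np.random.default_rng(3)
        t1 = rng.uniform(0, 1, 150)
        t2 = rng.uniform(0, 1, 150)
        mm, manifest = self._matrices(t1, t2)
        mm.beta["V1"] = np.clip(mm.beta["V1"] * 0.8 + 0.05, 0, 1)
        out = normalize_type2(mm, manifest)
        swapped = mm.beta[["V1", "A1"]].copy()
        swapped.columns = ["A1", "V1"]
        out_swapped = normalize_type2(matrices_from_beta(swapped), manifest)
        assert np.allclose(out.beta["V1"], out_swapped.beta["A1"], atol=1e-12)

    def test_too_few_probes_skips_with_warning(self):
        mm, manifest = self._matrices(np.linspace(0.1, 0.9, 10), np.linspace(0.1, 0.9, 150))
        with pytest.warns(UserWarning, match="skipping"):
            out = normalize_type2(mm, manifest)
        assert out.qc_log["type2_normalization"] == "skipped"
        assert out.beta.equals(mm.beta)


class TestGlobalMethylation:
    def test_constant_matrix(self, small_sheet):
        beta = pd.DataFrame(0.4, index=["a", "b"], columns=small_sheet.sample_ids)
        summary = global_methylation(matrices_from_beta(beta), small_sheet)
        assert all(v == pytest.approx(0.4) for v in summary.per_sample_mean_beta.values())
        assert all(v == pytest.approx(0.4) for v in summary.per_group_mean_beta.values())

    def test_group_mean_is_mean_of_member_samples(self, small_sheet):
        rng = np.random.default_rng(0)
        beta = pd.DataFrame(
            rng.uniform(0, 1, (20, 6)), index=[f"p{i}" for i in range(20)],
            columns=small_sheet.sample_ids,
        )
        summary = global_methylation(matrices_from_beta(beta), small_sheet)
        for group in ("arterial", "venous"):
            members = small_sheet.group_samples(group)
            expected = np.mean([summary.per_sample_mean_beta[s] for s in members])
            assert summary.per_group_mean_beta[group] == pytest.approx(expected)

    def test_offset_recovered_from_simulation(self, config):
        manifest = simulate_manifest(500, (5, 5), 0.0, seed=21)
        ds, _, _ = simulate_dataset(
            manifest, 9, TruthSpec(0, 0.0, 0, 0.0, global_offset=0.045), seed=22
        )
        mm = compute_beta_m(qc_filter(ds, config))
        summary = global_methylation(mm, ds.samples)
        diff = summary.per_group_mean_beta["venous"] - summary.per_group_mean_beta["arterial"]
        assert diff == pytest.approx(0.045, abs=0.01)


class TestVariableProbes:
    def test_constant_probe_excluded(self, config):
        beta = pd.DataFrame(
            {"A1": [0.5, 0.2], "V1": [0.5, 0.6]}, index=["const", "varying"]
        )
        selected = select_variable_probes(matrices_from_beta(beta), config)
        assert "const" not in selected

    def test_hand_computed_cv(self, config):
        beta = pd.DataFrame({"A1": [0.2], "V1": [0.6]}, index=["p"])
        cv = probe_cv(matrices_from_beta(beta))
        expected = np.std([0.2, 0.6], ddof=1) / 0.4
        assert cv["p"] == pytest.approx(expected)
        assert expected > 0.4
        assert select_variable_probes(matrices_from_beta(beta), config) == ["p"]

    def test_zero_mean_probe_is_nan(self):
        beta = pd.DataFrame({"A1": [0.0], "V1": [0.0]}, index=["p"])
        cv = probe_cv(matrices_from_beta(beta))
        assert np.isnan(cv["p"])

    def test_top_variable_ties_broken_lexicographically(self):
        beta = pd.DataFrame(
            {"A1": [0.2, 0.2, 0.1], "V1": [0.6, 0.6, 0.11]}, index=["pb", "pa", "pc"]
        )
        top = top_variable(matrices_from_beta(beta), 2)
        assert top == ["pa", "pb"]

    def test_n_larger_than_probe_count_warns(self):
        beta = pd.DataFrame({"A1": [0.2, 0.3], "V1": [0.6, 0.5]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="only 2"):
            top = top_variable(matrices_from_beta(beta), 10)
        assert sorted(top) == ["a", "b"]


class TestHierarchicalCluster:
    def _separated_matrices(self, seed=0):
        rng = np.random.default_rng(seed)
        sheet = make_sheet(4)
        n = 50
        beta = rng.uniform(0.3, 0.5, size=(n, 8))
        planted = rng.random(n) < 0.3
        for j, group in enumerate(sheet.frame["group"]):
            if group == "arterial":
                beta[planted, j] += 0.4
        beta = pd.DataFrame(
            np.clip(beta, 0, 1), index=[f"p{i}" for i in range(n)],
            columns=sheet.sample_ids,
        )
        return matrices_from_beta(beta), sheet

    def test_planted_groups_recovered(self):
        mm, sheet = self._separated_matrices()
        result = hierarchical_cluster(mm)
        labels = {g: {result.k2_labels[s] for s in sheet.group_samples(g)} for g in ("arterial", "venous")}
        assert len(labels["arterial"]) == 1
        assert len(labels["venous"]) == 1
        assert labels["arterial"] != labels["venous"]

    def test_duplicate_sample_merges_at_height_zero(self):
        beta = pd.DataFrame(
            {"A1": [0.2, 0.8], "V1": [0.6, 0.3], "A2": [0.2, 0.8], "V2": [0.9, 0.1]},
            index=["p1", "p2"],
        )
        result = hierarchical_cluster(matrices_from_beta(beta))
        assert result.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_linkage_shape_and_monotone_heights(self):
        mm, _ = self._separated_matrices(seed=5)
        result = hierarchical_cluster(mm)
        n = mm.mvalue.shape[1]
        assert result.linkage.shape[0] == n - 1
        heights = result.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_sample_permutation_invariance(self):
        mm, _ = self._separated_matrices(seed=7)
        result1 = hierarchical_cluster(mm)
        permuted = matrices_from_beta(mm.beta[list(reversed(mm.beta.columns))])
        result2 = hierarchical_cluster(permuted)
        assert np.allclose(
            np.sort(result1.linkage[:, 2]), np.sort(result2.linkage[:, 2])
        )
        part1 = frozenset(
            frozenset(s for s, l in result1.k2_labels.items() if l == k) for k in (1, 2)
        )
        part2 = frozenset(
            frozenset(s for s, l in result2.k2_labels.items() if l == k) for k in (1, 2)
        )
        assert part1 == part2
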