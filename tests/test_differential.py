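import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from acetyltempo import QuantTable, contrast, contrast_all, qc, transform


def _two_group_table(a, b):
    samples = [f"A_r{i+1}" for i in range(len(a))] + \
              [f"B_r{i+1}" for i in range(len(b))]
    data = pd.DataFrame([list(a) + list(b)],
                        index=pd.Index(["P_K1"], name="site_id"),
                        columns=samples)
    meta = pd.DataFrame(
        {"condition": ["A"] * len(a) + ["B"] * len(b),
         "replicate": list(range(1, len(a) + 1)) + list(range(1, len(b) + 1))},
        index=pd.Index(samples, name="sample"))
    return QuantTable(data, meta)


class TestTransform:
    def test_pseudocount_one_at_zero(self, tiny_table):
        t = tiny_table
        t.data.iloc[0, 0] = 0.0
        out = transform(t, pseudocount=1)
        assert out.data.iloc[0, 0] == 0.0

    def test_log2_of_seven_plus_one(self):
        t = _two_group_table([7, 7], [7, 7])
        assert np.allclose(transform(t, 1).data.to_numpy(), 3.0)

    def test_zero_with_zero_pseudocount_errors(self):
        t = _two_group_table([0, 1], [2, 3])
        with pytest.raises(ValueError, match="pseudocount"):
            transform(t, pseudocount=0)

    @given(st.lists(st.tuples(
        st.floats(0, 1e9, allow_nan=False),
        st.floats(0, 1e9, allow_nan=False)), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=100)
    def test_monotone(self, pairs):
        xs = np.array([min(p) for p in pairs])
        ys = np.array([max(p) for p in pairs])
        fx = np.log2(xs + 1)
        fy = np.log2(ys + 1)
        assert np.all(fx <= fy)
        # strict whenever the gap is representable after the +1 shift
        strict = (ys - xs) > 1e-9 * (1 + xs)
        assert np.all(fx[strict] < fy[strict])


class TestContrast:
    def test_identical_groups(self):
        t = _two_group_table([1, 2, 3], [1, 2, 3])
        out = contrast(t, "A", "B")
        row = out.iloc[0]
        assert row["t"] == 0 and row["p_value"] == 1
        assert not row["significant"] and row["direction"] == "none"

    def test_textbook_pooled_variance_oracle(self):
        # hand-computed via the pooled-variance formula: see frozen values
        t = _two_group_table([10, 12, 11], [14, 15, 16])
        row = contrast(t, "A", "B").iloc[0]
        assert row["log2fc"] == pytest.approx(4.0)
        assert row["t"] == pytest.approx(4.898979485566356, rel=1e-12)
        assert row["p_value"] == pytest.approx(0.008049893100837719, rel=1e-10)

    def test_alpha_monotonicity(self, small_dataset):
        table = small_dataset[0]
        logt = transform(table)
        c01 = contrast(logt, "UnT", "6hAmAc", alpha=0.01)
        c05 = contrast(logt, "UnT", "6hAmAc", alpha=0.05)
        assert c01["significant"].sum() <= c05["significant"].sum()

    def test_label_swap_negates_effect(self, small_dataset):
        logt = transform(small_dataset[0])
        fwd = contrast(logt, "UnT", "24hAmAc")
        rev = contrast(logt, "24hAmAc", "UnT")
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["t"], -rev["t"], equal_nan=True)
        assert np.array_equal(fwd["p_value"], rev["p_value"])

    def test_zero_variance_equal_means(self):
        t = _two_group_table([5, 5, 5], [5, 5, 5])
        row = contrast(t, "A", "B").iloc[0]
        assert row["p_value"] == 1 and row["t"] == 0
        assert not row["exact_separation"]

    def test_zero_variance_separated_means(self):
        t = _two_group_table([5, 5, 5], [9, 9, 9])
        row = contrast(t, "A", "B").iloc[0]
        assert row["p_value"] == 0 and row["exact_separation"]
        assert row["significant"] and row["direction"] == "up"

    def test_significant_implies_direction(self, small_dataset):
        logt = transform(small_dataset[0])
        out = contrast_all(logt, [("UnT", "6hAmAc"), ("UnT", "24hAmAc")])
        sig = out[out["significant"]]
        assert (sig["direction"] != "none").all()
        assert np.array_equal(sig["direction"] == "up", sig["log2fc"] > 0)

    def test_missing_values_excluded_not_imputed(self):
        t = _two_group_table([10.0, 12.0, 11.0, 50.0], [14.0, 15.0, 16.0, 17.0])
        t.data.loc["P_K1", "A_r4"] = np.nan
        t.data.loc["P_K1", "B_r4"] = np.nan
        row = contrast(t, "A", "B").iloc[0]
        assert row["t"] == pytest.approx(4.898979485566356, rel=1e-12)

    def test_under_two_replicates_dropped(self):
        t = _two_group_table([10.0, 12.0], [14.0, 15.0])
        t.data.loc["P_K1", "A_r2"] = np.nan
        out = contrast(t, "A", "B")
        assert len(out) == 0

    def test_bh_mode_is_no_looser_than_raw(self, small_dataset):
        logt = transform(small_dataset[0])
        raw = contrast(logt, "UnT", "24hAmAc")
        adj = contrast(logt, "UnT", "24hAmAc", adjust=True)
        assert adj["significant"].sum() <= raw["significant"].sum()


class TestQC:
    def test_rank_one_matrix_first_component_all_variance(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=20)
        v = rng.normal(size=6)
        data = pd.DataFrame(np.outer(u, v) + 5.0,
                            index=[f"P{i}_K1" for i in range(20)],
                            columns=[f"s{i}" for i in range(6)])
        meta = pd.DataFrame({"condition": ["A"] * 3 + ["B"] * 3,
                             "replicate": [1, 2, 3, 1, 2, 3]},
                            index=data.columns)
        summary = qc(QuantTable(data, meta), pairs=[("A", "B")])
        # centering removes the constant, leaving an exact rank-1 matrix
        assert summary.variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_constant_matrix_zero_variance(self):
        data = pd.DataFrame(np.full((4, 4), 3.0),
                            index=[f"P{i}_K1" for i in range(4)],
                            columns=list("abcd"))
        meta = pd.DataFrame({"condition": ["A", "A", "B", "B"],
                             "replicate": [1, 2, 1, 2]}, index=data.columns)
        summary = qc(QuantTable(data, meta), pairs=[("A", "B")])
        assert np.all(summary.variance_fraction == 0)

    def test_svd_reconstruction(self, small_dataset):
        logt = transform(small_dataset[0])
        x = logt.data.to_numpy()
        centered = x - x.mean(axis=1, keepdims=True)
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        assert np.max(np.abs(u @ np.diag(s) @ vt - centered)) <= 1e-8
        summary = qc(logt)
        assert np.all(summary.variance_fraction >= 0)
        assert summary.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_ma_coordinates(self, small_dataset):
        logt = transform(small_dataset[0])
        summary = qc(logt, pairs=[("UnT", "24hAmAc")])
        ma = summary.ma["24hAmAc_vs_UnT"]
        ma_a = logt.data[logt.samples_for("UnT")].mean(axis=1)
        ma_b = logt.data[logt.samples_for("24hAmAc")].mean(axis=1)
        assert np.allclose(ma["M"], ma_b - ma_a)
        assert np.allclose(ma["A"], (ma_a + ma_b) / 2)
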