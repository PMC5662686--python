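"""V_ST / V_i statistics: closed forms, oracles, invariances, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import vstscan as vs

from conftest import make_group_assignment, region_lrrs_from_matrix


def two_pass_vst(xi, xj):
    """Independent oracle: textbook two-pass variance computation."""

    def var(x):
        m = sum(x) / len(x)
        return sum((v - m) ** 2 for v in x) / (len(x) - 1)

    v_t = var(list(xi) + list(xj))
    v_s = (len(xi) * var(xi) + len(xj) * var(xj)) / (len(xi) + len(xj))
    return (v_t - v_s) / v_t if v_t else 0.0


class TestVst:
    def test_hand_computed_quarter(self):
        got = vs.vst([0, 1, 1, 2], ["A", "A", "B", "B"], "A", "B")
        assert got == pytest.approx(0.25, abs=1e-12)
        assert got == pytest.approx(two_pass_vst([0, 1], [1, 2]), abs=1e-12)

    def test_degenerate_constant_input_is_zero(self):
        assert vs.vst([1, 1, 1, 1], ["A", "A", "B", "B"], "A", "B") == 0.0

    def test_maximal_differentiation_is_one(self):
        got = vs.vst([0, 0, 0, 1, 1, 1], ["A"] * 3 + ["B"] * 3, "A", "B")
        assert got == pytest.approx(1.0, abs=1e-12)

    def test_missing_values_dropped_pairwise(self):
        values = [0, 1, np.nan, 1, 2, np.nan]
        labels = ["A", "A", "A", "B", "B", "B"]
        assert vs.vst(values, labels, "A", "B") == pytest.approx(0.25, abs=1e-12)

    def test_too_few_observed_values_errors(self):
        with pytest.raises(vs.ValidationError, match="non-missing"):
            vs.vst([0, np.nan, 1, 2], ["A", "A", "B", "B"], "A", "B")

    # 3-decimal grid keeps the comparison away from catastrophic cancellation
    _value = st.floats(-2, 2, allow_nan=False).map(lambda v: round(v, 3))

    @given(
        st.lists(_value, min_size=2, max_size=8),
        st.lists(_value, min_size=2, max_size=8),
    )
    def test_agrees_with_two_pass_oracle(self, xi, xj):
        values = xi + xj
        labels = ["A"] * len(xi) + ["B"] * len(xj)
        assert vs.vst(values, labels, "A", "B") == pytest.approx(
            two_pass_vst(xi, xj), abs=1e-12
        )
        assert vs.vst(values, labels, "A", "B") <= 1.0 + 1e-12

    @given(
        st.lists(_value, min_size=3, max_size=8),
        st.lists(_value, min_size=3, max_size=8),
        st.floats(-5, 5, allow_nan=False),
        st.floats(0.1, 4, allow_nan=False),
    )
    def test_invariant_under_shift_and_scale(self, xi, xj, shift, scale):
        labels = ["A"] * len(xi) + ["B"] * len(xj)
        base = vs.vst(xi + xj, labels, "A", "B")
        transformed = [scale * v + shift for v in xi + xj]
        assert vs.vst(transformed, labels, "A", "B") == pytest.approx(base, abs=1e-8)


class TestRegionMeanLrr:
    def _matrix(self):
        probes = pd.DataFrame(
            {"probe_id": ["p1", "p2", "p3"], "chrom": "1", "pos": [100, 200, 300]}
        )
        values = pd.DataFrame(
            {"S1": [0.1, 0.3, 0.9], "S2": [0.5, np.nan, 0.7]}, index=probes["probe_id"]
        )
        return vs.LrrMatrix(probes=probes, values=values)

    def test_mean_over_in_region_probes(self):
        region = vs.Cnvr("R1", "1", 100, 200, "loss", 1, frozenset({"S1"}))
        r = vs.region_mean_lrr(self._matrix(), region)
        assert r.n_probes == 2
        assert r.values["S1"] == pytest.approx(0.2)
        # probes exactly at start/end are included; missing probe excluded
        assert r.values["S2"] == pytest.approx(0.5)

    def test_no_probes_in_span_errors(self):
        region = vs.Cnvr("R9", "1", 400, 500, "loss", 1, frozenset({"S1"}))
        with pytest.raises(vs.ValidationError, match="R9"):
            vs.region_mean_lrr(self._matrix(), region)
        assert vs.region_mean_lrr_many(self._matrix(), [region], on_empty="drop") == []


class TestViScan:
    def test_standardized_terms_mean_zero_sd_one(self):
        rng = np.random.default_rng(5)
        groups = make_group_assignment()
        regions = region_lrrs_from_matrix(
            rng.normal(0, 0.2, size=(40, len(groups))), groups.samples
        )
        vst_table, vi_table = vs.vi_scan(regions, groups)
        for (gi, gj), sub in vst_table.table.groupby(["group_i", "group_j"]):
            m = vst_table.moments
            row = m[(m.group_i == gi) & (m.group_j == gj)].iloc[0]
            z = (sub.vst.to_numpy() - row["mean"]) / row["sd"]
            assert np.mean(z) == pytest.approx(0.0, abs=1e-9)
            assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_two_groups_have_identical_vi(self):
        rng = np.random.default_rng(6)
        groups = vs.GroupAssignment(
            {f"S{i}": ("A" if i < 5 else "B") for i in range(10)}
        )
        regions = region_lrrs_from_matrix(rng.normal(0, 1, (10, 10)), groups.samples)
        _, vi_table = vs.vi_scan(regions, groups)
        a = vi_table.group_values("A")
        b = vi_table.group_values("B")
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_vi_is_sum_of_three_terms_with_four_groups(self):
        rng = np.random.default_rng(7)
        groups = make_group_assignment()
        regions = region_lrrs_from_matrix(rng.normal(0, 1, (12, len(groups))), groups.samples)
        vst_table, vi_table = vs.vi_scan(regions, groups)
        g = "North"
        z_sum = np.zeros(12)
        for _, row in vst_table.moments.iterrows():
            if g in (row.group_i, row.group_j):
                pair = vst_table.pair_values(row.group_i, row.group_j)
                z_sum += (pair.to_numpy() - row["mean"]) / row["sd"]
        assert np.allclose(vi_table.group_values(g).to_numpy(), z_sum)

    def test_degenerate_pair_errors(self):
        groups = vs.GroupAssignment({f"S{i}": ("A" if i < 3 else "B") for i in range(6)})
        constant = np.ones((3, 6))  # every region identical => all vst equal
        regions = region_lrrs_from_matrix(constant, groups.samples)
        with pytest.raises(vs.ValidationError, match="sd = 0"):
            vs.vi_scan(regions, groups)

    def test_differentiated_region_ranks_first(self):
        """A region with a large carrier-frequency gap tops its group's V_i."""
        rng = np.random.default_rng(42)
        groups = make_group_assignment()
        samples = groups.samples
        n = len(samples)
        X = rng.normal(0, 0.2, size=(50, n))
        freqs = np.where(
            np.array([groups.group_of(s) for s in samples]) == "North", 0.8, 0.05
        )
        carriers = rng.random(n) < freqs
        X[0, carriers] += -0.45
        regions = region_lrrs_from_matrix(X, samples)
        _, vi_table = vs.vi_scan(regions, groups)
        top = vs.select_candidates(vi_table, "North", 0.02)
        assert top.cnvr_ids == ["R1"]


class TestSelectCandidates:
    def _table(self, values):
        ids = [f"R{i + 1}" for i in range(len(values))]
        return vs.ViTable(
            table=pd.DataFrame({"cnvr_id": ids, "group": "G", "vi": values})
        )

    def test_round_half_up_counts(self):
        vi = self._table(list(range(100)))
        assert len(vs.select_candidates(vi, "G", 0.05).cnvr_ids) == 5
        assert len(vs.select_candidates(vi, "G", 0.015).cnvr_ids) == 2  # 1.5 -> 2

    def test_descending_order_and_threshold(self):
        vi = self._table([3.0, 1.0, 5.0, 4.0])
        cs = vs.select_candidates(vi, "G", 0.5)
        assert cs.cnvr_ids == ["R3", "R4"]
        assert cs.threshold_vi == 4.0
        assert min(cs.vi_values) >= cs.threshold_vi

    def test_ties_broken_by_ascending_id(self):
        vi = self._table([1.0] * 10)
        cs = vs.select_candidates(vi, "G", 0.2)
        assert cs.cnvr_ids == ["R1", "R10"]  # lexicographic ordering of ids

    def test_zero_candidates_errors(self):
        with pytest.raises(vs.ValidationError, match="selects 0"):
            vs.select_candidates(self._table([1.0, 2.0]), "G", 0.01)

    def test_bad_quantile_and_unknown_group(self):
        with pytest.raises(vs.ValidationError):
            vs.select_candidates(self._table([1.0]), "G", 1.5)
        with pytest.raises(vs.ValidationError, match="no V_i"):
            vs.select_candidates(self._table([1.0, 2.0]), "H", 0.5)


def test_manhattan_table_has_coordinates():
    cnvrs = [vs.Cnvr("R1", "2", 100, 300, "loss", 2, frozenset({"S1", "S2"}))]
    vi = vs.ViTable(
        table=pd.DataFrame({"cnvr_id": ["R1"], "group": ["G"], "vi": [1.5]})
    )
    df = vs.manhattan_table(vi, cnvrs)
    assert df.iloc[0].tolist() == ["R1", "2", 200, "G", 1.5]
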