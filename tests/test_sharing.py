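"""Sharing coefficient, Sharing Factor, common-variant flagging and the
theta_V sweep."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saber.align import UNEDITED, SampleVariantTable
from saber.sharing import (COMMON_SUM, DEFAULT_THETA_SWEEP, CommonVariantSet,
                           ReducedSampleTable, VariantMatrix,
                           flag_common_variants, informative_fraction,
                           mean_pairwise_sharing, qc_warnings, reduce_sample,
                           sharing_coefficient, sharing_factor, sweep_theta)


def sharing_factor_oracle(counts1: dict, counts2: dict) -> float:
    """Brute-force min-sum over the explicit union of variant names."""
    names = set(counts1) | set(counts2)
    num = sum(2 * min(counts1.get(n, 0), counts2.get(n, 0)) for n in names)
    den = sum(counts1.get(n, 0) + counts2.get(n, 0) for n in names)
    return num / den


def _reduced(sample_id, counts: dict, unedited=0, common=0):
    return ReducedSampleTable(sample_id, unedited, common,
                              pd.Series(counts, dtype=np.int64))


class TestSharingCoefficient:
    def test_unique_variant_scores_zero(self):
        assert sharing_coefficient(42, 0) == 0.0

    def test_equal_counts_score_one(self):
        assert sharing_coefficient(17, 17) == 1.0

    def test_printed_counts_evaluate_directly(self):
        # the high-frequency shared allele: 20,225 vs 4,073 reads
        expected = 2 * 4073 / (20225 + 4073)
        assert sharing_coefficient(20225, 4073) == pytest.approx(expected)

    def test_absent_from_both_errors(self):
        with pytest.raises(ValueError, match="absent"):
            sharing_coefficient(0, 0)

    @given(st.integers(0, 10**6), st.integers(0, 10**6))
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_symmetric(self, v1, v2):
        if v1 + v2 == 0:
            return
        s = sharing_coefficient(v1, v2)
        assert 0 <= s <= 1
        assert s == sharing_coefficient(v2, v1)


class TestSharingFactor:
    def test_identical_tables_share_fully(self):
        t = _reduced("a", {"x": 10, "y": 30})
        assert sharing_factor(t, _reduced("b", {"x": 10, "y": 30})) == 1.0

    def test_disjoint_tables_share_nothing(self):
        a = _reduced("a", {"x": 10, "y": 30})
        b = _reduced("b", {"z": 25})
        assert sharing_factor(a, b) == 0.0

    def test_hand_evaluated_pair(self):
        a = _reduced("a", {"A": 10, "B": 30})
        b = _reduced("b", {"A": 10, "C": 50})
        assert sharing_factor(a, b) == pytest.approx(0.2)

    def test_symmetry_and_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        pool = [f"v{i}" for i in range(15)]
        for _ in range(100):
            c1 = {n: int(rng.integers(0, 100))
                  for n in rng.choice(pool, rng.integers(1, 10), replace=False)}
            c2 = {n: int(rng.integers(0, 100))
                  for n in rng.choice(pool, rng.integers(1, 10), replace=False)}
            c1 = {n: c for n, c in c1.items() if c} or {"v0": 1}
            c2 = {n: c for n, c in c2.items() if c} or {"v1": 1}
            a, b = _reduced("a", c1), _reduced("b", c2)
            s = sharing_factor(a, b)
            assert s == pytest.approx(sharing_factor_oracle(c1, c2))
            assert s == pytest.approx(sharing_factor(b, a))
            assert 0 <= s <= 1

    def test_all_universe_includes_unedited_sharing(self):
        # unedited reads dominate the pair: the all-rows Sharing Factor
        # must exceed the informative-only one on this construction
        a = _reduced("a", {"x": 10}, unedited=900)
        b = _reduced("b", {"y": 10}, unedited=900)
        assert sharing_factor(a, b, universe="informative") == 0.0
        assert sharing_factor(a, b, universe="all") > 0.9


class TestCommonVariants:
    def _matrix(self):
        tables = [
            SampleVariantTable("s1", pd.Series({"shared": 50, "u1": 950})),
            SampleVariantTable("s2", pd.Series({"shared": 50, "u2": 950})),
            SampleVariantTable("s3", pd.Series({"solo": 50, "u3": 950})),
        ]
        return VariantMatrix.from_tables(tables)

    def test_variant_above_theta_in_two_samples_flagged(self):
        common = flag_common_variants(self._matrix(), 0.003)
        assert "shared" in common
        assert "solo" not in common  # only one sample

    def test_theta_one_flags_nothing(self):
        assert not flag_common_variants(self._matrix(), 1.0).names

    def test_unedited_never_flagged(self):
        tables = [
            SampleVariantTable("s1", pd.Series({UNEDITED: 500, "u1": 500})),
            SampleVariantTable("s2", pd.Series({UNEDITED: 500, "u2": 500})),
        ]
        common = flag_common_variants(VariantMatrix.from_tables(tables), 0.01)
        assert UNEDITED not in common.names

    def test_reduction_conserves_reads(self):
        rng = np.random.default_rng(1)
        matrix = self._matrix()
        common = flag_common_variants(matrix, 0.003)
        for sid in matrix.sample_ids:
            table = matrix.sample_table(sid)
            reduced = reduce_sample(table, common)
            assert reduced.aligned == table.total
            assert not set(reduced.informative.index) & common.names

    def test_informative_fraction_arithmetic(self):
        t = ReducedSampleTable("s", 200, 100, pd.Series({"a": 400, "b": 300}))
        assert informative_fraction(t) == pytest.approx(0.7)
        assert informative_fraction(_reduced("s", {}, unedited=10)) == 0.0
        assert informative_fraction(_reduced("s", {"a": 5})) == 1.0


def _planted_matrix(n_samples=20, seed=0):
    """Each sample: 10% unedited, one planted shared variant at VAF 0.05,
    five unique clones carrying the rest."""
    tables = []
    for i in range(n_samples):
        counts = {UNEDITED: 100, "planted": 50}
        for j in range(5):
            counts[f"s{i}c{j}"] = 170
        tables.append(SampleVariantTable(f"s{i}", pd.Series(counts)))
    return VariantMatrix.from_tables(tables)


class TestSweep:
    def test_unique_variants_never_share(self):
        tables = [SampleVariantTable(f"s{i}",
                                     pd.Series({f"v{i}": 80, UNEDITED: 20}))
                  for i in range(4)]
        result = sweep_theta(VariantMatrix.from_tables(tables))
        assert all(s == 0 for s in result.mean_S)

    def test_planted_shared_variant_flagged_below_its_vaf(self):
        matrix = _planted_matrix()
        result = sweep_theta(matrix)
        assert result.selected_theta < 0.05
        common = flag_common_variants(matrix, result.selected_theta)
        assert "planted" in common
        reduced = [reduce_sample(matrix.sample_table(s), common)
                   for s in matrix.sample_ids]
        assert mean_pairwise_sharing(reduced) < 0.01

    def test_phi_is_maximal_at_theta_one(self):
        matrix = _planted_matrix()
        result = sweep_theta(matrix)
        phi = dict(zip(result.theta_values, result.mean_phi))
        assert all(phi[1.0] >= v for v in result.mean_phi)

    def test_selected_theta_is_on_grid_and_maximises_product(self):
        result = sweep_theta(_planted_matrix())
        assert result.selected_theta in result.theta_values
        best = max(result.z_product)
        idx = result.theta_values.index(result.selected_theta)
        assert result.z_product[idx] == pytest.approx(best)

    def test_needs_two_samples(self):
        t = SampleVariantTable("s", pd.Series({"v": 10}))
        with pytest.raises(ValueError):
            sweep_theta(VariantMatrix.from_tables([t]))


class TestQcWarnings:
    def _result(self, selected):
        from types import SimpleNamespace

        return SimpleNamespace(theta_values=list(DEFAULT_THETA_SWEEP),
                               selected_theta=selected)

    def test_high_sharing_and_low_phi_both_warn(self):
        warnings = qc_warnings(self._result(0.001), 0.51, 0.01)
        assert len(warnings) == 2

    def test_theta_at_sweep_maximum_warns(self):
        warnings = qc_warnings(self._result(0.3), 0.001, 0.9)
        assert len(warnings) == 1
        assert "0.3" in warnings[0]

    def test_clean_run_has_no_warnings(self):
        assert qc_warnings(self._result(0.003), 0.0024, 0.92) == []
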