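"""Set-theoretic measures, calibration, truth tables and minimization."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from implfx.datasets import QCADataset
from implfx.errors import ConfigurationError, StructuralError, UndefinedResultError
from implfx.qca import (
    CalibrationAnchors,
    build_truth_table,
    calibrate,
    minimize,
    necessity,
    sufficiency,
    _term_covers,
)
from implfx.simulate import QCASimParams, simulate_qca


def _dataset(memberships: dict, outcome) -> QCADataset:
    idx = pd.Index([f"c{i}" for i in range(len(outcome))], name="case")
    m = pd.DataFrame(memberships, index=idx, dtype=float)
    return QCADataset(memberships=m, outcome=pd.Series(outcome, index=idx, dtype=float))


class TestCalibration:
    def test_anchor_identities(self):
        a = CalibrationAnchors(2.0, 5.0, 9.0)
        out = calibrate(np.array([2.0, 5.0, 9.0]), a)
        assert out == pytest.approx([0.05, 0.5, 0.95])

    def test_decreasing_anchors_for_negated_condition(self):
        a = CalibrationAnchors(9.0, 5.0, 2.0)
        out = calibrate(np.array([9.0, 5.0, 2.0]), a)
        assert out == pytest.approx([0.05, 0.5, 0.95])

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=30, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_rank_preservation(self, raw):
        a = CalibrationAnchors(-10.0, 0.0, 10.0)
        order = np.argsort(raw, kind="stable")
        m = calibrate(np.array(raw), a)[order]
        assert np.all(np.diff(m) >= 0)  # monotone, ties only at float precision
        spread = np.diff(np.sort(raw))
        if np.min(spread) > 1e-6:
            assert np.all(np.diff(m) > 0)

    def test_non_monotone_anchors_rejected(self):
        with pytest.raises(ConfigurationError, match="monotone"):
            CalibrationAnchors(1.0, 1.0, 2.0)


class TestSubsetRelations:
    def test_min_sum_formula_direct_evaluation(self):
        meas = necessity(np.array([0.8, 0.4]), np.array([0.6, 0.6]))
        assert meas.consistency == pytest.approx(1.0 / 1.2)
        assert meas.coverage == pytest.approx(1.0 / 1.2)

    def test_identity_gives_unity(self):
        x = np.array([0.2, 0.7, 1.0])
        for fn in (necessity, sufficiency):
            meas = fn(x, x)
            assert meas.consistency == 1.0 and meas.coverage == 1.0

    def test_crisp_subset_consistency_one(self):
        x = np.array([1, 1, 1, 0], dtype=float)
        y = np.array([1, 1, 0, 0], dtype=float)  # y subset of x
        assert necessity(x, y).consistency == 1.0
        assert sufficiency(y, x).consistency == 1.0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_crisp_sufficiency_equals_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, 30).astype(float)
        y = rng.integers(0, 2, 30).astype(float)
        if x.sum() == 0:
            return
        cons = sufficiency(x, y).consistency
        assert cons == pytest.approx(((x == 1) & (y == 1)).sum() / (x == 1).sum())

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_measures_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1, 20)
        y = rng.uniform(0.01, 1, 20)
        for fn in (necessity, sufficiency):
            meas = fn(x, y)
            assert 0.0 <= meas.consistency <= 1.0
            assert 0.0 <= meas.coverage <= 1.0

    def test_zero_denominators_raise(self):
        with pytest.raises(UndefinedResultError):
            necessity(np.array([0.5]), np.array([0.0]))
        with pytest.raises(UndefinedResultError):
            sufficiency(np.array([0.0]), np.array([0.5]))


class TestTruthTable:
    def test_crisp_partition_counts(self, crisp_qca_frame):
        m, y = crisp_qca_frame
        data = QCADataset(memberships=m, outcome=y)
        table = build_truth_table(data)
        assert table.rows["n"].sum() == len(m)
        assert len(table.rows) == len(m[["A", "B"]].drop_duplicates())

    def test_planted_rule_coded_by_consistency(self):
        d = simulate_qca(QCASimParams(n_cases=64, planted_solution="A",
                                      condition_names=("A", "B"), seed=1))
        table = build_truth_table(d)
        for _, row in table.rows.iterrows():
            assert row["outcome"] == int(row["A"] == 1)

    def test_fuzzy_assignment_matches_exhaustive_comparison(self):
        d = simulate_qca(QCASimParams(n_cases=40, planted_solution="A*B",
                                      crisp=False, seed=9))
        table = build_truth_table(d)
        m = d.memberships.to_numpy()
        expected = {}
        for row in (m > 0.5).astype(int):
            expected[tuple(row)] = expected.get(tuple(row), 0) + 1
        got = {tuple(int(r[c]) for c in table.conditions): r["n"]
               for _, r in table.rows.iterrows()}
        assert got == expected

    def test_half_memberships_excluded_with_warning(self):
        data = _dataset({"A": [0.5, 1.0], "B": [0.2, 0.8]}, [0.4, 0.9])
        with pytest.warns(UserWarning, match="0.5"):
            table = build_truth_table(data)
        assert table.n_excluded == 1 and table.rows["n"].sum() == 1


class TestMinimize:
    def test_boolean_absorption(self):
        data = _dataset({"A": [1, 1, 0, 0], "B": [1, 0, 1, 0]}, [1, 1, 0, 0])
        sol = minimize(build_truth_table(data))
        assert sol.expression == "A"
        assert sol.consistency == 1.0 and sol.coverage == 1.0

    def test_xnor_terms_not_reducible(self):
        data = _dataset({"A": [1, 1, 0, 0], "B": [1, 0, 1, 0]}, [1, 0, 0, 1])
        sol = minimize(build_truth_table(data))
        assert sol.expression in ("A*B + ~A*~B", "~A*~B + A*B")

    def test_no_term_subsumes_another(self):
        d = simulate_qca(QCASimParams(n_cases=120, planted_solution="A*B + ~C",
                                      condition_names=("A", "B", "C"), seed=5))
        sol = minimize(build_truth_table(d))
        for t1, t2 in itertools.permutations(sol.terms, 2):
            assert not all(
                b1 is None or b1 == b2 for b1, b2 in zip(t1, t2)
            ), f"{t1} subsumes {t2}"

    def test_equivalence_on_random_codings(self, rng):
        # spot-check of the exhaustive-equivalence law on 3 conditions
        configs = list(itertools.product([0, 1], repeat=3))
        for _ in range(25):
            coding = rng.integers(0, 2, 8)
            if coding.sum() == 0:
                continue
            rows = np.array(configs, dtype=float)
            data = _dataset(
                {"A": rows[:, 0], "B": rows[:, 1], "C": rows[:, 2]},
                coding.astype(float),
            )
            sol = minimize(build_truth_table(data))
            for cfg, target in zip(configs, coding):
                covered = any(_term_covers(t, cfg) for t in sol.terms)
                assert covered == bool(target)

    def test_noise_degrades_consistency_monotonically(self):
        cons = []
        for noise in (0.0, 0.15, 0.3):
            d = simulate_qca(QCASimParams(n_cases=400, planted_solution="A",
                                          noise_rate=noise, seed=17))
            cons.append(sufficiency(d.memberships["A"], d.outcome).consistency)
        assert cons[0] > cons[1] > cons[2]

    def test_no_positive_rows_rejected(self):
        data = _dataset({"A": [1, 0], "B": [0, 1]}, [0, 0])
        with pytest.raises(StructuralError, match="positive"):
            minimize(build_truth_table(data))

    def test_tautology_warns_and_returns_true(self):
        data = _dataset({"A": [1, 0]}, [1, 1])
        with pytest.warns(UserWarning, match="TRUE"):
            sol = minimize(build_truth_table(data))
        assert sol.tautology and sol.expression == "TRUE"
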