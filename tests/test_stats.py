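"""ANOVA + Tukey letters, cross-regime correlation and CV%."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from coralbti.stats import (
    anova_tukey,
    compact_letter_display,
    cv_percent,
    cv_table,
    pearson_by_colony,
    tukey_pairwise_pvalues,
)


def _bti_frame(groups: dict, cutoff=30.0, regime="FHP"):
    rows = []
    for sp, vals in groups.items():
        for i, v in enumerate(vals):
            rows.append(
                {"fragment_id": f"{sp}-{i}", "species": sp,
                 "colony": f"c{i}", "regime": regime, "cutoff": cutoff,
                 "bti_days": v}
            )
    return pd.DataFrame(rows)


class TestAnovaTukey:
    def test_identical_within_groups_distinct_letters(self):
        df = _bti_frame({"A": [5, 5, 5], "B": [9, 9, 9]})
        res = anova_tukey(df, 30.0, "FHP")
        assert res.p_value == pytest.approx(0.0)
        assert res.letters["A"] != res.letters["B"]
        assert res.n_distinguished_pairs == 1

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(5, 1, 6), rng.normal(6, 1, 6)
        res = anova_tukey(_bti_frame({"A": a, "B": b}), 30.0, "FHP")
        t_stat, _ = sps.ttest_ind(a, b)
        assert res.f_stat == pytest.approx(t_stat**2, rel=1e-9)

    def test_cross_check_against_statsmodels_tukey(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(12)
        groups = {sp: rng.normal(mu, 1.0, 5)
                  for sp, mu in zip("ABCDE", [3, 5, 6, 6.5, 9])}
        ours = tukey_pairwise_pvalues(groups)
        vals = np.concatenate(list(groups.values()))
        labs = np.repeat(list(groups), 5)
        sm = pairwise_tukeyhsd(vals, labs)
        pairs = list(itertools.combinations(sm.groupsunique, 2))
        sm_p = {pair: p for pair, p in zip(pairs, sm.pvalues)}
        for pair, p in ours.items():
            assert p == pytest.approx(sm_p[pair], abs=1e-4)

    def test_small_species_excluded_with_warning(self):
        df = _bti_frame({"A": [5, 5.5, 6], "B": [9, 9.5, 10], "C": [7]})
        with pytest.warns(UserWarning, match="excluded"):
            res = anova_tukey(df, 30.0, "FHP")
        assert "C" not in res.species_means

    def test_letters_consistent_with_pairwise_significance(self):
        rng = np.random.default_rng(3)
        groups = {sp: rng.normal(mu, 0.8, 5)
                  for sp, mu in zip("ABCDE", [3, 3.5, 7, 7.2, 12])}
        res = anova_tukey(_bti_frame(groups), 30.0, "FHP")
        for (a, b), p in res.pairwise_p.items():
            share = set(res.letters[a]) & set(res.letters[b])
            if p < res.alpha:
                assert not share, f"{a},{b} significant but share {share}"
            else:
                assert share, f"{a},{b} not significant but no shared letter"


class TestCompactLetterDisplay:
    def test_all_equal_single_letter(self):
        p = {(a, b): 1.0 for a, b in itertools.combinations("ABC", 2)}
        out = compact_letter_display(list("ABC"), p)
        assert set(out.values()) == {"a"}

    def test_chain_structure(self):
        # A != C significant; A~B and B~C not: classic 'ab' bridge
        p = {("A", "B"): 0.3, ("B", "C"): 0.3, ("A", "C"): 0.01}
        out = compact_letter_display(list("ABC"), p)
        assert set(out["A"]) & set(out["B"])
        assert set(out["B"]) & set(out["C"])
        assert not set(out["A"]) & set(out["C"])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        names = list("ABCDE")
        p = {pair: float(rng.uniform(0, 0.2))
             for pair in itertools.combinations(names, 2)}
        base = compact_letter_display(names, p)

        perm = ["C", "A", "E", "B", "D"]
        p_perm = {}
        for (a, b), v in p.items():
            p_perm[(a, b)] = v
        out = compact_letter_display(perm, p_perm)
        # same partition into shared-letter classes, regardless of order
        def classes(d):
            cls = {}
            for n, letters in d.items():
                for L in letters:
                    cls.setdefault(L, set()).add(n)
            return {frozenset(v) for v in cls.values()}
        assert classes(base) == classes(out)


class TestPearsonByColony:
    def _paired_frame(self, fhp, shp):
        rows = []
        for i, (x, y) in enumerate(zip(fhp, shp)):
            for regime, v in (("FHP", x), ("SHP", y)):
                rows.append(
                    {"fragment_id": f"s-{i}-{regime}", "species": "s",
                     "colony": f"c{i}", "regime": regime,
                     "cutoff": 30.0, "bti_days": v}
                )
        return pd.DataFrame(rows)

    def test_identical_vectors(self):
        x = [3.0, 5.0, 7.0, 9.0]
        res = pearson_by_colony(self._paired_frame(x, x), 30.0)
        assert res.r == pytest.approx(1.0)
        assert res.n_pairs == 4

    def test_anti_correlated(self):
        x = np.array([3.0, 5.0, 7.0, 9.0])
        res = pearson_by_colony(self._paired_frame(x, -x), 30.0)
        assert res.r == pytest.approx(-1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(5, 2, 10), rng.normal(8, 3, 10)
        r0 = pearson_by_colony(self._paired_frame(x, y), 30.0).r
        r1 = pearson_by_colony(self._paired_frame(2.5 * x + 1, y), 30.0).r
        r2 = pearson_by_colony(self._paired_frame(x, 0.3 * y - 7), 30.0).r
        assert r1 == pytest.approx(r0, abs=1e-12)
        assert r2 == pytest.approx(r0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_by_colony(
                self._paired_frame([5, 5, 5, 5], [1, 2, 3, 4]), 30.0
            )

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="3 complete"):
            pearson_by_colony(self._paired_frame([1, 2], [3, 4]), 30.0)


class TestCV:
    def test_constant_values_zero(self):
        assert cv_percent([4, 4, 4, 4, 4]) == 0.0

    def test_hand_arithmetic(self):
        # SD({1,3}, n-1) = sqrt(2); mean = 2 -> 100*sqrt(2)/2
        assert cv_percent([1, 3]) == pytest.approx(100 * np.sqrt(2) / 2)
        assert cv_percent([1, 3]) == pytest.approx(70.71, abs=0.01)

    def test_zero_mean_undefined(self):
        with pytest.raises(ValueError, match="mean"):
            cv_percent([-1.0, 1.0])

    def test_cv_table_layout(self):
        df = _bti_frame({"A": [5, 5.5, 6], "B": [9, 10, 11]}, cutoff=10.0)
        out = cv_table(df, cutoffs=(10.0,))
        assert set(out["species"]) == {"A", "B"}
        row = out[out.species == "A"].iloc[0]
        assert row.cv_percent == pytest.approx(cv_percent([5, 5.5, 6]))
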