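"""Omics statistics: normalization, differential screen, FDR equivalence,
scatter normalization, correlations and the factorial screen."""

import numpy as np
import pandas as pd
import pytest

from mitoflex.errors import ConfigurationError, DomainError
from mitoflex.omics import (
    correlate_with_index,
    diet_response_scatter,
    differential,
    factorial_screen,
    normalize_to_class_standard,
)

from conftest import make_omics


def bh_oracle(p):
    """Independent Benjamini-Hochberg step-up implementation."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def two_group_table(lfd, hfd, age="old", **kwargs):
    lfd = np.asarray(lfd, dtype=float)
    hfd = np.asarray(hfd, dtype=float)
    values = np.hstack([lfd, hfd])
    n1, n2 = lfd.shape[1], hfd.shape[1]
    return make_omics(values, ages=[age] * (n1 + n2),
                      diets=["LFD"] * n1 + ["HFD"] * n2, **kwargs)


class TestNormalization:
    def test_unit_standards_are_identity(self):
        table = make_omics([[1.0, 2.0], [3.0, 4.0]], ages=["old", "old"],
                           diets=["LFD", "HFD"], classes=["TG", "PC"])
        out = normalize_to_class_standard(table, {"TG": 1.0, "PC": 1.0})
        assert np.allclose(out.values, table.values)

    def test_single_class_halved_others_untouched(self):
        table = make_omics([[2.0, 4.0], [3.0, 9.0]], ages=["old", "old"],
                           diets=["LFD", "HFD"], classes=["TG", "PC"])
        out = normalize_to_class_standard(table, {"TG": 2.0, "PC": 1.0})
        assert np.allclose(out.values.iloc[0], [1.0, 2.0])
        assert np.allclose(out.values.iloc[1], [3.0, 9.0])

    def test_missing_class_uses_mean_of_standards(self):
        # standards {1, 3} elsewhere -> missing class divided by 2
        table = make_omics([[4.0, 8.0]], ages=["old", "old"],
                           diets=["LFD", "HFD"], classes=["CER"])
        out = normalize_to_class_standard(table, {"TG": 1.0, "PC": 3.0})
        assert np.allclose(out.values.iloc[0], [2.0, 4.0])

    def test_zero_standard_names_the_class(self):
        table = make_omics([[1.0, 1.0]], ages=["old", "old"],
                           diets=["LFD", "HFD"], classes=["TG"])
        with pytest.raises(DomainError, match="TG"):
            normalize_to_class_standard(table, {"TG": 0.0})

    def test_requires_class_annotations(self):
        table = make_omics([[1.0, 1.0]], ages=["old", "old"],
                           diets=["LFD", "HFD"])
        with pytest.raises(ConfigurationError):
            normalize_to_class_standard(table, {"TG": 1.0})


class TestDifferential:
    def test_identical_groups_nothing_flagged(self, rng):
        base = rng.uniform(1, 10, size=(20, 1))
        values = np.tile(base, (1, 6))
        table = two_group_table(values[:, :3], values[:, 3:])
        out = differential(table, "old")
        assert np.allclose(out["fold_change"], 1.0)
        assert not out["significant"].any()

    def test_planted_analyte_recovered_exactly(self, rng):
        # 100 analytes, one shifted x4 with 5% within-group CV, others noise
        n = 100
        base = rng.uniform(10, 100, size=n)
        sigma = np.sqrt(np.log(1 + 0.05 ** 2))
        lfd = base[:, None] * np.exp(rng.normal(0, sigma, (n, 5)))
        hfd = base[:, None] * np.exp(rng.normal(0, sigma, (n, 5)))
        hfd[17] *= 4.0
        table = two_group_table(lfd, hfd)
        out = differential(table, "old")
        flagged = set(out.index[out["significant"]])
        assert flagged == {"a17"}

    def test_fdr_matches_independent_oracle(self, rng):
        n = 200
        lfd = rng.uniform(1, 10, (n, 4)) ** 2
        hfd = rng.uniform(1, 10, (n, 4)) ** 2
        table = two_group_table(lfd, hfd)
        out = differential(table, "old", fdr="bh")
        assert np.allclose(out["q"], bh_oracle(out["p"]), atol=1e-12)

    def test_q_at_least_p(self, rng):
        lfd = rng.uniform(1, 10, (50, 4))
        hfd = rng.uniform(1, 10, (50, 4))
        out = differential(two_group_table(lfd, hfd), "old")
        assert (out["q"] >= out["p"] - 1e-15).all()

    def test_flag_requires_both_gates(self, rng):
        # highly significant but FC 1.2 -> not flagged
        n = 30
        base = np.full((n, 1), 50.0)
        sigma = np.sqrt(np.log(1 + 0.01 ** 2))
        lfd = base * np.exp(rng.normal(0, sigma, (n, 6)))
        hfd = base * np.exp(rng.normal(0, sigma, (n, 6)))
        hfd[3] *= 1.2
        out = differential(two_group_table(lfd, hfd), "old")
        assert out.loc["a3", "q"] < 0.05
        assert 1.1 < out.loc["a3", "fold_change"] < 1.3
        assert not out.loc["a3", "significant"]

    def test_mean_centring_leaves_t_unchanged(self, rng):
        from mitoflex.omics import _welchless_t

        lfd = np.log2(rng.uniform(1, 10, (25, 5)))
        hfd = np.log2(rng.uniform(1, 10, (25, 5)))
        both = np.hstack([lfd, hfd])
        centred = both - both.mean(axis=1, keepdims=True)
        t_raw, _ = _welchless_t(both[:, :5], both[:, 5:])
        t_centred, _ = _welchless_t(centred[:, :5], centred[:, 5:])
        assert np.allclose(t_raw, t_centred, atol=1e-10)

    def test_order_invariance_of_flag_counts(self, rng):
        n = 60
        lfd = rng.uniform(1, 10, (n, 4)) ** 2
        hfd = rng.uniform(1, 10, (n, 4)) ** 2
        hfd[:5] *= 3.0
        table = two_group_table(lfd, hfd)
        baseline = int(differential(table, "old")["significant"].sum())
        rows = rng.permutation(table.values.index)
        cols = rng.permutation(table.values.columns)
        shuffled = make_omics(
            table.values.loc[rows, cols].to_numpy(),
            ages=[table.samples.loc[c, "age"] for c in cols],
            diets=[table.samples.loc[c, "diet"] for c in cols],
            analytes=list(rows),
        )
        assert int(differential(shuffled, "old")["significant"].sum()) == baseline

    def test_degenerate_variance_convention(self):
        values = np.array([[5.0, 5.0, 5.0, 5.0]])
        out = differential(two_group_table(values[:, :2], values[:, 2:]), "old")
        assert out["p"].iloc[0] == 1.0

    def test_stratum_size_guard(self):
        table = make_omics([[1.0, 2.0, 3.0]], ages=["old"] * 3,
                           diets=["LFD", "HFD", "HFD"])
        with pytest.raises(DomainError):
            differential(table, "old")

    def test_two_stage_option_runs(self, rng):
        lfd = rng.uniform(1, 10, (40, 4))
        hfd = rng.uniform(1, 10, (40, 4))
        out = differential(two_group_table(lfd, hfd), "old", fdr="two-stage")
        assert out.attrs["fdr_method"] == "two-stage"


class TestScatter:
    def test_no_effect_lands_on_identity_point(self):
        table = make_omics(np.full((1, 4), 6.0), ages=["young"] * 4,
                           diets=["LFD", "LFD", "HFD", "HFD"])
        out = diet_response_scatter(table)
        assert out["lfd_mean"].iloc[0] == pytest.approx(1.0)
        assert out["hfd_mean"].iloc[0] == pytest.approx(1.0)

    def test_doubled_hfd_balanced_groups(self):
        table = make_omics(np.array([[1.0, 1.0, 2.0, 2.0]]), ages=["young"] * 4,
                           diets=["LFD", "LFD", "HFD", "HFD"])
        out = diet_response_scatter(table)
        assert out["lfd_mean"].iloc[0] == pytest.approx(2.0 / 3.0)
        assert out["hfd_mean"].iloc[0] == pytest.approx(4.0 / 3.0)

    def test_scale_invariance(self):
        a = make_omics(np.array([[1.0, 3.0, 2.0, 5.0]]), ages=["young"] * 4,
                       diets=["LFD", "LFD", "HFD", "HFD"])
        b = make_omics(np.array([[1.0, 3.0, 2.0, 5.0]]) * 1e6,
                       ages=["young"] * 4, diets=["LFD", "LFD", "HFD", "HFD"])
        pd.testing.assert_frame_equal(diet_response_scatter(a),
                                      diet_response_scatter(b))


class TestCorrelate:
    def labels(self, n):
        half = n // 2
        return dict(ages=["young"] * half + ["old"] * (n - half),
                    diets=(["LFD", "HFD"] * n)[:n])

    def test_identical_to_index(self):
        idx = pd.Series([1.0, 2.0, 3.0, 4.0], index=[f"s{i}" for i in range(4)])
        table = make_omics(idx.to_numpy()[None, :], **self.labels(4))
        out = correlate_with_index(table, idx)
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_negated_index(self):
        idx = pd.Series([1.0, 2.0, 3.0, 4.0], index=[f"s{i}" for i in range(4)])
        table = make_omics((-idx.to_numpy() + 10.0)[None, :], **self.labels(4))
        out = correlate_with_index(table, idx)
        assert out["r"].iloc[0] == pytest.approx(-1.0)

    def test_textbook_formula_oracle(self, rng):
        n = 12
        idx = pd.Series(rng.normal(0, 1, n) + 5, index=[f"s{i}" for i in range(n)])
        y = -0.6 * idx.to_numpy() + rng.normal(0, 0.8, n) + 10.0
        y = np.maximum(y, 0.0)
        table = make_omics(y[None, :], **self.labels(n))
        out = correlate_with_index(table, idx)
        x = idx.to_numpy()
        r_oracle = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        assert out["r"].iloc[0] == pytest.approx(r_oracle, abs=1e-12)

    def test_zero_variance_flagged(self):
        idx = pd.Series([1.0, 2.0, 3.0, 4.0], index=[f"s{i}" for i in range(4)])
        table = make_omics(np.full((1, 4), 3.0), **self.labels(4))
        out = correlate_with_index(table, idx)
        assert not out["defined"].iloc[0]
        assert np.isnan(out["r"].iloc[0])

    def test_needs_three_observations(self):
        idx = pd.Series([1.0, 2.0], index=["s0", "s1"])
        table = make_omics([[1.0, 2.0]], ages=["young", "old"],
                           diets=["LFD", "HFD"])
        with pytest.raises(DomainError):
            correlate_with_index(table, idx)


class TestFactorial:
    def four_cell_table(self, values):
        n = values.shape[1] // 4
        ages = ["young"] * (2 * n) + ["old"] * (2 * n)
        diets = (["LFD"] * n + ["HFD"] * n) * 2
        return make_omics(values, ages=ages, diets=diets)

    def test_matches_statsmodels_type2(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        values = rng.normal(10, 2, size=(5, 16))
        values[2, 4:8] += 3.0  # young-HFD bump -> interaction + diet signal
        table = self.four_cell_table(values)
        out = factorial_screen(table, tukey=False)
        for i in range(5):
            df = pd.DataFrame({
                "y": values[i],
                "age": table.samples["age"].to_numpy(),
                "diet": table.samples["diet"].to_numpy(),
            })
            fit = ols("y ~ C(age) * C(diet)", data=df).fit()
            anova = sm.stats.anova_lm(fit, typ=2)
            assert out["p_age"].iloc[i] == pytest.approx(
                anova.loc["C(age)", "PR(>F)"], rel=1e-8)
            assert out["p_diet"].iloc[i] == pytest.approx(
                anova.loc["C(diet)", "PR(>F)"], rel=1e-8)
            assert out["p_interaction"].iloc[i] == pytest.approx(
                anova.loc["C(age):C(diet)", "PR(>F)"], rel=1e-8)

    def test_label_swap_flips_directions_preserves_p(self, rng):
        values = rng.normal(10, 2, size=(8, 12))
        values[:, 3:6] *= 1.4
        table = self.four_cell_table(values)
        swapped_diets = table.samples["diet"].map({"LFD": "HFD", "HFD": "LFD"})
        swapped = make_omics(values, ages=list(table.samples["age"]),
                             diets=list(swapped_diets))
        a = factorial_screen(table, tukey=False)
        b = factorial_screen(swapped, tukey=False)
        assert np.allclose(a["p_diet"], b["p_diet"], atol=1e-12)
        assert np.allclose(a["dir_diet"], -b["dir_diet"])

    def test_planted_diet_effect_detected(self, rng):
        # +50% diet effect, CV 10%, n = 6/cell: detected, age effect not
        n_rep = 30
        hits_diet, hits_age = 0, 0
        for _ in range(n_rep):
            base = 100.0
            sigma = np.sqrt(np.log(1 + 0.1 ** 2))
            cells = []
            for age in ("young", "old"):
                for diet in ("LFD", "HFD"):
                    mult = 1.5 if diet == "HFD" else 1.0
                    cells.append(base * mult * np.exp(rng.normal(0, sigma, 6)))
            values = np.hstack(cells)[None, :]
            ages = ["young"] * 12 + ["old"] * 12
            diets = (["LFD"] * 6 + ["HFD"] * 6) * 2
            out = factorial_screen(make_omics(values, ages=ages, diets=diets),
                                   tukey=False)
            hits_diet += out["p_diet"].iloc[0] < 0.05
            hits_age += out["p_age"].iloc[0] < 0.05
        assert hits_diet >= int(0.95 * n_rep)
        assert hits_age < int(0.5 * n_rep)

    def test_empty_cell_rejected(self):
        table = make_omics(np.ones((1, 6)), ages=["young"] * 6,
                           diets=["LFD", "LFD", "LFD", "HFD", "HFD", "HFD"])
        with pytest.raises(DomainError):
            factorial_screen(table)

    def test_tukey_columns_present_and_bounded(self, rng):
        values = rng.normal(10, 2, size=(4, 12))
        table = self.four_cell_table(values)
        out = factorial_screen(table, tukey=True)
        for col in ("p_tukey_diet_young", "p_tukey_diet_old",
                    "p_tukey_age_lfd", "p_tukey_age_hfd"):
            assert ((out[col] >= 0) & (out[col] <= 1)).all()
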