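import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernaforge import ddct, duncan_groups, fatty_acid_ratios, trait_correlation


def ct_frame(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "target_id", "ct_target", "ct_reference"]
    )


class TestDdct:
    def test_zero_ddct_is_fold_one(self):
        rec = ct_frame([("s1", "cal", "t", 20.0, 15.0), ("s2", "cal", "t", 20.0, 15.0)])
        out = ddct(rec, "cal")
        assert (out["rel_expression"] == 1.0).all()

    def test_worked_case_fold_four(self):
        rec = ct_frame([("s1", "cal", "t", 22.0, 15.0), ("s2", "tr", "t", 20.0, 15.0)])
        out = ddct(rec, "cal")
        assert out.loc[out["group"] == "tr", "ddct"].iloc[0] == -2.0
        assert out.loc[out["group"] == "tr", "rel_expression"].iloc[0] == 4.0

    def test_global_ct_shift_invariant(self):
        rec = ct_frame(
            [("s1", "cal", "t", 22.0, 15.0), ("s2", "tr", "t", 20.0, 16.5)]
        )
        shifted = rec.copy()
        shifted[["ct_target", "ct_reference"]] += 3.25
        pd.testing.assert_series_equal(
            ddct(rec, "cal")["rel_expression"], ddct(shifted, "cal")["rel_expression"]
        )

    def test_calibrator_geometric_mean_is_one(self):
        rng = np.random.default_rng(2)
        rows = [
            (f"s{i}", "cal" if i < 4 else "tr", "t", 20 + rng.normal(), 15 + rng.normal())
            for i in range(8)
        ]
        out = ddct(ct_frame(rows), "cal")
        cal = out[out["group"] == "cal"]["rel_expression"]
        assert np.exp(np.log(cal).mean()) == pytest.approx(1.0, abs=1e-12)

    def test_missing_reference_rejected(self):
        rec = ct_frame([("s1", "cal", "t", 22.0, np.nan)])
        with pytest.raises(ValueError, match="reference"):
            ddct(rec, "cal")

    def test_unknown_calibrator_rejected(self):
        rec = ct_frame([("s1", "cal", "t", 22.0, 15.0)])
        with pytest.raises(ValueError, match="calibrator"):
            ddct(rec, "nope")


class TestTraitCorrelation:
    def grid(self, x, ys):
        samples = [f"s{i}" for i in range(len(x))]
        expr = pd.DataFrame([x], index=["L"], columns=samples)
        traits = pd.DataFrame(ys, index=samples)
        return expr, traits

    def test_exact_linear_relation(self):
        x = np.array([1.0, 2, 4, 3, 5, 7, 6, 8])
        expr, traits = self.grid(x, {"fa": 2 * x})
        out = trait_correlation(expr, traits)
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "p_value"] == 0.0
        assert out.loc[0, "stars"] == "***"

    def test_zero_r_gives_p_one(self):
        x = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        y = np.array([1.0, 1, -1, -1, 1, 1, -1, -1])
        expr, traits = self.grid(x, {"fa": y})
        out = trait_correlation(expr, traits)
        assert out.loc[0, "r"] == pytest.approx(0.0, abs=1e-15)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=16)
        y = 0.5 * x + rng.normal(size=16)
        expr, traits = self.grid(x, {"fa": y})
        out = trait_correlation(expr, traits)
        ref = stats.pearsonr(x, y)
        assert out.loc[0, "r"] == pytest.approx(ref.statistic, abs=1e-12)
        assert out.loc[0, "p_value"] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_variance_reported_missing(self):
        expr, traits = self.grid(np.ones(6), {"fa": np.arange(6.0)})
        out = trait_correlation(expr, traits)
        assert np.isnan(out.loc[0, "r"]) and np.isnan(out.loc[0, "p_value"])


def duncan_oracle(values_by_group, alpha=0.05):
    """Independent formulation: a sorted pair is separated iff EVERY range
    containing it exceeds that range's least significant range."""
    groups = sorted(values_by_group, key=lambda g: (np.mean(values_by_group[g]), g))
    means = np.array([np.mean(values_by_group[g]) for g in groups])
    ns = np.array([len(values_by_group[g]) for g in groups])
    df = int(ns.sum() - len(groups))
    mse = sum(
        ((np.asarray(values_by_group[g]) - np.mean(values_by_group[g])) ** 2).sum()
        for g in groups
    ) / df
    nh = len(groups) / (1.0 / ns).sum()
    k = len(groups)

    lsr_cache = {}

    def lsr(p):
        if p not in lsr_cache:  # ppf of the studentized range is expensive
            lsr_cache[p] = stats.studentized_range.ppf((1 - alpha) ** (p - 1), p, df) * np.sqrt(
                mse / nh
            )
        return lsr_cache[p]

    separated = {}
    for i, j in itertools.combinations(range(k), 2):
        separated[(i, j)] = all(
            means[b] - means[a] > lsr(b - a + 1) for a in range(i + 1) for b in range(j, k)
        )
    return groups, separated


class TestDuncan:
    def assert_matches_oracle(self, data, alpha=0.05):
        letters = duncan_groups(data, alpha=alpha)
        groups, separated = duncan_oracle(data, alpha=alpha)
        for (i, j), sep in separated.items():
            shares = bool(set(letters[groups[i]]) & set(letters[groups[j]]))
            assert shares != sep, (groups[i], groups[j], letters)

    def test_two_clearly_separated_groups(self):
        rng = np.random.default_rng(0)
        data = {"g1": rng.normal(0, 1, 4), "g2": rng.normal(100, 1, 4)}
        assert sorted(duncan_groups(data).values()) == ["a", "b"]
        # direct two-group studentized-range computation agrees
        self.assert_matches_oracle(data)

    def test_identical_groups_share_one_letter(self):
        data = {g: [5.0, 5.0, 5.0] for g in "abcd"}
        assert set(duncan_groups(data).values()) == {"a"}

    def test_letter_assignment_invariant_to_input_order(self):
        rng = np.random.default_rng(4)
        data = {g: rng.normal(i, 1, 4) for i, g in enumerate("abcde")}
        forward = duncan_groups(data)
        backward = duncan_groups(dict(reversed(list(data.items()))))
        assert forward == backward

    @pytest.mark.parametrize("seed,spread", [(0, 0.5), (1, 1.0), (2, 3.0), (3, 8.0)])
    def test_oracle_agreement_on_random_layouts(self, seed, spread):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        data = {
            f"g{i}": rng.normal(i * spread, 1.0, int(rng.integers(2, 7))) for i in range(k)
        }
        self.assert_matches_oracle(data)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            duncan_groups({"a": [1.0], "b": [1.0, 2.0]})


class TestRatios:
    classes = pd.DataFrame(
        {
            "saturation_class": {"C16:0": "SFA", "C18:1": "MUFA", "C18:2n6": "PUFA", "C18:3n3": "PUFA"},
            "omega_class": {"C16:0": "none", "C18:1": "none", "C18:2n6": "n-6", "C18:3n3": "n-3"},
        }
    )

    def test_worked_ratio(self):
        traits = pd.DataFrame(
            {"C16:0": [4.0], "C18:1": [1.0], "C18:2n6": [1.5], "C18:3n3": [0.5]}, index=["s1"]
        )
        out = fatty_acid_ratios(traits, self.classes)
        assert out.loc["s1", "PUFA_SFA"] == 0.5
        assert out.loc["s1", "n6_n3"] == 3.0
        assert out.loc["s1", "SFA"] == 4.0 and out.loc["s1", "PUFA"] == 2.0

    def test_zero_denominator_reported_missing(self):
        traits = pd.DataFrame(
            {"C16:0": [0.0], "C18:1": [1.0], "C18:2n6": [1.5], "C18:3n3": [0.0]}, index=["s1"]
        )
        out = fatty_acid_ratios(traits, self.classes)
        assert np.isnan(out.loc["s1", "PUFA_SFA"]) and np.isnan(out.loc["s1", "n6_n3"])

    def test_class_sums_additive_under_split(self):
        whole = pd.DataFrame({"C16:0": [4.0], "C18:1": [1.0], "C18:2n6": [2.0], "C18:3n3": [1.0]}, index=["s"])
        halves = pd.DataFrame(
            {"C16:0": [4.0], "C18:1": [1.0], "C18:2n6": [1.0], "C20:4n6": [1.0], "C18:3n3": [1.0]},
            index=["s"],
        )
        classes2 = pd.concat(
            [
                self.classes,
                pd.DataFrame({"saturation_class": {"C20:4n6": "PUFA"}, "omega_class": {"C20:4n6": "n-6"}}),
            ]
        )
        a = fatty_acid_ratios(whole, self.classes)
        b = fatty_acid_ratios(halves, classes2)
        assert a.loc["s", "PUFA"] == b.loc["s", "PUFA"]
        assert a.loc["s", "n6_n3"] == b.loc["s", "n6_n3"]

    def test_unlabeled_trait_rejected(self):
        traits = pd.DataFrame({"mystery": [1.0]}, index=["s1"])
        with pytest.raises(ValueError, match="mystery"):
            fatty_acid_ratios(traits, self.classes)
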