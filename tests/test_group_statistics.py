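"""Statistical battery: Mann-Whitney, Bonferroni, Cohen's d, diagnostics,
rank correlations, and the comparison registry."""

from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pytest

from restdcx.exceptions import (
    InsufficientDataError,
    InvalidSpecError,
    UndefinedEffectError,
)
from restdcx.group_statistics import (
    bonferroni,
    clinical_correlations,
    cohens_d,
    diagnostic_metrics,
    label_effect_size,
    mann_whitney_u,
    run_comparison_registry,
    spearman,
)


def exact_mwu_p(x, y):
    """Brute-force oracle: enumerate every assignment of the pooled sample
    into groups of sizes (n1, n2) and count U statistics at least as extreme."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_of(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    u_obs = u_of(x, y)
    mu = n1 * len(y) / 2.0
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_of(xs, ys)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_worked_example_enumeration(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1, abs=1e-12)
        assert p == pytest.approx(exact_mwu_p([1, 2, 3], [4, 5, 6]), abs=1e-12)

    def test_identical_samples_give_p_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_symmetry_under_group_swap(self, rng):
        x = rng.normal(size=7)
        y = rng.normal(size=12)
        _, p1 = mann_whitney_u(x, y)
        _, p2 = mann_whitney_u(y, x)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_exact_and_asymptotic_agree_for_small_samples(self):
        """Tie-free samples with min(n) <= 8: normal approximation within
        0.03 of the exact permutation p over 500 random cases."""
        gen = np.random.default_rng(42)
        worst = 0.0
        for _ in range(500):
            n1 = int(gen.integers(4, 9))
            n2 = int(gen.integers(6, 21))
            x = gen.normal(size=n1)
            y = gen.normal(size=n2)
            _, p_exact = mann_whitney_u(x, y, mode="exact")
            _, p_approx = mann_whitney_u(x, y, mode="asymptotic")
            worst = max(worst, abs(p_exact - p_approx))
        assert worst <= 0.03

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidSpecError):
            mann_whitney_u([], [1.0])


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected", [(0.004, 8, 0.032), (0.5, 8, 1.0), (0.2, 1, 0.2)]
    )
    def test_arithmetic(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected, abs=1e-15)


class TestCohensD:
    def test_equal_means_give_zero(self):
        d, _ = cohens_d([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert d == 0.0

    def test_worked_example(self):
        """x=[2,3,4], y=[1,2,3]: both SDs are 1, so d = 1.0, labelled large."""
        d, label = cohens_d([2, 3, 4], [1, 2, 3])
        assert d == pytest.approx(1.0, abs=1e-12)
        assert label == "large"

    @pytest.mark.parametrize(
        "value,expected",
        [(0.005, "negligible"), (0.05, "very small"), (0.3, "small"),
         (0.6, "medium"), (1.0, "large"), (1.32, "very large"),
         (2.5, "huge"), (-1.32, "very large")],
    )
    def test_magnitude_labels(self, value, expected):
        assert label_effect_size(value) == expected

    def test_zero_pooled_sd_with_unequal_means(self):
        with pytest.raises(UndefinedEffectError):
            cohens_d([1.0, 1.0], [2.0, 2.0])


class TestDiagnostics:
    def test_worked_example_counts(self):
        """Ten controls at 1.0 make the threshold 1.0; patients [2.0, 0.5]:
        TP=1, FN=1, TN=10, FP=0 -> sens 50%, spec 100%, PPV 100%, NPV 90.9%."""
        rep = diagnostic_metrics([2.0, 0.5], [1.0] * 10)
        assert rep.threshold == 1.0
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (1, 1, 10, 0)
        assert rep.sensitivity == 50.0
        assert rep.specificity == 100.0
        assert rep.ppv == 100.0
        assert rep.npv == pytest.approx(100 * 10 / 11, abs=0.01)

    def test_no_positive_patients(self):
        rep = diagnostic_metrics([0.1, 0.2], [1.0, 1.0, 1.0])
        assert rep.sensitivity == 0.0
        assert np.isnan(rep.ppv)
        assert rep.npv == pytest.approx(100 * rep.tn / (rep.tn + 2))

    def test_shift_invariance(self, rng):
        pat = rng.normal(1.0, 0.3, size=20)
        con = rng.normal(0.0, 0.3, size=16)
        a = diagnostic_metrics(pat, con)
        b = diagnostic_metrics(pat + 5.0, con + 5.0)
        assert (a.tp, a.fp, a.tn, a.fn) == (b.tp, b.fp, b.tn, b.fn)

    def test_count_identities_on_random_inputs(self, rng):
        for _ in range(25):
            pat = rng.normal(size=rng.integers(2, 30))
            con = rng.normal(size=rng.integers(2, 30))
            rep = diagnostic_metrics(pat, con)
            assert rep.tp + rep.fn == len(pat)
            assert rep.tn + rep.fp == len(con)
            for rate in (rep.sensitivity, rep.specificity):
                assert 0.0 <= rate <= 100.0


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_constant_covariate_warns_and_is_nan(self):
        with pytest.warns(UserWarning):
            rho, p = spearman([1, 2, 3, 4], [7, 7, 7, 7])
        assert np.isnan(rho) and np.isnan(p)

    def test_exact_p_matches_full_enumeration(self):
        """n=4 with one discordant swap: p equals the fraction of the 24 rank
        permutations with |rho| at least as large."""
        x = [1, 2, 3, 4]
        y = [1, 2, 4, 3]
        rho, p = spearman(x, y)
        base = np.arange(1, 5)
        rhos = []
        for perm in permutations(base):
            d2 = np.sum((np.array(perm) - base) ** 2)
            rhos.append(1 - 6 * d2 / (4 * 15))
        expected = np.mean(np.abs(rhos) >= abs(rho) - 1e-12)
        assert p == pytest.approx(expected, abs=1e-12)
        assert rho == pytest.approx(0.8, abs=1e-12)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            spearman([1, 2], [2, 1])


def _synthetic_cohort_tables(rng, effect=0.0, n_controls=10, n_patients=14):
    """Hand-built efficiency + metadata tables with all subgroups populated."""
    rows, recs = [], []
    for i in range(n_controls + n_patients):
        group = "control" if i < n_controls else "patient"
        sid = f"s{i:02d}"
        ge = rng.normal(0.3 + (effect if group == "patient" else 0.0), 0.03)
        rec = {"subject_id": sid, "ge_whole": ge}
        for rsn in ("visual", "somatomotor", "dorsal_attention", "ventral_attention",
                    "limbic", "frontoparietal", "default_mode"):
            rec[f"ge_{rsn}"] = rng.normal(0.2, 0.02)
        recs.append(rec)
        if group == "control":
            rows.append({"subject_id": sid, "group": group, "lobe": "na",
                         "lesional": "na", "side": "na", "ilae": "",
                         "onset_age": "", "duration": ""})
        else:
            j = i - n_controls
            rows.append({
                "subject_id": sid, "group": group,
                "lobe": "temporal" if j % 3 else "extratemporal",
                "lesional": "yes" if j % 2 else "no",
                "side": "L" if j % 4 < 2 else "R",
                "ilae": (j % 5) + 1,
                "onset_age": 10 + j, "duration": 5 + j,
            })
    return pd.DataFrame(recs), pd.DataFrame(rows)


class TestComparisonRegistry:
    def test_whole_brain_registry_has_eight_comparisons(self, rng):
        reports, metadata = _synthetic_cohort_tables(rng)
        comparisons, diagnostics, correlations = run_comparison_registry(
            reports, metadata
        )
        whole = comparisons[comparisons["network"] == "whole"]
        assert sorted(whole["comparison_id"]) == list("abcdefgh")
        # Bonferroni over the 8 whole-brain comparisons
        np.testing.assert_allclose(
            whole["p_bonferroni"], np.minimum(1.0, 8 * whole["p_raw"])
        )

    def test_rsn_registry_reports_seven_networks_per_comparison(self, rng):
        reports, metadata = _synthetic_cohort_tables(rng)
        comparisons, _, _ = run_comparison_registry(reports, metadata)
        rsn = comparisons[comparisons["network"] != "whole"]
        for cid in "abcdefg":
            nets = rsn[rsn["comparison_id"] == cid]["network"]
            assert len(nets) == 7
        assert "h" not in set(rsn["comparison_id"])
        np.testing.assert_allclose(
            rsn["p_bonferroni"], np.minimum(1.0, 7 * rsn["p_raw"])
        )

    def test_identical_groups_give_null_results(self, rng):
        reports, metadata = _synthetic_cohort_tables(rng)
        # make every patient value identical to a control counterpart pattern
        reports["ge_whole"] = 0.5
        comparisons, _, _ = run_comparison_registry(reports, metadata)
        whole = comparisons[comparisons["network"] == "whole"]
        assert np.all(whole["p_raw"] == 1.0)
        assert np.all(whole["cohen_d"] == 0.0)

    def test_diagnostics_and_correlations_present(self, rng):
        reports, metadata = _synthetic_cohort_tables(rng, effect=0.2)
        _, diagnostics, correlations = run_comparison_registry(reports, metadata)
        assert list(diagnostics["group"]) == ["patients", "TLE", "ETLE"]
        assert sorted(correlations["variable"]) == ["duration", "ilae", "onset"]

    def test_empty_subgroup_warns_and_is_skipped(self, rng):
        reports, metadata = _synthetic_cohort_tables(rng)
        metadata.loc[metadata["lobe"] == "extratemporal", "lobe"] = "temporal"
        with pytest.warns(UserWarning, match="skipped"):
            comparisons, _, _ = run_comparison_registry(reports, metadata)
        assert "c" not in set(comparisons["comparison_id"])


def test_clinical_correlations_pairwise_dropping(rng):
    values = pd.Series(rng.normal(size=12))
    clinical = pd.DataFrame({
        "onset_age": list(rng.integers(5, 40, size=10)) + [np.nan, np.nan],
        "duration": rng.integers(1, 30, size=12),
        "ilae": rng.integers(1, 6, size=12),
    })
    out = clinical_correlations(values, clinical)
    assert int(out.loc[out["variable"] == "onset", "n"].iloc[0]) == 10
    assert int(out.loc[out["variable"] == "duration", "n"].iloc[0]) == 12
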