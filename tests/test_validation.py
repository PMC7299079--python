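import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from cogclust.synthetic import cohort_preset, generate
from cogclust.validation import (
    align_labels,
    chi_square,
    cohen_kappa,
    composition_chi_square,
    crosstab,
    label_profiles,
    load_cluster_composition,
    load_diagnosis_distribution,
    per_item_chi_square,
    within_stratum_validation,
)

from conftest import profiles_from_codes


def _series(values, ids=None):
    ids = ids or [f"s{i}" for i in range(len(values))]
    return pd.Series(values, index=pd.Index(ids, name="subject_id"))


class TestCrosstab:
    def test_hand_tally(self):
        assignment = _series([1, 1, 1, 2, 2, 2])
        levels = _series(["below", "below", "within", "above", "above", "within"])
        table = crosstab(assignment, levels)
        assert table.loc[1, "below"] == 2
        assert table.loc[1, "within"] == 1
        assert table.loc[2, "above"] == 2
        assert table.to_numpy().sum() == 6

    def test_single_cluster_single_row(self):
        table = crosstab(_series([1, 1]), _series(["below", "above"]))
        assert table.shape[0] == 1

    def test_disjoint_subjects_raise(self):
        a = _series([1], ids=["x"])
        b = _series(["below"], ids=["y"])
        with pytest.raises(ValueError):
            crosstab(a, b)


class TestChiSquare:
    def test_proportional_rows_give_zero(self):
        res = chi_square(np.array([[10, 20, 30], [20, 40, 60]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 2

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square(np.array([[5, 0], [7, 0]]))

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            chi_square(np.array([[5, 5]]))

    def test_brute_force_oracle(self, rng):
        """Statistic equals the direct sum (O - E)^2 / E from margins."""
        for _ in range(50):
            shape = (int(rng.integers(2, 5)), int(rng.integers(2, 5)))
            table = rng.integers(1, 60, size=shape).astype(float)
            res = chi_square(table)
            total = table.sum()
            expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
            stat = ((table - expected) ** 2 / expected).sum()
            assert res.statistic == pytest.approx(stat, abs=1e-9)
            assert res.df == (shape[0] - 1) * (shape[1] - 1)

    def test_published_composition_rows_reproduce(self):
        """Every bundled cluster-composition row recomputes to its published
        chi-square at the printed precision."""
        table = composition_chi_square()
        assert len(table) == 20
        for _, row in table.iterrows():
            printed = f"{row.published_statistic}"
            decimals = len(printed.split(".")[1]) if "." in printed else 0
            assert round(row.statistic, decimals) == pytest.approx(
                row.published_statistic
            ), f"{row.method}/{row['item']}"
            assert row.p_value < 0.001


def _profiles_matching_counts(method="twostep"):
    """Build a 387-subject level table + assignment matching the bundled
    per-item cluster composition counts (items filled independently)."""
    comp = load_cluster_composition()
    comp = comp[comp.method == method].set_index("item")
    n_low = int(comp.iloc[0][["low_below", "low_within", "low_above"]].sum())
    n_high = int(comp.iloc[0][["high_below", "high_within", "high_above"]].sum())
    ids = [f"s{i:03d}" for i in range(n_low + n_high)]
    assignment = _series([1] * n_low + [2] * n_high, ids=ids)
    data = {}
    for item, row in comp.iterrows():
        col = (
            ["below"] * int(row.low_below)
            + ["within"] * int(row.low_within)
            + ["above"] * int(row.low_above)
            + ["below"] * int(row.high_below)
            + ["within"] * int(row.high_within)
            + ["above"] * int(row.high_above)
        )
        data[item] = col
    return assignment, pd.DataFrame(data, index=assignment.index)


def test_per_item_chi_square_matches_published():
    assignment, profiles = _profiles_matching_counts("twostep")
    table = per_item_chi_square(assignment, profiles)
    assert table.loc["MCST_categories", "statistic"] == pytest.approx(60.56, abs=0.005)
    assert table.loc["ToL_total_moves", "statistic"] == pytest.approx(183.7, abs=0.05)


class TestLabelProfiles:
    def test_higher_below_share_is_low(self):
        assignment = _series([1] * 10 + [2] * 10)
        levels = ["below"] * 4 + ["within"] * 6 + ["below"] * 1 + ["within"] * 9
        profiles = pd.DataFrame({"item": levels}, index=assignment.index)
        labels, flags = label_profiles(assignment, profiles)
        assert labels == {1: "Low", 2: "High"}
        assert flags == []

    def test_published_fixture_cluster1_is_low(self):
        assignment, profiles = _profiles_matching_counts("twostep")
        labels, _ = label_profiles(assignment, profiles)
        assert labels[1] == "Low"
        assert labels[2] == "High"

    def test_exact_tie_flagged(self):
        assignment = _series([1, 1, 2, 2])
        profiles = pd.DataFrame(
            {"item": ["below", "within", "below", "within"]}, index=assignment.index
        )
        labels, flags = label_profiles(assignment, profiles)
        assert flags and "tie" in flags[0]

    def test_requires_two_clusters(self):
        assignment = _series([1, 1, 1])
        profiles = pd.DataFrame({"item": ["below"] * 3}, index=assignment.index)
        with pytest.raises(ValueError):
            label_profiles(assignment, profiles)


class TestAlignLabels:
    def test_swapped_labels_align_perfectly(self):
        a = _series([1, 1, 2, 2, 1])
        b = a.map({1: 2, 2: 1})
        aligned = align_labels(a, b)
        assert (aligned == a).all()

    def test_identity_kept_when_diagonal_maximal(self):
        a = _series([1] * 50 + [2] * 50)
        b = _series([1] * 40 + [2] * 10 + [1] * 5 + [2] * 45)
        aligned = align_labels(a, b)
        pd.testing.assert_series_equal(aligned, b)

    def test_differing_k_raises(self):
        a = _series([1, 2, 3])
        b = _series([1, 1, 2])
        with pytest.raises(ValueError):
            align_labels(a, b)

    def test_random_labels_agree_at_chance(self, rng):
        """Independent labelings agree at about the max-margin chance level."""
        n = 4000
        a = _series(rng.choice([1, 2], size=n, p=[0.6, 0.4]).tolist())
        b = _series(rng.choice([1, 2], size=n, p=[0.7, 0.3]).tolist())
        aligned = align_labels(a, b)
        agreement = float((aligned == a).mean())
        # best permutation of independent labels: p agreement ~ max over the
        # two pairings of sum_i p_i q_perm(i) = .6*.7+.4*.3 = 0.54
        assert agreement == pytest.approx(0.54, abs=0.04)


class TestCohenKappa:
    def test_identical_assignments(self):
        a = _series([1, 2, 1, 2, 2])
        report = cohen_kappa(a, a.copy())
        assert report.kappa == pytest.approx(1.0)
        assert report.percent_agreement == 100.0

    def test_chance_level_square_table(self):
        a = _series([1] * 50 + [2] * 50)
        b = _series(([1] * 25 + [2] * 25) * 2)
        report = cohen_kappa(a, b)
        assert report.kappa == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_100_subjects(self):
        # confusion [[45, 5], [10, 40]]
        a = _series([1] * 50 + [2] * 50)
        b = _series([1] * 45 + [2] * 5 + [1] * 10 + [2] * 40)
        report = cohen_kappa(a, b)
        p_o = 0.85
        p_e = 0.55 * 0.50 + 0.45 * 0.50
        assert report.p_observed == pytest.approx(p_o)
        assert report.p_chance == pytest.approx(p_e)
        assert report.kappa == pytest.approx((p_o - p_e) / (1 - p_e))

    def test_degenerate_margins_flagged(self):
        a = _series([1, 1, 1])
        report = cohen_kappa(a, a.copy())
        assert np.isnan(report.kappa)
        assert report.flags

    def test_sklearn_oracle(self, rng):
        for _ in range(20):
            n = 80
            a = _series(rng.integers(1, 4, size=n).tolist())
            b = _series(rng.integers(1, 4, size=n).tolist())
            assert cohen_kappa(a, b).kappa == pytest.approx(
                cohen_kappa_score(a.to_numpy(), b.to_numpy()), abs=1e-12
            )

    def test_relabeling_invariance(self, rng):
        for _ in range(20):
            a = _series(rng.integers(1, 4, size=60).tolist())
            b = _series(rng.integers(1, 4, size=60).tolist())
            relabel = {1: 7, 2: 9, 3: 8}
            k1 = cohen_kappa(a, b).kappa
            k2 = cohen_kappa(a.map(relabel), b.map(relabel)).kappa
            assert k1 == pytest.approx(k2, abs=1e-12)


class TestWithinStratumValidation:
    def test_strata_equal_to_blocks_give_kappa_one(self, two_block_profiles):
        strata = _series(
            ["g1"] * 20 + ["g2"] * 20, ids=list(two_block_profiles.index)
        )
        # strata aligned with the blocks are one-class: kappa undefined
        results = within_stratum_validation(
            two_block_profiles, strata, method="twostep", k_max=2, min_stratum_size=5
        )
        for res in results.values():
            assert res.selection is not None
            assert res.agreement is None
            assert any("one-class" in f or "constant" in f for f in res.flags)

    def test_mixed_strata_recover_whole_sample_partition(self, two_block_profiles):
        # strata orthogonal to the blocks: each stratum holds both profiles
        strata = _series(
            (["g1"] * 10 + ["g2"] * 10) * 2, ids=list(two_block_profiles.index)
        )
        results = within_stratum_validation(
            two_block_profiles, strata, method="twostep", k_max=2, min_stratum_size=5
        )
        for res in results.values():
            assert res.selection.chosen_k == 2
            assert res.agreement.kappa == pytest.approx(1.0)
            assert res.agreement.percent_agreement == 100.0

    def test_small_stratum_skipped(self, two_block_profiles):
        strata = _series(
            ["tiny"] * 3 + ["rest"] * 37, ids=list(two_block_profiles.index)
        )
        results = within_stratum_validation(
            two_block_profiles, strata, method="twostep", k_max=2, min_stratum_size=10
        )
        assert results["tiny"].selection is None
        assert "skipped" in results["tiny"].flags[0]

    def test_synthetic_diagnosis_strata_choose_two_clusters(self):
        """Under the stratified cohort preset most diagnoses reproduce the
        two-cluster solution within their own subsample."""
        sample = generate(cohort_preset(n_subjects=387, seed=11, with_strata=True))
        results = within_stratum_validation(
            sample.profiles,
            sample.stratum,
            method="lca",
            k_max=4,
            seed=3,
            min_stratum_size=20,
            n_starts=5,
        )
        chosen = [r.selection.chosen_k for r in results.values() if r.selection]
        assert len(chosen) == 4
        assert sum(k == 2 for k in chosen) >= 3


def test_bundled_tables_consistent():
    comp = load_cluster_composition()
    # every method block sums to the cohort size per item
    for method in ("twostep", "lca"):
        block = comp[comp.method == method]
        totals = block[
            ["low_below", "low_within", "low_above", "high_below", "high_within", "high_above"]
        ].sum(axis=1)
        assert (totals == 387).all()
    diag = load_diagnosis_distribution()
    assert diag.groupby("method")[["low", "high"]].sum().sum(axis=1).tolist() == [387, 387]
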