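"""Kruskal-Wallis screening: statistic, exact p, divergence flags, exclusions."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from paleodiet.plan import Scope, scope_cluster
from paleodiet.records import ChronoGroup, ClusterMode, ClusterSpec, Taxon
from paleodiet.screening import (
    ExclusionEntry,
    ExclusionList,
    ScreeningStatus,
    apply_exclusions,
    kruskal_wallis,
    screen_cohort,
)
from paleodiet.synthetic import FoodwebParams, generate_foodweb, plant_site_shift


def _rank_sum_h(groups):
    """Hand rank-sum formula 12/(N(N+1)) * sum(R_j^2/n_j) - 3(N+1), no ties."""
    pooled = np.concatenate(groups)
    order = pooled.argsort()
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(1, pooled.size + 1)
    n = pooled.size
    h, start = 0.0, 0
    for g in groups:
        h += ranks[start : start + len(g)].sum() ** 2 / len(g)
        start += len(g)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)


class TestKruskalWallis:
    def test_exchangeable_groups_are_not_heterogeneous(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert res.statistic < 1.0
        assert res.pvalue > 0.5

    def test_separated_groups_match_hand_formula_and_permutation(self):
        groups = [[1, 2, 3], [4, 5, 6]]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(_rank_sum_h(groups))
        # independent oracle: scipy H over all C(6,3)=20 assignments
        pooled = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        h_obs = stats.kruskal(*groups).statistic
        perm_h = []
        for combo in itertools.combinations(range(6), 3):
            mask = np.zeros(6, dtype=bool)
            mask[list(combo)] = True
            perm_h.append(stats.kruskal(pooled[mask], pooled[~mask]).statistic)
        p_exact = np.mean(np.asarray(perm_h) >= h_obs - 1e-9)
        assert len(perm_h) == 20
        assert res.pvalue == pytest.approx(p_exact, abs=1e-12)

    def test_all_tied_values_give_h_zero_p_one(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_asymptotic_matches_scipy(self):
        groups = [[1.2, 3.4, 2.2, 5.0], [2.0, 4.4, 6.1], [0.5, 1.1, 2.5, 3.3]]
        res = kruskal_wallis(groups, method="asymptotic")
        ref = stats.kruskal(*groups)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.pvalue == pytest.approx(ref.pvalue)

    def test_statistic_handles_ties_like_scipy(self):
        groups = [[1, 1, 2, 3], [2, 2, 3, 4]]
        res = kruskal_wallis(groups, method="asymptotic")
        ref = stats.kruskal(*groups)
        assert res.statistic == pytest.approx(ref.statistic)

    @pytest.mark.parametrize(
        "groups", [([],), ([1.0],), ([1.0], []), ([1.0], [2.0])]
    )
    def test_preconditions(self, groups):
        with pytest.raises(ValueError):
            kruskal_wallis(list(groups))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        a=st.lists(st.integers(-50, 50), min_size=2, max_size=6),
        b=st.lists(st.integers(-50, 50), min_size=2, max_size=6),
        scale=st.sampled_from([0.5, 1.0, 2.0, 7.5]),
        shift=st.floats(-5, 5),
    )
    def test_h_invariant_under_monotone_transform(self, a, b, scale, shift):
        """H depends on ranks only, so a strictly increasing map (affine or
        cubing) preserves it exactly."""
        res1 = kruskal_wallis([a, b], method="asymptotic")
        res2 = kruskal_wallis(
            [[scale * x + shift for x in a], [scale * x + shift for x in b]],
            method="asymptotic",
        )
        res3 = kruskal_wallis([[x**3 for x in a], [x**3 for x in b]], method="asymptotic")
        assert res1.statistic == pytest.approx(res2.statistic, abs=1e-9)
        assert res1.statistic == pytest.approx(res3.statistic, abs=1e-9)


class TestScreenCohort:
    def test_planted_shift_is_detected_and_site_flagged(self):
        params = plant_site_shift(
            FoodwebParams(seed=7), Taxon.BOVID, "SW-B", 4.0, "d15N"
        )
        records, truth = generate_foodweb(params)
        assert truth.planted_shifts[0].site == "SW-B"
        results = screen_cohort(
            records,
            Taxon.BOVID,
            ClusterSpec(mode=ClusterMode.GLOBAL),
            ChronoGroup.FAUNA_MOIS3,
        )
        res = results["d15N"]
        assert res.heterogeneous
        assert "SW-B" in res.flagged_sites
        # the unshifted isotope stays homogeneous
        assert not results["d13C"].heterogeneous

    def test_homogeneous_data_passes(self, foodweb):
        records, _ = foodweb
        results = screen_cohort(
            records,
            Taxon.REINDEER,
            scope_cluster(Scope.WHOLE_DATASET),
            ChronoGroup.FAUNA_MOIS3,
        )
        for res in results.values():
            assert res.status is ScreeningStatus.TESTED
            assert not res.heterogeneous

    def test_single_site_cohort_is_untestable(self, foodweb):
        records, _ = foodweb
        cluster = ClusterSpec(
            mode=ClusterMode.GEOGRAPHIC, included_labels={"central"}
        )
        results = screen_cohort(
            records, Taxon.HORSE, cluster, ChronoGroup.FAUNA_MOIS3
        )
        for res in results.values():
            assert res.status is ScreeningStatus.UNTESTABLE
            assert res.pvalue is None


class TestExclusions:
    def test_matching_records_removed(self, foodweb):
        records, _ = foodweb
        n_match = sum(
            1 for r in records if r.taxon is Taxon.BOVID and r.site == "SW-B"
        )
        assert n_match > 0
        excl = ExclusionList((ExclusionEntry(Taxon.BOVID, "SW-B", "test"),))
        kept = apply_exclusions(records, excl)
        assert len(kept) == len(records) - n_match
        assert all(not (r.taxon is Taxon.BOVID and r.site == "SW-B") for r in kept)

    def test_empty_list_is_identity(self, foodweb):
        records, _ = foodweb
        assert apply_exclusions(records, ExclusionList()) == records

    def test_unmatched_entry_warns_not_raises(self, foodweb, caplog):
        records, _ = foodweb
        excl = ExclusionList((ExclusionEntry(Taxon.BOVID, "Nowhere"),))
        with caplog.at_level("WARNING"):
            kept = apply_exclusions(records, excl)
        assert kept == records
        assert any("matched no records" in m for m in caplog.messages)

    def test_duplicate_entries_rejected(self):
        with pytest.raises(ValueError):
            ExclusionList(
                (
                    ExclusionEntry(Taxon.BOVID, "S"),
                    ExclusionEntry(Taxon.BOVID, "S", "again"),
                )
            )

    def test_config_round_trip(self):
        excl = ExclusionList.from_config(
            [{"taxon": "bovid", "site": "Gough's cave", "reason": "divergent"}]
        )
        assert ExclusionList.from_config(excl.to_config()) == excl
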