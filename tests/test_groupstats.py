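"""Rank-sum tests against enumeration, BH-FDR, Cohen's d, and the
demographic participant filter."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from isasync.groupstats import (
    age_comparison,
    bh_fdr,
    band_comparison,
    channelwise_comparison,
    cohens_d,
    participant_filter,
    rank_sum_one_tailed,
)
from isasync.synth import Participant


def enumerate_one_sided_p(x, y):
    """Exact P(rank sum of x >= observed) by enumerating all assignments."""
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1
    obs = ranks[: len(x)].sum()
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), len(x)):
        total += 1
        if ranks[list(combo)].sum() >= obs:
            count += 1
    return count / total


class TestRankSum:
    def test_complete_separation_exact(self):
        w, p = rank_sum_one_tailed([4, 5, 6], [1, 2, 3])
        assert p == pytest.approx(1 / 20)
        assert w == 15.0
        assert p == pytest.approx(enumerate_one_sided_p([4, 5, 6], [1, 2, 3]))

    def test_identical_samples_not_significant(self):
        _, p = rank_sum_one_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.5

    def test_wrong_direction_large_p(self):
        _, p = rank_sum_one_tailed([1, 2, 3], [4, 5, 6])
        assert p >= 19 / 20

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=7),
        st.lists(st.floats(-50, 50), min_size=2, max_size=7),
    )
    def test_matches_enumeration_oracle_untied(self, x, y):
        pooled = x + y
        if len(set(pooled)) < len(pooled):
            return  # enumeration oracle assumes no ties
        _, p = rank_sum_one_tailed(x, y)
        assert p == pytest.approx(enumerate_one_sided_p(x, y), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_one_tailed([], [1.0])


class TestBH:
    def test_flat_pvalues_unchanged(self):
        p = np.full(5, 0.03)
        assert np.allclose(bh_fdr(p), 0.03)

    def test_stepup_hand_example(self):
        adj = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.123]) == pytest.approx([0.123])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_monotone_and_capped(self, p):
        adj = bh_fdr(p)
        assert np.all(adj <= 1.0 + 1e-12)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestCohensD:
    def test_unit_shift_unit_pooled_sd(self):
        assert cohens_d([1, 2, 3], [2, 3, 4]) == pytest.approx(-1.0)

    def test_identical_groups_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_matches_direct_formula(self, rng):
        x = rng.standard_normal(20) + 0.4
        y = rng.standard_normal(20)
        sp = np.sqrt((19 * x.var(ddof=1) + 19 * y.var(ddof=1)) / 38)
        assert cohens_d(x, y) == pytest.approx((x.mean() - y.mean()) / sp, abs=1e-12)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestAgeComparison:
    def test_identical_lists_p_one(self):
        _, p = age_comparison([30.0, 40.0, 50.0], [30.0, 40.0, 50.0])
        assert p == pytest.approx(1.0)

    def test_separated_triples_exact(self):
        _, p = age_comparison([20, 21, 22], [60, 61, 62])
        assert p == pytest.approx(0.1)

    def test_singletons(self):
        _, p = age_comparison([25.0], [52.0])
        assert p == pytest.approx(1.0)


class TestParticipantFilter:
    def _p(self, sex, age, group="Novice"):
        return Participant(id=f"{sex}{age}", group=group, sex=sex, age=age)

    def test_rule_applied(self):
        roster = [self._p("F", 45), self._p("F", 30), self._p("M", 60)]
        kept = participant_filter(roster)
        assert [p.id for p in kept] == ["F30", "M60"]

    def test_all_males_unchanged(self):
        roster = [self._p("M", a) for a in (20, 50, 70)]
        assert participant_filter(roster) == roster

    def test_default_cohort_pooled_counts(self):
        from isasync import synth

        spec = synth.CohortSpec(n_channels=64, fs=8.0, bands=(0.05,))
        parts = synth.make_participants(spec)
        kept = participant_filter(parts)
        # counting oracle: retained = males + young females, per group
        for group in ("Expert", "Novice"):
            expect = sum(
                1 for p in parts
                if p.group == group and (p.sex == "M" or p.age <= 38)
            )
            got = sum(1 for p in kept if p.group == group)
            assert got == expect
            assert got * 64 == expect * spec.n_channels
        assert len(kept) < len(parts)


@pytest.fixture(scope="module")
def summaries():
    import pandas as pd

    rng = np.random.default_rng(3)
    rows = []
    for group, shift in (("Expert", 0.2), ("Novice", 0.0)):
        for pid in range(6):
            for ch in range(4):
                for band in (0.03, 0.07):
                    rows.append(
                        {
                            "participant": f"{group[0]}{pid}",
                            "group": group,
                            "channel": ch,
                            "band": band,
                            "psi": np.clip(rng.normal(0.4 + shift, 0.08), 0, 1),
                        }
                    )
    return pd.DataFrame(rows)


class TestTables:
    def test_band_comparison_structure(self, summaries):
        tbl = band_comparison(summaries)
        assert list(tbl["band"]) == [0.03, 0.07]
        assert (tbl["n_expert"] == 24).all()
        assert np.all(tbl["p_fdr"] >= tbl["p_raw"] - 1e-15)
        assert (tbl["p_fdr"] < 0.05).all()  # injected shift is large
        assert (tbl["cohens_d"] > 0).all()

    def test_channelwise_fraction(self, summaries):
        tbl, frac = channelwise_comparison(summaries, 0.03)
        assert len(tbl) == 4
        assert frac == tbl["significant"].mean()

    def test_single_channel_identical_groups(self):
        import pandas as pd

        rows = []
        for group in ("Expert", "Novice"):
            for pid in range(5):
                rows.append(
                    {"participant": f"{group[0]}{pid}", "group": group,
                     "channel": 0, "band": 0.05, "psi": 0.1 * pid}
                )
        tbl, frac = channelwise_comparison(pd.DataFrame(rows), 0.05)
        assert not tbl["significant"].any()
        assert frac == 0.0
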