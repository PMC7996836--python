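import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cemarker._errors import CohortError
from cemarker.cohort import (
    ITEM_NAMES,
    CohortSelection,
    QuestionnaireTable,
    balance_groups,
    drop_missing,
    filter_rows,
    item_ci,
    select_extremes,
)


def make_table(scores, ids=None, extra=None):
    scores = np.asarray(scores, dtype=float)
    if ids is None:
        ids = [f"p{i:02d}" for i in range(len(scores))]
    df = pd.DataFrame(scores, columns=list(ITEM_NAMES), index=pd.Index(ids, name="participant_id"))
    if extra:
        for k, v in extra.items():
            df[k] = v
    return QuestionnaireTable(df)


class TestItemCI:
    def test_hand_computed_five_point_example(self):
        # mean 3, sd 1.5811, t(0.975, 4) = 2.776 -> 3 +/- 1.963
        ci = item_ci([1, 2, 3, 4, 5])
        assert ci.lower == pytest.approx(1.0368, abs=1e-3)
        assert ci.upper == pytest.approx(4.9632, abs=1e-3)
        assert not ci.degenerate

    def test_constant_scores_degenerate_flagged(self):
        ci = item_ci([3, 3, 3, 3])
        assert ci == (3.0, 3.0, True)

    def test_two_scores_insufficient(self):
        with pytest.raises(CohortError, match=">= 3"):
            item_ci([2, 4])

    def test_level_widens_interval(self):
        narrow = item_ci([1, 2, 3, 4, 5], level=0.8)
        wide = item_ci([1, 2, 3, 4, 5], level=0.99)
        assert wide.upper - wide.lower > narrow.upper - narrow.lower


class TestDropMissing:
    def test_no_missing_is_identity(self):
        table = make_table(np.full((5, 4), 3.0))
        out, n = drop_missing(table)
        assert n == 0 and len(out) == 5

    def test_row_missing_one_item_dropped(self):
        scores = np.full((4, 4), 3.0)
        scores[2, 1] = np.nan
        out, n = drop_missing(make_table(scores))
        assert n == 1
        assert "p02" not in out.participant_ids

    def test_all_missing_fails(self):
        with pytest.raises(CohortError, match="every participant"):
            drop_missing(make_table(np.full((3, 4), np.nan)))


class TestSelectExtremes:
    def background(self, rng, n=40):
        return np.clip(np.round(rng.normal(3.0, 0.3, size=(n, 4))), 1, 5)

    def test_all_four_items_required(self, rng):
        bg = self.background(rng)
        almost = [5.0, 5.0, 5.0, 3.0]  # inside CI on the fourth item
        full = [5.0, 5.0, 5.0, 5.0]
        table = make_table(np.vstack([bg, almost, full]))
        sel = select_extremes(table)
        assert sel.high_ids == ("p41",)

    def test_disjoint_and_possibly_empty(self, rng):
        table = make_table(self.background(rng))
        sel = select_extremes(table)
        assert sel.high_ids == () and sel.low_ids == ()

    def test_low_side_selection(self, rng):
        bg = self.background(rng)
        table = make_table(np.vstack([bg, [1.0, 1.0, 1.0, 1.0]]))
        sel = select_extremes(table)
        assert sel.low_ids == ("p40",)

    def test_missing_values_rejected(self):
        scores = np.full((5, 4), 3.0)
        scores[0, 0] = np.nan
        with pytest.raises(CohortError, match="missing"):
            select_extremes(make_table(scores))

    @given(st.randoms(use_true_random=False))
    def test_invariant_to_row_order(self, pyrandom):
        rng = np.random.default_rng(0)
        bg = self.background(rng)
        rows = np.vstack([bg, [5, 5, 5, 5], [1, 1, 1, 1]])
        ids = [f"p{i:02d}" for i in range(len(rows))]
        order = list(range(len(rows)))
        pyrandom.shuffle(order)
        base = select_extremes(make_table(rows, ids))
        shuffled = select_extremes(
            make_table(rows[order], [ids[i] for i in order])
        )
        assert set(base.high_ids) == set(shuffled.high_ids)
        assert set(base.low_ids) == set(shuffled.low_ids)


def brute_force_best(table, ids, k):
    """Independent exhaustive minimizer of within-subset pairwise distance."""
    ids = sorted(ids, key=str)
    vec = table.scores.loc[ids].to_numpy(dtype=float)
    sd = vec.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (vec - vec.mean(axis=0)) / sd
    best, best_val = None, np.inf
    for combo in itertools.combinations(range(len(ids)), k):
        sub = z[list(combo)]
        total = 0.0
        for a in range(k):
            for b in range(a + 1, k):
                total += np.linalg.norm(sub[a] - sub[b])
        if total < best_val:
            best, best_val = combo, total
    return tuple(ids[i] for i in best)


class TestBalanceGroups:
    def selection_for(self, high_ids, low_ids):
        return CohortSelection(ci_bounds={}, high_ids=tuple(high_ids), low_ids=tuple(low_ids))

    def test_exhaustive_matches_independent_brute_force(self, rng):
        scores = np.clip(rng.normal(4.0, 0.5, size=(16, 4)), 1, 5)
        table = make_table(scores)
        high = table.participant_ids[:12]
        low = table.participant_ids[12:]
        sel = balance_groups(table, self.selection_for(high, low), k=4)
        assert sel.balanced_high_ids == brute_force_best(table, high, 4)

    def test_group_of_size_k_returned_unchanged(self):
        table = make_table(np.arange(32, dtype=float).reshape(8, 4))
        sel = balance_groups(
            table, self.selection_for(table.participant_ids[:4], table.participant_ids[4:]), k=4
        )
        assert set(sel.balanced_high_ids) == set(table.participant_ids[:4])

    def test_tight_cluster_beats_spread_candidates(self, rng):
        cluster = 3.0 + 0.01 * rng.standard_normal((10, 4))
        other = np.clip(3.0 + 2.0 * rng.standard_normal((8, 4)), 1, 5)
        table = make_table(np.vstack([cluster, other, np.ones((10, 4))]))
        high = table.participant_ids[:18]
        low = table.participant_ids[18:]
        sel = balance_groups(table, self.selection_for(high, low), k=10)
        assert set(sel.balanced_high_ids) == set(table.participant_ids[:10])

    def test_greedy_path_recovers_obvious_cluster(self, rng):
        # C(25, 10) > 10^6 forces the greedy search
        cluster = 2.0 + 0.01 * rng.standard_normal((10, 4))
        spread = np.clip(3.0 + 1.5 * rng.standard_normal((15, 4)), 1, 5)
        table = make_table(np.vstack([cluster, spread, np.full((10, 4), 5.0)]))
        high = table.participant_ids[:25]
        low = table.participant_ids[25:]
        sel = balance_groups(table, self.selection_for(high, low), k=10)
        assert set(sel.balanced_high_ids) == set(table.participant_ids[:10])

    def test_smaller_group_never_reduced(self, rng):
        table = make_table(rng.normal(3, 0.5, size=(10, 4)))
        sel = balance_groups(
            table, self.selection_for(table.participant_ids[:7], table.participant_ids[7:])
        )
        assert set(sel.balanced_low_ids) == set(table.participant_ids[7:])
        assert len(sel.balanced_high_ids) == 3

    def test_k_above_group_size_fails(self, rng):
        table = make_table(rng.normal(3, 0.5, size=(6, 4)))
        with pytest.raises(CohortError, match="larger group has only"):
            balance_groups(
                table, self.selection_for(table.participant_ids[:4], table.participant_ids[4:]), k=5
            )

    def test_balanced_sets_are_subsets(self, rng):
        table = make_table(rng.normal(3, 0.5, size=(12, 4)))
        high = table.participant_ids[:8]
        low = table.participant_ids[8:]
        sel = balance_groups(table, self.selection_for(high, low), k=4)
        assert set(sel.balanced_high_ids) <= set(high)
        assert set(sel.balanced_low_ids) <= set(low)

    def test_invariant_to_candidate_order(self, rng):
        scores = rng.normal(3, 0.7, size=(14, 4))
        table = make_table(scores)
        high = table.participant_ids[:10]
        low = table.participant_ids[10:]
        sel1 = balance_groups(table, self.selection_for(high, low), k=4)
        sel2 = balance_groups(table, self.selection_for(high[::-1], low), k=4)
        assert sel1.balanced_high_ids == sel2.balanced_high_ids

    def test_objective_variants_run(self, rng):
        table = make_table(rng.normal(3, 0.7, size=(10, 4)))
        high = table.participant_ids[:7]
        low = table.participant_ids[7:]
        for objective in ("sum", "max", "centroid"):
            sel = balance_groups(table, self.selection_for(high, low), k=3, objective=objective)
            assert len(sel.balanced_high_ids) == 3


def test_filter_rows_with_metadata():
    table = make_table(np.full((4, 4), 3.0), extra={"age_group": ["young", "old", "young", "old"]})
    young = filter_rows(table, lambda row: row["age_group"] == "young")
    assert len(young) == 2
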