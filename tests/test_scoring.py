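"""Quantitative scoring: formulas, conservation, ODF identities and bounds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmrsq.item_bank import DEFENSE_IDS, LEVEL_DEFENSES
from dmrsq.qsort import DEFAULT_DISTRIBUTION, QSort
from dmrsq.scoring import (
    InvalidSortError,
    compute_odf,
    full_profile,
    odf_from_items,
    score_categories,
    score_defenses,
    score_levels,
)
from dmrsq.simulate import _fill_by_salience, random_sort

ODF_MAX = 1513 / 234  # greedy top-down assignment of levels to ranks
ODF_MIN = 553 / 234   # its mirror image


def brute_force_defense_scores(sort, bank):
    """Independent oracle: accumulate rank mass item by item via
    defense_for_item, then normalize by the formula constants."""
    sums = {d: 0 for d in DEFENSE_IDS}
    for item_id in range(1, 151):
        sums[bank.defense_for_item(item_id).defense_id] += \
            sort.assignment[item_id]
    return {d: (s - 5) * 100.0 / 234.0 for d, s in sums.items()}


def extremal_sort(bank, maximize):
    """Greedy ODF extremizer: most (least) adaptive items into the top
    ranks, optimal by the rearrangement inequality."""
    sign = -1 if maximize else 1
    order = sorted(range(1, 151),
                   key=lambda i: (sign * bank.level_of_item(i), i))
    return _fill_by_salience(order, DEFAULT_DISTRIBUTION)


def test_defense_score_extremes(bank):
    """All five items at rank 1 -> 0; all five at rank 7 -> (35-5)*100/234."""
    low = extremal_sort(bank, maximize=False)
    dl = score_defenses(low, bank)
    # in the minimizing sort every high-adaptive item sits at rank 1
    for dd in LEVEL_DEFENSES["L7"]:
        assert dl[dd] == 0.0
    # a sort filing D30's five items first puts them all at rank 7
    d30 = set(bank.items_for_defense("D30"))
    order = sorted(d30) + [i for i in range(1, 151) if i not in d30]
    sort = _fill_by_salience(order, DEFAULT_DISTRIBUTION)
    d = score_defenses(sort, bank)
    assert d["D30"] == pytest.approx((35 - 5) * 100 / 234, abs=1e-12)


@settings(max_examples=25, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_scores_match_brute_force_oracle(seed):
    from dmrsq import load_item_bank

    bank = load_item_bank()
    sort = random_sort(seed)
    d = score_defenses(sort, bank)
    oracle = brute_force_defense_scores(sort, bank)
    for dd in DEFENSE_IDS:
        assert d[dd] == pytest.approx(oracle[dd], abs=1e-12)


@settings(max_examples=25, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_conservation_identities(seed):
    """Defense, level and category scores each sum to 100; the sublevel
    and subcategory splits are exact partitions."""
    from dmrsq import load_item_bank

    bank = load_item_bank()
    d = score_defenses(random_sort(seed), bank)
    lvl = score_levels(d)
    cat = score_categories(d)
    assert sum(d[x] for x in DEFENSE_IDS) == pytest.approx(100, abs=1e-9)
    assert sum(lvl[f"L{i}"] for i in range(1, 8)) == \
        pytest.approx(100, abs=1e-9)
    assert lvl["L5a"] + lvl["L5b"] == pytest.approx(lvl["L5"], abs=1e-9)
    assert cat["C1"] + cat["C2"] + cat["C3"] == pytest.approx(100, abs=1e-9)
    assert cat["C1a"] + cat["C1b"] == pytest.approx(cat["C1"], abs=1e-9)
    assert cat["C3"] == pytest.approx(lvl["L7"], abs=1e-9)
    assert cat["C2"] == pytest.approx(lvl["L5"] + lvl["L6"], abs=1e-9)


def test_odf_item_level_identity(bank):
    for seed in range(20):
        sort = random_sort(seed)
        profile = full_profile(sort, bank)
        assert profile.odf.value == \
            pytest.approx(odf_from_items(sort, bank), abs=1e-9)


def test_odf_extremes_attained(bank):
    hi = extremal_sort(bank, maximize=True)
    lo = extremal_sort(bank, maximize=False)
    assert full_profile(hi, bank).odf.value == pytest.approx(ODF_MAX, abs=1e-12)
    assert full_profile(lo, bank).odf.value == pytest.approx(ODF_MIN, abs=1e-12)


def test_random_sorts_respect_odf_bounds(bank):
    for seed in range(200):
        odf = odf_from_items(random_sort(seed), bank)
        assert ODF_MIN - 1e-12 <= odf <= ODF_MAX + 1e-12


def test_odf_monotone_under_adaptive_swap(bank):
    """Swapping the ranks of a low-level item (high rank) and a high-level
    item (low rank) strictly increases ODF."""
    sort = random_sort(5)
    profile0 = full_profile(sort, bank)
    l1_items = [i for i in sort.assignment if bank.level_of_item(i) == 1]
    l7_items = [i for i in sort.assignment if bank.level_of_item(i) == 7]
    lo = max(l1_items, key=lambda i: sort.assignment[i])
    hi = min(l7_items, key=lambda i: sort.assignment[i])
    assert sort.assignment[lo] > sort.assignment[hi]
    delta = sort.assignment[lo] - sort.assignment[hi]
    sort.assignment[lo], sort.assignment[hi] = \
        sort.assignment[hi], sort.assignment[lo]
    profile1 = full_profile(sort, bank)
    assert profile1.odf.value - profile0.odf.value == \
        pytest.approx(6 * delta / 234, abs=1e-12)


def test_invalid_sort_refused_with_report(bank):
    sort = QSort(assignment={i: 1 for i in range(1, 151)})
    with pytest.raises(InvalidSortError) as exc:
        score_defenses(sort, bank)
    assert "rank 1: 150/60" in exc.value.report.violations
    with pytest.raises(InvalidSortError):
        full_profile(QSort(assignment={}), bank)


def test_odf_below_4_flag(bank):
    lo = extremal_sort(bank, maximize=False)
    hi = extremal_sort(bank, maximize=True)
    assert full_profile(lo, bank).odf.below_4
    assert not full_profile(hi, bank).odf.below_4


def test_non_default_distribution_warns(bank):
    from dmrsq.qsort import ForcedDistribution
    from dmrsq.simulate import random_sort as rs

    dist = ForcedDistribution({1: 100, 2: 30, 3: 20})
    rng = np.random.default_rng(0)
    order = [int(x) for x in rng.permutation(np.arange(1, 151))]
    sort = _fill_by_salience(order, dist)
    with pytest.warns(UserWarning, match="non-default"):
        d = score_defenses(sort, bank, dist)
    assert sum(d[x] for x in DEFENSE_IDS) == pytest.approx(100, abs=1e-9)
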