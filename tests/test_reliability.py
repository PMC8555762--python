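"""Agreement statistics: ICC mean-square decomposition against independent
oracles, ICC invariances, Q-correlation, and the simulated panel design."""

import numpy as np
import pandas as pd
import pytest

from dmrsq.reliability import (
    AgreementResult,
    ScoreMatrix,
    icc,
    panel_score_matrix,
    q_correlation,
    reliability_experiment,
)
from dmrsq.simulate import (
    RaterModel,
    random_profiles,
    random_sort,
    rater_panel,
)
from dmrsq.qsort import DEFAULT_DISTRIBUTION


def brute_force_mean_squares(x):
    """Naive double-loop sums of squares for the two-way decomposition."""
    n, k = x.shape
    gm = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((r - gm) ** 2 for r in row)
    ssc = n * sum((c - gm) ** 2 for c in col)
    sse = sum((x[i, j] - row[i] - col[j] + gm) ** 2
              for i in range(n) for j in range(k))
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def brute_force_icc(x, form):
    n, k = x.shape
    msr, msc, mse = brute_force_mean_squares(x)
    if form == "ICC(2,1)":
        return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return (msr - mse) / (msr + (msc - mse) / n)


@pytest.mark.parametrize("form", ["ICC(2,1)", "ICC(2,k)"])
def test_icc_matches_brute_force_anova(form):
    rng = np.random.default_rng(1234)
    for _ in range(20):
        x = rng.normal(size=(5, 3)) + 2 * rng.normal(size=(5, 1))
        res = icc(ScoreMatrix(values=x), form=form)
        assert res.estimate == pytest.approx(brute_force_icc(x, form),
                                             abs=1e-9)


@pytest.mark.parametrize("form,pg_type", [("ICC(2,1)", "ICC(A,1)"),
                                          ("ICC(2,k)", "ICC(A,k)")])
def test_icc_matches_pingouin(form, pg_type):
    """Cross-check against an independent implementation (two-way random
    effects, absolute agreement)."""
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(7)
    x = rng.normal(size=(6, 4)) + 1.5 * rng.normal(size=(6, 1))
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(6), 4),
        "rater": np.tile(np.arange(4), 6),
        "score": x.ravel(),
    })
    ref = pg.intraclass_corr(df, "subject", "rater", "score")
    expected = float(ref.loc[ref.Type == pg_type, "ICC"].iloc[0])
    assert icc(ScoreMatrix(values=x), form=form).estimate == \
        pytest.approx(expected, abs=1e-9)


def test_identical_columns_give_icc_one():
    col = np.array([1.0, 2.0, 5.0, 9.0])
    x = np.column_stack([col, col, col])
    res = icc(ScoreMatrix(values=x), form="ICC(2,1)")
    assert res.estimate == pytest.approx(1.0, abs=1e-12)
    assert not res.flags


def test_degenerate_matrix_flagged():
    x = np.full((4, 3), 2.5)
    res = icc(ScoreMatrix(values=x))
    assert res.estimate == 1.0
    assert "degenerate" in res.flags


def test_negative_icc_reported_with_flag():
    # strong rater-by-subject interaction, no subject effect
    x = np.array([[0.0, 1.0], [1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
    res = icc(ScoreMatrix(values=x))
    assert res.estimate < 0
    assert "negative" in res.flags


def test_icc_shift_scale_invariance():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(6, 3)) + rng.normal(size=(6, 1))
    base = icc(ScoreMatrix(values=x)).estimate
    assert icc(ScoreMatrix(values=x + 100)).estimate == \
        pytest.approx(base, abs=1e-9)
    assert icc(ScoreMatrix(values=x * 3.7)).estimate == \
        pytest.approx(base, abs=1e-9)


def test_icc2k_at_least_icc21():
    rng = np.random.default_rng(3)
    for _ in range(10):
        x = rng.normal(size=(6, 3)) + rng.normal(size=(6, 1))
        a = icc(ScoreMatrix(values=x), "ICC(2,1)").estimate
        b = icc(ScoreMatrix(values=x), "ICC(2,k)").estimate
        if 0 <= a <= 1 and 0 <= b <= 1:
            assert b >= a - 1e-12


def test_icc_approaches_variance_ratio():
    """Subject effect + independent noise: for a large panel ICC(2,1)
    approaches var_subject / (var_subject + var_noise)."""
    rng = np.random.default_rng(11)
    n, k = 600, 3
    vs, ve = 4.0, 1.0
    x = (np.sqrt(vs) * rng.normal(size=(n, 1))
         + np.sqrt(ve) * rng.normal(size=(n, k)))
    res = icc(ScoreMatrix(values=x))
    assert res.estimate == pytest.approx(vs / (vs + ve), abs=0.05)


def test_icc_input_requirements():
    with pytest.raises(ValueError):
        icc(ScoreMatrix(values=np.zeros((1, 3))))
    with pytest.raises(ValueError):
        icc(ScoreMatrix(values=np.zeros((3, 1))))
    with pytest.raises(ValueError):
        ScoreMatrix(values=np.array([[1.0, np.nan], [0.0, 1.0]]))
    with pytest.raises(ValueError):
        icc(ScoreMatrix(values=np.zeros((3, 3))), form="ICC(3,1)")


def test_q_correlation_identity_and_reversal(bank):
    a = random_sort(1)
    assert q_correlation(a, a).estimate == pytest.approx(1.0)
    # capacity-respecting reversal: file the same items in opposite order
    from dmrsq.qsort import to_rank_vector
    from dmrsq.simulate import _fill_by_salience

    order = sorted(a.assignment, key=lambda i: (a.assignment[i], i))
    rev = _fill_by_salience(order, DEFAULT_DISTRIBUTION)
    res = q_correlation(a, rev)
    assert res.estimate < -0.5
    # independent random sorts: near-zero correlation on average
    ests = [q_correlation(random_sort(2 * s), random_sort(2 * s + 1)).estimate
            for s in range(20)]
    assert abs(np.mean(ests)) < 0.1


def test_q_correlation_rank_method(bank):
    a, b = random_sort(4), random_sort(9)
    res = q_correlation(a, b, method="rank")
    assert -1 <= res.estimate <= 1
    with pytest.raises(ValueError):
        q_correlation(a, b, method="kendall")


def test_experiment_noise_zero_gives_icc_one(bank):
    profiles = random_profiles(4, seed=8)
    raters = [RaterModel(noise_sd=0.0, seed=s) for s in (1, 2, 3)]
    table = reliability_experiment(
        profiles, raters, bank,
        scales=("ODF", "L7", "C1", "D2", "L5a", "C1a"),
    )
    assert np.allclose(table["estimate"], 1.0, atol=1e-12)


def test_experiment_icc_between_zero_and_one_with_noise(bank):
    profiles = random_profiles(6, seed=21)
    raters = [RaterModel(noise_sd=0.02, seed=s) for s in (4, 5, 6)]
    table = reliability_experiment(profiles, raters, bank, scales=("ODF",))
    est = float(table["estimate"].iloc[0])
    assert 0.0 < est < 1.0


def test_score_matrix_csv_round_trip(tmp_path, bank):
    profiles = random_profiles(3, seed=2)
    raters = [RaterModel(noise_sd=0.05, seed=s) for s in (1, 2)]
    panel = rater_panel(profiles, raters, bank=bank)
    m = panel_score_matrix(panel, "ODF", bank)
    path = tmp_path / "odf.csv"
    m.to_csv(path)
    back = ScoreMatrix.from_csv(path, scale="ODF")
    assert np.allclose(back.values, m.values)
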