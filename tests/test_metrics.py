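"""Transfer statistics against brute-force and closed-form oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shapebench.errors import UndefinedTransferIndexError
from shapebench.metrics import (
    build_report,
    format_report,
    hauc,
    read_report,
    tfi,
    transfer_regression,
    write_report,
)
from shapebench.protocol import RunLog

# -- independent oracles ----------------------------------------------------


def hauc_oracle(curve, k):
    total = 0.0
    for e in range(k):
        total += curve[e] - 50.0
    return total


def ols_oracle(x, y):
    """Closed-form simple OLS slope and Pearson r."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    sxy = np.sum((x - xm) * (y - ym))
    syy = np.sum((y - ym) ** 2)
    slope = sxy / sxx
    r = sxy / math.sqrt(sxx * syy) if syy > 0 else 0.0
    return slope, r


curves = st.lists(
    st.floats(min_value=0.0, max_value=100.0, allow_nan=False), min_size=1, max_size=40
)


# -- hauc -------------------------------------------------------------------


def test_hauc_hand_computed_values():
    assert hauc([50.0] * 7, 7) == 0.0
    assert hauc([60.0, 70.0, 80.0], 3) == pytest.approx(60.0)
    assert hauc([40.0] * 5, 5) == pytest.approx(-50.0)


def test_hauc_rejects_out_of_range_k():
    with pytest.raises(ValueError, match="epoch range"):
        hauc([60.0, 70.0], 3)
    with pytest.raises(ValueError, match="epoch range"):
        hauc([60.0, 70.0], 0)


def test_hauc_trapezoid_rule():
    # piecewise-linear integral of (acc - 50) over [1, 3]
    assert hauc([60.0, 70.0, 80.0], 3, rule="trapezoid") == pytest.approx(40.0)
    assert hauc([60.0, 70.0, 80.0], 1, rule="trapezoid") == pytest.approx(10.0)


@settings(deadline=None, max_examples=200)
@given(curves, st.data())
def test_hauc_matches_brute_force(curve, data):
    k = data.draw(st.integers(min_value=1, max_value=len(curve)))
    expected = hauc_oracle(curve, k)
    got = hauc(curve, k)
    assert got == pytest.approx(expected, rel=1e-10, abs=1e-10)


def test_hauc_brute_force_on_1000_random_curves():
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        n = int(rng.integers(1, 30))
        curve = rng.uniform(0, 100, n)
        k = int(rng.integers(1, n + 1))
        assert hauc(curve, k) == pytest.approx(
            hauc_oracle(curve, k), rel=1e-10, abs=1e-10
        )


# -- transfer index ---------------------------------------------------------


def test_tfi_perfect_transfer_is_exactly_100():
    assert tfi([100.0] * 20, [100.0] * 20, 20) == 100.0


def test_tfi_chance_transfer_is_zero():
    assert tfi([80.0, 90.0, 95.0], [50.0, 50.0, 50.0], 3) == 0.0


def test_tfi_single_epoch_hand_value():
    assert tfi([80.0], [65.0], 1) == pytest.approx(50.0)


def test_tfi_k1_equals_single_epoch_ratio():
    rng = np.random.default_rng(5)
    for _ in range(50):
        le = rng.uniform(55, 100, 10)
        tr = rng.uniform(0, 100, 10)
        expected = (tr[0] - 50) / (le[0] - 50) * 100
        assert tfi(le, tr, 1) == pytest.approx(expected, rel=1e-12)


def test_tfi_undefined_when_learning_at_or_below_chance():
    with pytest.raises(UndefinedTransferIndexError):
        tfi([50.0] * 5, [80.0] * 5, 5)
    with pytest.raises(UndefinedTransferIndexError):
        tfi([40.0] * 5, [80.0] * 5, 5)


@settings(deadline=None, max_examples=150)
@given(
    st.lists(st.floats(min_value=50.5, max_value=100.0), min_size=1, max_size=30),
    st.data(),
)
def test_tfi_identity_and_bounds(learning, data):
    k = data.draw(st.integers(min_value=1, max_value=len(learning)))
    assert tfi(learning, learning, k) == pytest.approx(100.0, rel=1e-12)
    # transfer pinned between chance and the learning curve => TFI in [0, 100]
    frac = data.draw(st.floats(min_value=0.0, max_value=1.0))
    transfer = [50.0 + frac * (v - 50.0) for v in learning]
    val = tfi(learning, transfer, k)
    assert -1e-9 <= val <= 100.0 + 1e-9


def test_tfi_monotone_in_transfer_accuracy():
    rng = np.random.default_rng(17)
    le = rng.uniform(60, 100, 20)
    tr = rng.uniform(40, 90, 20)
    base = tfi(le, tr, 20)
    for e in range(20):
        bumped = tr.copy()
        bumped[e] = min(100.0, bumped[e] + 5.0)
        assert tfi(le, bumped, 20) > base


# -- regression -------------------------------------------------------------


def test_regression_identity_curves():
    le = [55.0, 60.0, 70.0, 85.0, 95.0]
    res = transfer_regression(le, le)
    assert not res.degenerate
    assert res.slope == pytest.approx(1.0, abs=1e-12)
    assert res.r == pytest.approx(1.0, abs=1e-12)


def test_regression_constant_learning_is_degenerate():
    res = transfer_regression([100.0] * 10, list(np.linspace(50, 90, 10)))
    assert res.degenerate
    assert math.isnan(res.slope) and math.isnan(res.r)


def test_regression_recovers_known_slope():
    rng = np.random.default_rng(3)
    le = rng.uniform(55, 95, 20)
    tr = 0.5 * le + 10.0
    res = transfer_regression(le, tr)
    assert res.slope == pytest.approx(0.5, rel=1e-9)
    assert res.r == pytest.approx(1.0, abs=1e-9)


def test_regression_signed_and_absolute_r():
    le = np.linspace(55, 95, 10)
    tr = 100.0 - 0.5 * le
    assert transfer_regression(le, tr).r == pytest.approx(-1.0, abs=1e-9)
    assert transfer_regression(le, tr, absolute_r=True).r == pytest.approx(1.0, abs=1e-9)


def test_regression_matches_closed_form_on_random_curves():
    rng = np.random.default_rng(99)
    for _ in range(1000):
        n = int(rng.integers(3, 30))
        le = rng.uniform(0, 100, n)
        if np.var(le) < 1e-6:
            continue
        tr = rng.uniform(0, 100, n)
        res = transfer_regression(le, tr)
        slope, r = ols_oracle(le, tr)
        assert res.slope == pytest.approx(slope, rel=1e-10, abs=1e-10)
        assert res.r == pytest.approx(r, rel=1e-10, abs=1e-10)


def test_regression_needs_three_epochs():
    with pytest.raises(ValueError, match="3"):
        transfer_regression([60.0, 70.0], [55.0, 60.0])


# -- report building --------------------------------------------------------


def _mklog(exp, learning, transfer, model="reference"):
    return RunLog(exp, model, 0, learning=learning, transfer=transfer)


def test_report_from_oracle_logs(tmp_path):
    perfect = _mklog("C.1", [100.0] * 20, [100.0] * 20)
    chance = _mklog("C.2", list(np.linspace(60, 99, 20)), [50.0] * 20)
    rep = build_report([perfect, chance])
    assert len(rep) == 2
    row_p = rep[rep["experiment"] == "C.1"].iloc[0]
    assert row_p["tfi_first"] == pytest.approx(100.0)
    assert row_p["tfi_last"] == pytest.approx(100.0)
    assert bool(row_p["degenerate"])  # learning constant at 100
    row_c = rep[rep["experiment"] == "C.2"].iloc[0]
    assert row_c["tfi_last"] == pytest.approx(0.0)
    assert not bool(row_c["degenerate"])

    p = tmp_path / "report.csv"
    write_report(rep, p)
    back = read_report(p)
    assert back["tfi_last"].tolist() == pytest.approx(rep["tfi_last"].tolist())

    text = format_report(rep)
    assert "N/A" in text  # degenerate regression rendered as not applicable


def test_report_contains_six_statistics_per_run():
    log = _mklog("E", list(np.linspace(55, 95, 20)), list(np.linspace(52, 80, 20)))
    rep = build_report([log])
    row = rep.iloc[0]
    for col in ("learning_acc_first", "learning_acc_last", "tfi_first",
                "tfi_last", "slope", "r"):
        assert np.isfinite(row[col])


def test_report_skips_invalid_logs():
    bad = RunLog("F", "reference", 0, [], [], valid=False)
    assert build_report([bad]).empty
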