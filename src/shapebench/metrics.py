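"""Transfer-of-learning statistics: HAUC, transfer index, and regression.

The half-area under an accuracy curve accumulates (accuracy − 50) over
training epochs — "half" because only the area above the 50% chance level
of a balanced binary task counts, which also normalizes the statistic so a
never-better-than-chance curve scores zero (and a below-chance curve
scores negative).  The transfer index is the ratio of the transfer curve's
half-area to the learning curve's, in percent:

    TFI(k) = 100 · HAUC_transfer(k) / HAUC_learn(k)

A perfect transfer gives 100%.  The companion regression fits transfer
accuracy against learning accuracy across epochs (ordinary least squares)
and reports the slope and the Pearson correlation R; when the learning
accuracy is constant — e.g., pinned at 100% from epoch 1 — the regression
is degenerate and reported as not applicable rather than fabricated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedTransferIndexError
from .protocol import RunLog

__all__ = [
    "hauc",
    "tfi",
    "transfer_regression",
    "RegressionResult",
    "build_report",
    "write_report",
    "read_report",
    "format_report",
]

HaucRule = Literal["sum", "trapezoid"]

#: predictor variance (percent²) below which the regression is degenerate
DEGENERATE_VARIANCE = 1e-9


def _check_curve(curve: Sequence[float]) -> np.ndarray:
    c = np.asarray(curve, dtype=float)
    if c.ndim != 1 or len(c) == 0:
        raise ValueError("curve must be a nonempty 1-D sequence")
    if np.any(c < 0) or np.any(c > 100):
        raise ValueError("accuracies must lie in [0, 100]")
    return c


def hauc(curve: Sequence[float], k: int, rule: HaucRule = "sum") -> float:
    """Half-area under the accuracy curve over epochs 1..k.

    The default rule is the discrete sum Σ (accuracy(e) − 50), which
    reduces to the single-epoch excess at k = 1; ``trapezoid`` integrates
    the same excess piecewise-linearly over [1, k] instead.  May be
    negative for below-chance curves.
    """
    c = _check_curve(curve)
    if not 1 <= k <= len(c):
        raise ValueError(f"k={k} outside the curve's epoch range 1..{len(c)}")
    excess = c[:k] - 50.0
    if rule == "sum":
        return float(np.sum(excess))
    if rule == "trapezoid":
        return float(np.trapezoid(excess)) if k > 1 else float(excess[0])
    raise ValueError(f"unknown HAUC rule: {rule!r}")


def tfi(
    learning: Sequence[float],
    transfer: Sequence[float],
    k: int,
    rule: HaucRule = "sum",
) -> float:
    """Transfer index at epoch k, percent.

    Raises :class:`UndefinedTransferIndexError` when the learning HAUC is
    not positive — the index is undefined for a classifier that never
    rose above chance on its own task.
    """
    le = _check_curve(learning)
    tr = _check_curve(transfer)
    if len(le) != len(tr):
        raise ValueError("learning and transfer curves must share epoch range")
    denom = hauc(le, k, rule)
    if denom <= 0:
        raise UndefinedTransferIndexError(
            f"learning HAUC at k={k} is {denom:.6g}; transfer index undefined"
        )
    return 100.0 * hauc(tr, k, rule) / denom


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    r: float
    degenerate: bool

    def as_tuple(self) -> tuple[float, float, bool]:
        return (self.slope, self.r, self.degenerate)


def transfer_regression(
    learning: Sequence[float],
    transfer: Sequence[float],
    *,
    absolute_r: bool = False,
) -> RegressionResult:
    """OLS of transfer accuracy on learning accuracy across epochs.

    R is the signed Pearson correlation by default (``absolute_r`` flips
    to |r|).  When the predictor variance is below tolerance (learning
    accuracy constant across epochs) the fit is degenerate: the result is
    flagged and slope/R are NaN.
    """
    le = _check_curve(learning)
    tr = _check_curve(transfer)
    if len(le) != len(tr):
        raise ValueError("curves must share epoch range")
    if len(le) < 3:
        raise ValueError("regression needs at least 3 epochs")
    if float(np.var(le)) < DEGENERATE_VARIANCE:
        return RegressionResult(math.nan, math.nan, True)
    fit = stats.linregress(le, tr)
    r = abs(fit.rvalue) if absolute_r else float(fit.rvalue)
    return RegressionResult(float(fit.slope), r, False)


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = [
    "model",
    "experiment",
    "learning_acc_first",
    "learning_acc_last",
    "tfi_first",
    "tfi_last",
    "slope",
    "r",
    "degenerate",
]


def build_report(
    logs: Iterable[RunLog],
    rule: HaucRule = "sum",
    *,
    absolute_r: bool = False,
) -> pd.DataFrame:
    """Summary table: one row per run with the six headline statistics.

    Per run: learning accuracy at the first and last epoch, transfer index
    at the first and last epoch, regression slope and R (NaN with the
    ``degenerate`` flag set when not applicable).  Undefined transfer
    indices are reported as NaN rather than a fabricated number.
    """
    rows = []
    for log in logs:
        if not log.valid or log.epochs == 0:
            continue
        k = log.epochs

        def _tfi(at: int) -> float:
            try:
                return tfi(log.learning, log.transfer, at, rule)
            except UndefinedTransferIndexError:
                return math.nan

        reg = transfer_regression(log.learning, log.transfer, absolute_r=absolute_r)
        rows.append(
            {
                "model": log.model_name,
                "experiment": log.experiment_id,
                "learning_acc_first": log.learning[0],
                "learning_acc_last": log.learning[-1],
                "tfi_first": _tfi(1),
                "tfi_last": _tfi(k),
                "slope": reg.slope,
                "r": reg.r,
                "degenerate": reg.degenerate,
            }
        )
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def format_report(report: pd.DataFrame) -> str:
    """Human-readable table; degenerate regressions print as N/A."""
    show = report.copy()
    for col in ("slope", "r"):
        show[col] = [
            "N/A" if d else f"{v:.3f}"
            for v, d in zip(report[col], report["degenerate"])
        ]
    for col in ("learning_acc_first", "learning_acc_last", "tfi_first", "tfi_last"):
        show[col] = [
            "N/A" if (isinstance(v, float) and math.isnan(v)) else f"{v:.2f}"
            for v in report[col]
        ]
    return show.drop(columns=["degenerate"]).to_string(index=False)
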