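"""Chemometric model evaluation: R², RMSE, RPD, splits, reference summaries.

Conventions: R² = 1 - SSres/SStot; RMSE = sqrt(mean squared error); RPD =
SD(reference)/RMSE with the sample (n-1) standard deviation, computed on the
same set as the RMSE.  An RPD above 2.5 conventionally indicates a usable
quantitative calibration.  The calibration/prediction split is a random
fruit-level partition at 5:1.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "EvaluationReport",
    "SplitPlan",
    "r_squared",
    "rmse",
    "rpd",
    "split_samples",
    "summarize_reference",
    "evaluate_predictions",
]


@dataclass
class EvaluationReport:
    r2: float
    rmse_brix: float
    rmse_scaled: float
    rpd: float
    n: int
    sd_reference: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SplitPlan:
    calibration_ids: list[str]
    prediction_ids: list[str]
    ratio: tuple[int, int]
    seed: int


def _check_pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    return y, yhat


def r_squared(y, yhat) -> float:
    """Coefficient of determination 1 - SSres/SStot."""
    y, yhat = _check_pair(y, yhat)
    if y.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("reference values are constant; R² undefined")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def rmse(y, yhat) -> float:
    """Root mean square error, in the units of ``y``."""
    y, yhat = _check_pair(y, yhat)
    if y.size < 1:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def rpd(y, rmse_value: float) -> float:
    """Residual prediction deviation SD(y)/RMSE (sample SD, n-1 denominator)."""
    if rmse_value <= 0:
        raise ZeroDivisionError("RPD undefined: RMSE must be positive")
    y = np.asarray(y, dtype=np.float64)
    return float(np.std(y, ddof=1)) / rmse_value


def split_samples(ids: list[str], ratio: tuple[int, int] = (5, 1), seed: int = 0) -> SplitPlan:
    """Random disjoint calibration/prediction partition at the given ratio.

    The calibration count is round(n * a/(a+b)); 570 ids at 5:1 give 475/95.
    """
    ids = list(ids)
    n = len(ids)
    if n < sum(ratio):
        raise ValueError(f"need at least {sum(ratio)} ids, got {n}")
    n_cal = int(round(n * ratio[0] / (ratio[0] + ratio[1])))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cal = [ids[i] for i in sorted(perm[:n_cal])]
    pred = [ids[i] for i in sorted(perm[n_cal:])]
    return SplitPlan(calibration_ids=cal, prediction_ids=pred, ratio=tuple(ratio), seed=seed)


def summarize_reference(values) -> dict:
    """Reference-statistics row: n, max, min, mean, sample SD."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("need at least two values")
    return {
        "n": int(v.size),
        "max": float(v.max()),
        "min": float(v.min()),
        "mean": float(v.mean()),
        "sd": float(np.std(v, ddof=1)),
    }


def evaluate_predictions(
    y_brix, yhat_brix, label_scaler: tuple[float, float] | None = None
) -> EvaluationReport:
    """Full report on °Brix predictions; RMSE also on the min-max-scaled axis.

    ``label_scaler`` is the (min, max) °Brix of the calibration labels; when
    omitted the scaled RMSE uses the evaluated set's own range.  R² is
    scale-invariant so a single value covers both axes.
    """
    y, yhat = _check_pair(y_brix, yhat_brix)
    if label_scaler is None:
        label_scaler = (float(y.min()), float(y.max()))
    lo, hi = label_scaler
    span = hi - lo if hi > lo else 1.0
    r2 = r_squared(y, yhat)
    e_brix = rmse(y, yhat)
    return EvaluationReport(
        r2=r2,
        rmse_brix=e_brix,
        rmse_scaled=e_brix / span,
        rpd=rpd(y, e_brix) if e_brix > 0 else float("inf"),
        n=int(y.size),
        sd_reference=float(np.std(y, ddof=1)),
    )
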