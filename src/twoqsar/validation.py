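"""External/internal validation statistics and stringent acceptance criteria.

Implements the full battery used to judge QSAR regression models:

* residual summaries — RMSE (divide by n), MAE, the sample standard
  deviation of residuals, the maximum absolute residual, and the mean error;
* squared correlation coefficients r^2 / q^2 (with a selectable centering
  convention, see :func:`r_squared`);
* the external-set coefficients qF1^2, qF2^2, qF3^2 differing in the
  reference mean and per-sample normalization;
* Lin's concordance correlation coefficient (CCC);
* the through-origin regression statistics k, r0^2, r0'^2
  (Golbraikh-Tropsha formulation);
* the Ojha-style rm^2 family (rm^2, rm'^2, their mean and absolute gap);
* the combined stringent acceptance criteria (coefficient floors, the
  r^2 - q_cv^2 gap, through-origin closeness and slope window, r0^2
  symmetry, rm^2 floors, and a CCC floor);
* 10-fold cross-validation and the Y-scrambling randomization test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "PredictionSet",
    "ValidationReport",
    "CriteriaVerdict",
    "residuals",
    "error_stats",
    "r_squared",
    "external_q2",
    "ccc",
    "origin_regression",
    "rm2_family",
    "validation_report",
    "criteria_check",
    "kfold_cv",
    "y_scramble",
]

Fitter = Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]]


@dataclass
class PredictionSet:
    """Paired observed/predicted responses for one evaluation set.

    ``reference_train_mean`` (the training-set mean response) and
    ``reference_train_size`` are required for qF1^2 / qF3^2, which judge an
    external set against the training distribution.
    """

    ids: list[str]
    y_obs: np.ndarray
    y_pred: np.ndarray
    reference_train_mean: Optional[float] = None
    reference_train_size: Optional[int] = None

    def __post_init__(self) -> None:
        self.y_obs = np.asarray(self.y_obs, dtype=float)
        self.y_pred = np.asarray(self.y_pred, dtype=float)
        if not (len(self.ids) == len(self.y_obs) == len(self.y_pred)):
            raise ValueError("ids, y_obs, y_pred must have equal length")
        if len(self.y_obs) < 2:
            raise ValueError("a prediction set needs at least 2 points")

    @property
    def n(self) -> int:
        return len(self.y_obs)


@dataclass
class ValidationReport:
    """The full statistic set for one (observed, predicted) pairing."""

    r2_or_q2: float
    rmse: float
    mae: float
    s: float
    delta_max: float
    mean_error: float
    k: float
    r0_sq: float
    r0_prime_sq: float
    rm2: float
    rm2_prime: float
    rm2_avg: float
    rm2_delta: float
    q2_cv: Optional[float] = None
    qF1: Optional[float] = None
    qF2: Optional[float] = None
    qF3: Optional[float] = None
    ccc: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)


def residuals(p: PredictionSet) -> np.ndarray:
    """Elementwise prediction residuals, observed minus predicted."""
    return p.y_obs - p.y_pred


def error_stats(p: PredictionSet) -> tuple[float, float, float, float, float]:
    """(rmse, mae, s, delta_max, mean_error) of the residuals.

    RMSE divides by n; s is the sample standard deviation of the residuals
    (n-1 denominator); delta_max is the largest absolute residual.
    """
    d = residuals(p)
    rmse = float(np.sqrt(np.sum(d ** 2) / p.n))
    mae = float(np.mean(np.abs(d)))
    s = float(np.std(d, ddof=1))
    delta_max = float(np.max(np.abs(d)))
    mean_error = float(np.mean(d))
    return rmse, mae, s, delta_max, mean_error


def r_squared(p: PredictionSet,
              centering: str = "observed_mean") -> float:
    """Squared correlation coefficient r^2 (training) / q^2 (external).

    1 - sum(residual^2) / sum((y_i - c)^2), where the centering constant c
    is the observed mean (the conventional choice and the default) or the
    predicted mean (``centering="predicted_mean"``, matching texts that
    center the denominator on the average predicted value).
    """
    if centering not in ("observed_mean", "predicted_mean"):
        raise ValueError(f"unknown centering {centering!r}")
    c = float(np.mean(p.y_obs if centering == "observed_mean" else p.y_pred))
    denom = float(np.sum((p.y_obs - c) ** 2))
    if denom == 0:
        raise ZeroDivisionError("zero denominator in r_squared: "
                                "observations have no spread about the center")
    return 1.0 - float(np.sum(residuals(p) ** 2)) / denom


def external_q2(p: PredictionSet) -> tuple[float, float, float]:
    """(qF1^2, qF2^2, qF3^2) for an external set.

    qF1^2 centers the denominator on the training mean <y_TR>; qF2^2 on the
    external mean <y_EXT>; qF3^2 divides the residual sum by n_EXT and the
    training-centered denominator sum by n_TR.
    """
    if p.reference_train_mean is None or p.reference_train_size is None:
        raise ValueError("external_q2 requires reference_train_mean and "
                         "reference_train_size")
    d2 = float(np.sum(residuals(p) ** 2))
    y_tr = p.reference_train_mean
    n_tr = p.reference_train_size
    qf1 = 1.0 - d2 / float(np.sum((p.y_obs - y_tr) ** 2))
    qf2 = 1.0 - d2 / float(np.sum((p.y_obs - np.mean(p.y_obs)) ** 2))
    qf3 = 1.0 - (d2 / p.n) / (float(np.sum((p.y_obs - y_tr) ** 2)) / n_tr)
    return qf1, qf2, qf3


def ccc(p: PredictionSet) -> float:
    """Lin's concordance correlation coefficient.

    2 * sum((y - <y>)(yhat - <yhat>)) over
    [sum((y - <y>)^2) + sum((yhat - <yhat>)^2) + n(<y> - <yhat>)^2];
    penalizes location/scale shifts as well as poor correlation, and is
    symmetric in its two arguments.
    """
    y, yh = p.y_obs, p.y_pred
    my, myh = float(np.mean(y)), float(np.mean(yh))
    num = 2.0 * float(np.sum((y - my) * (yh - myh)))
    den = (float(np.sum((y - my) ** 2)) + float(np.sum((yh - myh) ** 2))
           + p.n * (my - myh) ** 2)
    return num / den


def origin_regression(p: PredictionSet) -> tuple[float, float, float]:
    """(k, r0^2, r0'^2) from through-origin regressions.

    k is the slope of the no-intercept fit of predicted on observed,
    k = sum(y*yhat) / sum(y^2).  r0^2 is the determination coefficient of
    that through-origin line for the predicted values,
    1 - sum((yhat - k*y)^2) / sum((yhat - <yhat>)^2); r0'^2 swaps the axes
    (observed regressed on predicted without intercept).
    """
    y, yh = p.y_obs, p.y_pred
    sy2 = float(np.sum(y ** 2))
    syh2 = float(np.sum(yh ** 2))
    if sy2 == 0 or syh2 == 0:
        raise ZeroDivisionError("through-origin regression needs nonzero vectors")
    k = float(np.sum(y * yh)) / sy2
    k_prime = float(np.sum(y * yh)) / syh2
    r0 = 1.0 - float(np.sum((yh - k * y) ** 2)) / float(
        np.sum((yh - np.mean(yh)) ** 2))
    r0p = 1.0 - float(np.sum((y - k_prime * yh) ** 2)) / float(
        np.sum((y - np.mean(y)) ** 2))
    return k, r0, r0p


def rm2_family(r2: float, r0_sq: float, r0_prime_sq: float,
               variant: str = "as_printed"
               ) -> tuple[float, float, float, float]:
    """(rm^2, rm'^2, <rm^2>, delta rm^2) from r^2 and the through-origin pair.

    ``as_printed``: rm^2 = r^2 * (1 - |r^2 - r0^2|) (no square root);
    ``sqrt``: rm^2 = r^2 * (1 - sqrt(|r^2 - r0^2|)), the Ojha original.
    The primed member uses r0'^2; the family is completed by the mean of the
    two and their absolute difference.
    """
    if variant not in ("as_printed", "sqrt"):
        raise ValueError(f"unknown rm2 variant {variant!r}")
    import warnings
    for nm, v in (("r2", r2), ("r0_sq", r0_sq), ("r0_prime_sq", r0_prime_sq)):
        if not (0.0 <= v <= 1.0):
            warnings.warn(f"rm2_family input {nm}={v} outside [0, 1]",
                          stacklevel=2)

    def gap(a: float) -> float:
        g = abs(r2 - a)
        return np.sqrt(g) if variant == "sqrt" else g

    rm2 = r2 * (1.0 - gap(r0_sq))
    rm2p = r2 * (1.0 - gap(r0_prime_sq))
    return rm2, rm2p, (rm2 + rm2p) / 2.0, abs(rm2 - rm2p)


def validation_report(
    p: PredictionSet,
    *,
    kind: str = "training",
    q2_cv: Optional[float] = None,
    centering: str = "observed_mean",
    rm2_variant: str = "as_printed",
) -> ValidationReport:
    """Compute the full statistic battery for one prediction set.

    ``kind`` is ``"training"`` or ``"external"``; external sets with the
    training reference fields populated additionally get qF1-3^2 and CCC.
    """
    if kind not in ("training", "external"):
        raise ValueError(f"kind must be 'training' or 'external', got {kind!r}")
    rmse, mae, s, dmax, mean_err = error_stats(p)
    r2 = r_squared(p, centering=centering)
    k, r0, r0p = origin_regression(p)
    rm2, rm2p, rm2a, rm2d = rm2_family(r2, r0, r0p, variant=rm2_variant)
    qf1 = qf2 = qf3 = c = None
    if kind == "external":
        c = ccc(p)
        if p.reference_train_mean is not None:
            qf1, qf2, qf3 = external_q2(p)
    return ValidationReport(
        r2_or_q2=r2, rmse=rmse, mae=mae, s=s, delta_max=dmax,
        mean_error=mean_err, k=k, r0_sq=r0, r0_prime_sq=r0p,
        rm2=rm2, rm2_prime=rm2p, rm2_avg=rm2a, rm2_delta=rm2d,
        q2_cv=q2_cv, qF1=qf1, qF2=qf2, qF3=qf3, ccc=c,
    )


#: Criterion keys, in the order the checks are reported.
CRITERIA = (
    "coefficient_floor",   # every available r^2-family coefficient >= 0.70
    "cv_gap",              # |r^2 - q_cv^2| < 0.10 (training only)
    "origin_fit",          # (r^2 - r0^2)/r^2 < 0.10 and 0.85 <= k <= 1.15
    "origin_symmetry",     # |r0^2 - r0'^2| < 0.30
    "rm2_floor",           # rm^2 >= 0.65
    "rm2_consistency",     # <rm^2> >= 0.65 and delta rm^2 < 0.20
    "ccc_floor",           # CCC >= 0.85 (where CCC is computed)
)


@dataclass
class CriteriaVerdict:
    """Per-criterion pass/fail for one evaluation set.

    Criteria that do not apply to the set (the r^2 - q_cv^2 gap outside the
    training set, the CCC floor where no CCC was computed) are ``None`` and
    excluded from ``overall``.
    """

    checks: dict[str, Optional[bool]] = field(default_factory=dict)

    @property
    def overall(self) -> bool:
        return all(v for v in self.checks.values() if v is not None)

    def to_dict(self) -> dict:
        return {"checks": dict(self.checks), "overall": self.overall}


def _check_one(report: ValidationReport, kind: str) -> CriteriaVerdict:
    r2 = report.r2_or_q2
    coeffs = [r2]
    if kind == "training":
        if report.q2_cv is not None:
            coeffs.append(report.q2_cv)
    else:
        coeffs.extend(v for v in (report.qF1, report.qF2, report.qF3)
                      if v is not None)
    def lt(value: float, bound: float) -> bool:
        # strict inequality at printed precision: 0.80 vs 0.90 is a gap of
        # exactly 0.10 and must fail "< 0.10" despite float representation
        return round(value, 12) < bound

    checks: dict[str, Optional[bool]] = {}
    checks["coefficient_floor"] = all(v >= 0.70 for v in coeffs)
    if kind == "training" and report.q2_cv is not None:
        checks["cv_gap"] = lt(abs(r2 - report.q2_cv), 0.10)
    else:
        checks["cv_gap"] = None
    checks["origin_fit"] = (lt((r2 - report.r0_sq) / r2, 0.10)
                            and 0.85 <= report.k <= 1.15)
    checks["origin_symmetry"] = lt(abs(report.r0_sq - report.r0_prime_sq),
                                   0.30)
    checks["rm2_floor"] = report.rm2 >= 0.65
    checks["rm2_consistency"] = (report.rm2_avg >= 0.65
                                 and lt(report.rm2_delta, 0.20))
    checks["ccc_floor"] = (report.ccc >= 0.85
                           if report.ccc is not None else None)
    return CriteriaVerdict(checks)


def criteria_check(
    train_report: Optional[ValidationReport] = None,
    external_report: Optional[ValidationReport] = None,
) -> dict[str, CriteriaVerdict]:
    """Stringent acceptance verdicts for training and/or external sets.

    Returns one :class:`CriteriaVerdict` per supplied report, keyed
    ``"training"`` / ``"external"``; a model is acceptable only when every
    applicable criterion holds in every set it is judged on.
    """
    if train_report is None and external_report is None:
        raise ValueError("at least one report is required")
    out: dict[str, CriteriaVerdict] = {}
    if train_report is not None:
        out["training"] = _check_one(train_report, "training")
    if external_report is not None:
        out["external"] = _check_one(external_report, "external")
    return out


def kfold_cv(X: np.ndarray, y: np.ndarray, folds: int = 10,
             fitter: Fitter = None, seed: int = 0) -> float:
    """q_cv^2 from seeded k-fold cross-validation with pooled predictions.

    ``fitter(X_train, y_train)`` must return a predict callable; out-of-fold
    predictions are pooled and scored with :func:`r_squared` (observed-mean
    centering).
    """
    if fitter is None:
        raise ValueError("a fitter functional is required")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if not (2 <= folds <= n):
        raise ValueError(f"need 2 <= folds <= n, got folds={folds}, n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    pred = np.empty(n)
    for f in range(folds):
        test = order[f::folds]
        train = np.setdiff1d(order, test)
        model = fitter(X[train], y[train])
        pred[test] = np.asarray(model(X[test]), dtype=float)
    pset = PredictionSet([str(i) for i in range(n)], y, pred)
    return r_squared(pset, centering="observed_mean")


def y_scramble(X: np.ndarray, y: np.ndarray, fitter: Fitter,
               reps: int = 25, seed: int = 0,
               permutations: Optional[Sequence[np.ndarray]] = None
               ) -> tuple[float, list[float]]:
    """Chance-correlation estimate by response scrambling.

    For each repetition the responses are randomly permuted, the model is
    refit on the unchanged descriptors, and the training r^2 against the
    scrambled responses is recorded.  Returns the mean <rs^2> and the
    per-repetition list; a sound model shows <rs^2> near zero while its
    unscrambled r^2 stays high.  ``permutations`` overrides the seeded
    random permutations with explicit index arrays (one per repetition).
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    if permutations is not None and len(permutations) != reps:
        raise ValueError("need exactly one permutation per repetition")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    out: list[float] = []
    for rep in range(reps):
        perm = (np.asarray(permutations[rep]) if permutations is not None
                else rng.permutation(len(y)))
        ys = y[perm]
        model = fitter(X, ys)
        pred = np.asarray(model(X), dtype=float)
        pset = PredictionSet([str(i) for i in range(len(y))], ys, pred)
        out.append(r_squared(pset, centering="observed_mean"))
    return float(np.mean(out)), out
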