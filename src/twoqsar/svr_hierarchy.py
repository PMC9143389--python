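"""Hierarchical support vector regression: members, grid search, stacking.

An HSVR model is an ensemble of RBF-kernel SVR members — each trained on its
own small descriptor subset with its own runtime configuration, playing the
role of a local model — whose prediction vector feeds a second-level (meta)
SVR that arbitrates between them.  Assembly is governed by parsimony: one-
member ensembles are exhausted before any two-member combination is scored,
and so on, so the simplest ensemble that satisfies the acceptance criteria
on both the training and test sets wins.

Epsilon- and nu-SVR formulations are both supported; hyperparameters
(cost C, kernel width gamma, tube width epsilon or support-vector fraction
nu) come from a systematic grid search.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.svm import SVR, NuSVR

from .core_io import CompoundRecord, DescriptorTable, NormParams
from .partition import DataSplit
from .validation import PredictionSet, r_squared

__all__ = [
    "SvrConfig",
    "SvrMember",
    "SvrEnsemble",
    "HsvrModel",
    "fit_svr",
    "grid_search",
    "grid_search_cv",
    "default_grid",
    "assemble_ensemble",
    "fit_meta",
    "predict_hsvr",
    "EnsembleSearchError",
]


@dataclass(frozen=True, order=True)
class SvrConfig:
    """Runtime configuration of one SVR: formulation + hyperparameters."""

    mode: str  # "epsilon" or "nu"
    C: float
    gamma: float
    epsilon: Optional[float] = None
    nu: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("epsilon", "nu"):
            raise ValueError(f"mode must be 'epsilon' or 'nu', got {self.mode!r}")
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if self.mode == "epsilon":
            if self.epsilon is None or self.epsilon < 0 or self.nu is not None:
                raise ValueError("epsilon mode requires epsilon >= 0 and no nu")
        else:
            if self.nu is None or not (0 < self.nu <= 1) or self.epsilon is not None:
                raise ValueError("nu mode requires nu in (0, 1] and no epsilon")

    def build(self, tol: float = 1e-3):
        if self.mode == "epsilon":
            return SVR(kernel="rbf", C=self.C, gamma=self.gamma,
                       epsilon=self.epsilon, tol=tol)
        return NuSVR(kernel="rbf", C=self.C, gamma=self.gamma,
                     nu=self.nu, tol=tol)

    def tie_break_key(self) -> tuple:
        # preferred on ties: smaller C, smaller gamma, smaller eps / larger nu
        third = self.epsilon if self.mode == "epsilon" else -self.nu
        return (self.C, self.gamma, third)


@dataclass
class SvrMember:
    """One fitted SVR restricted to its own descriptor subset."""

    descriptor_subset: list[str]
    config: SvrConfig
    estimator: object = None

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        if self.estimator is None:
            raise RuntimeError("member is not fitted")
        missing = [c for c in self.descriptor_subset if c not in frame.columns]
        if missing:
            raise KeyError(f"missing descriptors {missing}")
        return self.estimator.predict(
            frame[self.descriptor_subset].to_numpy(dtype=float))


@dataclass
class SvrEnsemble:
    """Ordered SVR members; the order fixes the meta-input column layout."""

    members: list[SvrMember]
    trace: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("an ensemble needs at least one member")

    def member_predictions(self, frame: pd.DataFrame) -> np.ndarray:
        return np.column_stack([m.predict(frame) for m in self.members])


@dataclass
class HsvrModel:
    """Ensemble + meta-SVR over the members' prediction vector."""

    ensemble: SvrEnsemble
    meta: SvrMember
    norm_params: Optional[NormParams] = None

    def __post_init__(self) -> None:
        if len(self.meta.descriptor_subset) != len(self.ensemble.members):
            raise ValueError("meta input dimension must equal ensemble size")


class EnsembleSearchError(RuntimeError):
    """No member combination passed the acceptance criteria at any size."""

    def __init__(self, msg: str, best: Optional[dict] = None,
                 trace: Optional[list] = None):
        super().__init__(msg)
        self.best = best
        self.trace = trace or []


def fit_svr(X: np.ndarray, y: np.ndarray, config: SvrConfig,
            descriptor_subset: Optional[Sequence[str]] = None,
            tol: float = 1e-3) -> SvrMember:
    """Solve the epsilon- or nu-SVR problem with an RBF kernel."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y) or len(y) < 2:
        raise ValueError("X must be n x d with matching y, n >= 2")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in SVR input")
    est = config.build(tol=tol).fit(X, y)
    subset = list(descriptor_subset) if descriptor_subset is not None else [
        f"x{j}" for j in range(X.shape[1])]
    return SvrMember(descriptor_subset=subset, config=config, estimator=est)


def default_grid(mode: str = "epsilon") -> list[SvrConfig]:
    """Systematic hyperparameter lattice.

    C spans 2^-5 .. 2^15 and gamma 2^-15 .. 2^3, both in steps of x4;
    epsilon in {0.01, 0.05, 0.1, 0.2} or nu in {0.25, 0.5, 0.75}.
    """
    Cs = [2.0 ** e for e in range(-5, 16, 2)]
    gammas = [2.0 ** e for e in range(-15, 4, 2)]
    out = []
    if mode == "epsilon":
        for C, g, e in itertools.product(Cs, gammas, (0.01, 0.05, 0.1, 0.2)):
            out.append(SvrConfig("epsilon", C, g, epsilon=e))
    elif mode == "nu":
        for C, g, nu in itertools.product(Cs, gammas, (0.25, 0.5, 0.75)):
            out.append(SvrConfig("nu", C, g, nu=nu))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def grid_search(
    X_train: np.ndarray, y_train: np.ndarray,
    X_val: np.ndarray, y_val: np.ndarray,
    grid: Sequence[SvrConfig],
) -> tuple[SvrConfig, list[tuple[SvrConfig, float]]]:
    """Evaluate every lattice point; return the validation-q^2 maximizer.

    Ties prefer smaller C, then smaller gamma, then smaller epsilon (or
    larger nu).  Returns the winning config and the full score table.
    """
    if not grid:
        raise ValueError("empty grid")
    y_val = np.asarray(y_val, dtype=float)
    table: list[tuple[SvrConfig, float]] = []
    for cfg in grid:
        member = fit_svr(X_train, y_train, cfg)
        pred = member.estimator.predict(np.asarray(X_val, dtype=float))
        pset = PredictionSet([str(i) for i in range(len(y_val))], y_val, pred)
        table.append((cfg, r_squared(pset, centering="observed_mean")))
    best_cfg, _ = min(table, key=lambda t: (-t[1],) + t[0].tie_break_key())
    return best_cfg, table


def grid_search_cv(
    X: np.ndarray, y: np.ndarray, grid: Sequence[SvrConfig],
    folds: int = 5, seed: int = 0,
) -> tuple[SvrConfig, list[tuple[SvrConfig, float]]]:
    """Grid search scored by seeded k-fold cross-validated q^2.

    The leakage-free alternative to :func:`grid_search`: no held-out test
    information enters the hyperparameter choice.  Ties break as in
    :func:`grid_search`.
    """
    if not grid:
        raise ValueError("empty grid")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    folds = min(folds, len(y))
    table: list[tuple[SvrConfig, float]] = []
    for cfg in grid:
        pred = np.empty(len(y))
        for f in range(folds):
            test = order[f::folds]
            train = np.setdiff1d(order, test)
            est = cfg.build().fit(X[train], y[train])
            pred[test] = est.predict(X[test])
        pset = PredictionSet([str(i) for i in range(len(y))], y, pred)
        table.append((cfg, r_squared(pset, centering="observed_mean")))
    best_cfg, _ = min(table, key=lambda t: (-t[1],) + t[0].tie_break_key())
    return best_cfg, table


def _frame(table: DescriptorTable) -> pd.DataFrame:
    return table.to_frame()


def assemble_ensemble(
    candidates: Sequence[tuple[Sequence[str], SvrConfig]],
    table: DescriptorTable,
    y: Sequence[float],
    splits: DataSplit,
    acceptance: Callable[[PredictionSet, PredictionSet], bool],
    max_members: int = 3,
) -> SvrEnsemble:
    """Parsimony-governed ensemble assembly.

    Candidate (descriptor subset, config) pairs are fitted on the training
    rows; combinations are then searched in strictly increasing size order
    (all singles, then all pairs, ...) and the first combination whose
    mean-member predictions pass the ``acceptance`` functional on the train
    and test prediction sets is returned.  No size-(m+1) combination is
    scored before every size-m combination has a verdict, and the search
    stops at the first success — ``trace`` on the returned ensemble (and on
    the failure error) records the full evaluation order.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    y = np.asarray(y, dtype=float)
    frame = _frame(table)
    row = {cid: i for i, cid in enumerate(table.compound_ids)}
    tr = [row[i] for i in splits.train_ids]
    te = [row[i] for i in splits.test_ids]
    fitted = []
    for subset, cfg in candidates:
        subset = list(subset)
        Xtr = frame.iloc[tr][subset].to_numpy(dtype=float)
        fitted.append(fit_svr(Xtr, y[tr], cfg, descriptor_subset=subset))
    y_tr_mean = float(np.mean(y[tr]))

    trace: list[dict] = []
    best: Optional[dict] = None
    for size in range(1, max_members + 1):
        for combo in itertools.combinations(range(len(fitted)), size):
            members = [fitted[i] for i in combo]
            pred_tr = np.mean(
                [m.predict(frame.iloc[tr]) for m in members], axis=0)
            pred_te = np.mean(
                [m.predict(frame.iloc[te]) for m in members], axis=0)
            p_train = PredictionSet(list(splits.train_ids), y[tr], pred_tr)
            p_test = PredictionSet(list(splits.test_ids), y[te], pred_te,
                                   reference_train_mean=y_tr_mean,
                                   reference_train_size=len(tr))
            ok = bool(acceptance(p_train, p_test))
            test_q2 = r_squared(p_test, centering="observed_mean")
            entry = dict(size=size, candidates=list(combo),
                         subsets=[m.descriptor_subset for m in members],
                         test_q2=test_q2, passed=ok)
            trace.append(entry)
            if best is None or test_q2 > best["test_q2"]:
                best = entry
            if ok:
                return SvrEnsemble(members=members, trace=trace)
    raise EnsembleSearchError(
        f"no combination of up to {max_members} members passed acceptance",
        best=best, trace=trace)


def fit_meta(
    ensemble: SvrEnsemble,
    table: DescriptorTable,
    y: Sequence[float],
    meta_grid: Sequence[SvrConfig],
    cv_folds: int = 5,
    seed: int = 0,
) -> HsvrModel:
    """Stack a meta-SVR on the members' training predictions.

    The n x m matrix of member predictions on the training rows becomes the
    meta input; the meta configuration is picked from ``meta_grid`` by
    seeded k-fold cross-validated q^2 on that matrix (ties resolved like
    :func:`grid_search`), then refit on all rows.
    """
    if not meta_grid:
        raise ValueError("empty meta grid")
    for m in ensemble.members:
        if m.estimator is None:
            raise RuntimeError("ensemble has unfitted members")
    y = np.asarray(y, dtype=float)
    Z = ensemble.member_predictions(_frame(table))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    folds = min(cv_folds, len(y))
    scores: list[tuple[SvrConfig, float]] = []
    for cfg in meta_grid:
        pred = np.empty(len(y))
        for f in range(folds):
            test = order[f::folds]
            train = np.setdiff1d(order, test)
            est = cfg.build().fit(Z[train], y[train])
            pred[test] = est.predict(Z[test])
        pset = PredictionSet([str(i) for i in range(len(y))], y, pred)
        scores.append((cfg, r_squared(pset, centering="observed_mean")))
    best_cfg, _ = min(scores, key=lambda t: (-t[1],) + t[0].tie_break_key())
    meta = fit_svr(Z, y, best_cfg,
                   descriptor_subset=[f"member_{i}" for i in
                                      range(len(ensemble.members))])
    return HsvrModel(ensemble=ensemble, meta=meta,
                     norm_params=table.norm_params)


def predict_hsvr(
    model: HsvrModel,
    data: Union[DescriptorTable, pd.DataFrame, Sequence[CompoundRecord]],
    *,
    apply_norm: bool = False,
) -> np.ndarray:
    """HSVR prediction: member outputs stacked through the meta-SVR.

    ``data`` may be a descriptor table, a DataFrame, or compound records;
    with ``apply_norm`` the model's stored normalization parameters are
    applied first (for raw, unscaled inputs).  A missing descriptor raises
    ``KeyError`` naming it.
    """
    frame = _as_frame(data)
    needed = sorted({d for m in model.ensemble.members
                     for d in m.descriptor_subset})
    missing = [d for d in needed if d not in frame.columns]
    if missing:
        raise KeyError(f"missing descriptors {missing}")
    if apply_norm:
        if model.norm_params is None:
            raise ValueError("model carries no normalization parameters")
        frame = frame.copy()
        for name in needed:
            frame[name] = ((frame[name] - model.norm_params.means[name])
                           / model.norm_params.scales[name])
    Z = model.ensemble.member_predictions(frame)
    return model.meta.estimator.predict(Z)


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, DescriptorTable):
        return data.to_frame()
    if isinstance(data, pd.DataFrame):
        return data
    recs = list(data)
    return pd.DataFrame([r.descriptors for r in recs],
                        index=[r.id for r in recs])


def save_hsvr(model: HsvrModel, path) -> None:
    """Serialize configs/subsets + support data to a single JSON bundle."""
    def member_blob(m: SvrMember) -> dict:
        est = m.estimator
        return {
            "subset": m.descriptor_subset,
            "config": {k: v for k, v in vars(m.config).items()
                       if v is not None},
            "support_vectors": est.support_vectors_.tolist(),
            "dual_coef": est.dual_coef_.tolist(),
            "intercept": est.intercept_.tolist(),
        }
    blob = {
        "members": [member_blob(m) for m in model.ensemble.members],
        "meta": member_blob(model.meta),
        "norm_params": (None if model.norm_params is None else
                        {"means": model.norm_params.means,
                         "scales": model.norm_params.scales}),
    }
    with open(path, "w") as fh:
        json.dump(blob, fh, indent=1)


def load_hsvr(path) -> HsvrModel:
    """Rebuild a serialized HSVR bundle (refit-free, kernel evaluation)."""
    with open(path) as fh:
        blob = json.load(fh)

    def rebuild(b: dict) -> SvrMember:
        cfg = SvrConfig(**b["config"])
        sv = np.asarray(b["support_vectors"], dtype=float)
        dual = np.asarray(b["dual_coef"], dtype=float)
        icpt = float(np.asarray(b["intercept"]).ravel()[0])
        member = SvrMember(descriptor_subset=list(b["subset"]), config=cfg)
        member.estimator = _KernelEvaluator(sv, dual.ravel(), icpt, cfg.gamma)
        return member

    members = [rebuild(b) for b in blob["members"]]
    meta = rebuild(blob["meta"])
    params = None
    if blob.get("norm_params"):
        params = NormParams(blob["norm_params"]["means"],
                            blob["norm_params"]["scales"])
    return HsvrModel(ensemble=SvrEnsemble(members=members), meta=meta,
                     norm_params=params)


class _KernelEvaluator:
    """Minimal RBF decision function for deserialized members."""

    def __init__(self, sv: np.ndarray, dual: np.ndarray, intercept: float,
                 gamma: float):
        self.sv, self.dual, self.intercept, self.gamma = sv, dual, intercept, gamma

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.sv[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.gamma * d2) @ self.dual + self.intercept
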