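"""PLS regression with cross-validated complexity, plus the published
four-descriptor skin-permeability model.

PLS projects (possibly collinear) descriptors onto latent components before
the linear fit, so it tolerates descriptor pairs an OLS fit could not.  The
number of components is picked by cross-validated q^2, and the fitted model
is collapsed to a plain affine form (intercept + per-descriptor weights) so
its chemistry reads off directly.

:func:`published_skin_model` returns the literature four-descriptor model

    log Kp = -2.62974 + 1.26972 log P - 0.55661 Vm - 0.554268 0chi
             - 0.076344 Jurs_PPSA_1

as a fixture.  Whether its coefficients apply to raw or autoscaled
descriptor values is not recorded with the model; the fixture evaluates the
affine form on whatever values are supplied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .core_io import CompoundRecord, DescriptorTable, NormParams

__all__ = ["PlsModel", "fit_pls", "published_skin_model", "predict_pls"]


@dataclass
class PlsModel:
    """Affine collapse of a PLS fit: intercept + per-descriptor weights."""

    intercept: float
    coefficients: dict[str, float]
    n_components: int
    norm_params: Optional[NormParams] = None
    cv_trace: list[tuple[int, float]] = field(default_factory=list)

    def to_json(self, path) -> None:
        blob = {"intercept": self.intercept,
                "coefficients": self.coefficients,
                "n_components": self.n_components}
        if self.norm_params is not None:
            blob["norm_params"] = {"means": self.norm_params.means,
                                   "scales": self.norm_params.scales}
        with open(path, "w") as fh:
            json.dump(blob, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PlsModel":
        with open(path) as fh:
            blob = json.load(fh)
        params = None
        if blob.get("norm_params"):
            params = NormParams(blob["norm_params"]["means"],
                                blob["norm_params"]["scales"])
        return cls(blob["intercept"], blob["coefficients"],
                   blob["n_components"], norm_params=params)


def fit_pls(
    X: np.ndarray,
    y: Sequence[float],
    max_components: Optional[int] = None,
    cv_folds: int = 10,
    seed: int = 0,
    descriptor_names: Optional[Sequence[str]] = None,
    norm_params: Optional[NormParams] = None,
) -> PlsModel:
    """Fit PLS, choosing the component count by cross-validated q^2.

    NIPALS-style PLS is fit for k = 1 .. ``max_components`` (default
    min(p, 10), capped at min(n-1, p)); each k is scored by pooled
    out-of-fold q^2 over ``cv_folds`` seeded folds, the maximizer kept, and
    the winning fit collapsed to regression-coefficient form.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= cv_folds:
        raise ValueError(f"need n > cv_folds, got n={n}, folds={cv_folds}")
    cap = min(n - 1, p)
    if max_components is None:
        max_components = min(p, 10)
    if max_components > cap:
        raise ValueError(
            f"max_components={max_components} exceeds min(n-1, p)={cap}")
    names = (list(descriptor_names) if descriptor_names is not None
             else [f"x{j}" for j in range(p)])

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    trace: list[tuple[int, float]] = []
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    for k in range(1, max_components + 1):
        pred = np.empty(n)
        for f in range(cv_folds):
            test = order[f::cv_folds]
            train = np.setdiff1d(order, test)
            m = PLSRegression(n_components=k, scale=False).fit(X[train], y[train])
            pred[test] = m.predict(X[test]).ravel()
        q2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot
        trace.append((k, q2))
    best_k = max(trace, key=lambda t: t[1])[0]
    final = PLSRegression(n_components=best_k, scale=False).fit(X, y)
    coef = final.coef_.ravel()
    intercept = float(y.mean() - X.mean(axis=0) @ coef)
    return PlsModel(
        intercept=intercept,
        coefficients={names[j]: float(coef[j]) for j in range(p)},
        n_components=best_k,
        norm_params=norm_params,
        cv_trace=trace,
    )


def published_skin_model() -> PlsModel:
    """The literature four-descriptor PLS model for log Kp (cm/h).

    Intercept -2.62974 with weights +1.26972 (log P), -0.55661 (Vm),
    -0.554268 (0chi) and -0.076344 (Jurs_PPSA_1).  No normalization state
    is attached: the affine form is evaluated on the values supplied.
    """
    return PlsModel(
        intercept=-2.62974,
        coefficients={
            "log_P": 1.26972,
            "V_m": -0.55661,
            "chi0": -0.554268,
            "Jurs_PPSA_1": -0.076344,
        },
        n_components=4,
    )


def predict_pls(
    model: PlsModel,
    data: Union[DescriptorTable, pd.DataFrame, Sequence[CompoundRecord]],
) -> np.ndarray:
    """Affine evaluation of a PLS model.

    Fitted models carrying normalization parameters transform raw inputs to
    the training scale first; the published fixture (no parameters) applies
    its printed coefficients directly.  A missing descriptor raises
    ``KeyError`` naming it.
    """
    if isinstance(data, DescriptorTable):
        frame = data.to_frame()
        normalized = data.normalized
    elif isinstance(data, pd.DataFrame):
        frame = data
        normalized = False
    else:
        recs = list(data)
        frame = pd.DataFrame([r.descriptors for r in recs],
                             index=[r.id for r in recs])
        normalized = False
    missing = [d for d in model.coefficients if d not in frame.columns]
    if missing:
        raise KeyError(f"missing descriptors {missing}")
    out = np.full(len(frame), model.intercept, dtype=float)
    for name, w in model.coefficients.items():
        col = frame[name].to_numpy(dtype=float)
        if model.norm_params is not None and not normalized:
            col = ((col - model.norm_params.means[name])
                   / model.norm_params.scales[name])
        out += w * col
    return out
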