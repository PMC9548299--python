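"""Logistic relative-risk models for emergent intubation.

The model family mirrors the continuous-monitoring risk models validated
for respiratory failure: binary logistic regressions over the windowed
cardiorespiratory features, differing in predictor basis and horizon —

* a linear-basis model with a 24 h horizon, optionally built by forward
  stepwise selection (AIC);
* two restricted-cubic-spline models (3 knots per feature by default)
  with 4 h and 6 h horizons.

A window is labelled positive when it falls within the model's horizon
before an emergent intubation; windows during mechanical ventilation or
under DNI orders are censored out.  The original development coefficients
were never published, so models here are re-fit on the synthetic
development split; the evaluation therefore validates the pipeline, not
any historical weights.

Model output is expressed as *relative risk*: the predicted event
probability divided by the mean predicted probability on the development
set, i.e. a fold-increase over the average patient (mean 1 on the
development set by construction).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)

__all__ = [
    "RiskModelSpec",
    "FittedRiskModel",
    "MODEL_PRESETS",
    "label_epochs",
    "rcs_knots",
    "rcs_basis",
    "make_basis",
    "fit_model",
    "predict_relative_risk",
]

RIDGE_LAMBDA = 1e-6  # weak L2 on slopes only, stabilizes separation


@dataclass(frozen=True)
class RiskModelSpec:
    """Functional form of one risk model.

    basis
        ``"linear"`` or ``"rcs"`` (restricted cubic spline, linear beyond
        the boundary knots).
    horizon_hours
        Width of the positive-label window before the event.
    selection
        ``"none"`` or ``"forward-stepwise"`` (AIC, enter while ΔAIC < 0).
    knot_quantiles
        Development-data quantiles at which spline knots are placed.
    """

    name: str
    feature_names: tuple[str, ...]
    basis: str = "linear"
    horizon_hours: float = 24.0
    selection: str = "none"
    knot_quantiles: tuple[float, ...] = (0.10, 0.50, 0.90)

    def __post_init__(self) -> None:
        if self.basis not in ("linear", "rcs"):
            raise ValueError("basis must be 'linear' or 'rcs'")
        if self.selection not in ("none", "forward-stepwise"):
            raise ValueError("selection must be 'none' or 'forward-stepwise'")
        if self.horizon_hours <= 0:
            raise ValueError("horizon_hours must be > 0")
        if self.basis == "rcs" and len(self.knot_quantiles) < 3:
            raise ValueError("restricted cubic splines need >= 3 knots")


def _preset(name: str, features: Sequence[str], basis: str, horizon: float,
            selection: str = "none") -> RiskModelSpec:
    return RiskModelSpec(
        name=name,
        feature_names=tuple(features),
        basis=basis,
        horizon_hours=horizon,
        selection=selection,
    )


def MODEL_PRESETS(feature_names: Sequence[str]) -> dict[str, RiskModelSpec]:
    """The three-model family over a given feature list.

    ``politano``: linear basis, 24 h horizon (stepwise selection available
    but off by default); ``moss_micu``: splines, 4 h; ``moss_sicu``:
    splines, 6 h.
    """
    return {
        "politano": _preset("politano", feature_names, "linear", 24.0),
        "moss_micu": _preset("moss_micu", feature_names, "rcs", 4.0),
        "moss_sicu": _preset("moss_sicu", feature_names, "rcs", 6.0),
    }


def label_epochs(
    window_ends: np.ndarray,
    event_time: float | None,
    horizon_hours: float,
    censored: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary labels for the 15-min epochs of one admission.

    A window end ``e`` is positive iff an event exists and
    ``0 < event_time - e <= horizon`` (open at 0: a window stamped exactly
    at the event is not positive).  Censored epochs are dropped.

    Returns
    -------
    (kept_idx, labels)
        Indices into ``window_ends`` that survive censoring, and their
        labels.
    """
    ends = np.asarray(window_ends, dtype=float)
    keep = np.ones(ends.size, dtype=bool) if censored is None else ~np.asarray(censored, bool)
    idx = np.flatnonzero(keep)
    if event_time is None:
        return idx, np.zeros(idx.size, dtype=int)
    delta = event_time - ends[idx]
    labels = ((delta > 0) & (delta <= horizon_hours * 60.0)).astype(int)
    return idx, labels


# ---------------------------------------------------------------------------
# restricted cubic splines (Harrell truncated-power form)


def rcs_knots(x: np.ndarray, quantiles: Sequence[float]) -> np.ndarray:
    """Knot locations at the given quantiles of the development data."""
    k = np.quantile(np.asarray(x, dtype=float), list(quantiles))
    if np.any(np.diff(k) <= 0):
        # degenerate (e.g. heavily tied) feature: spread knots minimally
        k = k + np.arange(len(k)) * 1e-9 * max(1.0, abs(k[-1]))
    return k


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted-cubic-spline columns for one feature: ``k - 1`` columns
    (the linear term plus ``k - 2`` nonlinear terms), linear beyond the
    boundary knots; nonlinear columns vanish below the first knot."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = t.size
    if k < 3:
        raise ValueError("need at least 3 knots")
    norm = (t[-1] - t[0]) ** 2

    def plus3(u: np.ndarray) -> np.ndarray:
        return np.where(u > 0, u**3, 0.0)

    cols = [x]
    for j in range(k - 2):
        c = (
            plus3(x - t[j])
            - plus3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + plus3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        ) / norm
        cols.append(c)
    return np.column_stack(cols)


def make_basis(
    features: pd.DataFrame,
    spec: RiskModelSpec,
    knots: dict[str, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Design matrix for a model spec (no intercept column; the fit adds it).

    For the linear basis the design is the feature columns unchanged.  For
    the spline basis each feature contributes ``k - 1`` columns; knots are
    computed from the supplied (development) data when not given.

    Raises ``ValueError`` naming the first offending row on non-finite
    input: features must be imputed first.
    """
    X = features[list(spec.feature_names)]
    bad = ~np.isfinite(X.to_numpy(dtype=float))
    if bad.any():
        row = int(np.flatnonzero(bad.any(axis=1))[0])
        raise ValueError(f"non-finite feature value in row {X.index[row]}; impute first")
    if spec.basis == "linear":
        return X.copy(), {}
    knots = dict(knots) if knots else {}
    cols: dict[str, np.ndarray] = {}
    for f in spec.feature_names:
        x = X[f].to_numpy(dtype=float)
        if f not in knots:
            knots[f] = rcs_knots(x, spec.knot_quantiles)
        B = rcs_basis(x, knots[f])
        cols[f] = B[:, 0]
        for j in range(1, B.shape[1]):
            cols[f"{f}_rcs{j}"] = B[:, j]
    return pd.DataFrame(cols, index=X.index), knots


@dataclass
class FittedRiskModel:
    """A fitted logistic risk model and its normalization constant."""

    spec: RiskModelSpec
    column_names: tuple[str, ...]
    coefficients: np.ndarray  # aligned with column_names
    intercept: float
    train_mean_p: float
    knots: dict[str, np.ndarray] = field(default_factory=dict)
    selected_features: tuple[str, ...] | None = None

    def linear_predictor(self, design: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.column_names if c not in design.columns]
        if missing:
            raise ValueError(f"design matrix lacks model columns: {missing}")
        Xm = design[list(self.column_names)].to_numpy(dtype=float)
        return self.intercept + Xm @ self.coefficients

    def predict_proba(self, design: pd.DataFrame) -> np.ndarray:
        eta = self.linear_predictor(design)
        return expit(eta)

    def to_json(self) -> str:
        payload = {
            "spec": asdict(self.spec),
            "column_names": list(self.column_names),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": self.intercept,
            "train_mean_p": self.train_mean_p,
            "knots": {k: [float(v) for v in vals] for k, vals in self.knots.items()},
            "selected_features": (
                list(self.selected_features) if self.selected_features else None
            ),
            "ridge_lambda": RIDGE_LAMBDA,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FittedRiskModel":
        d = json.loads(text)
        spec_d = d["spec"]
        spec_d["feature_names"] = tuple(spec_d["feature_names"])
        spec_d["knot_quantiles"] = tuple(spec_d["knot_quantiles"])
        spec = RiskModelSpec(**spec_d)
        return cls(
            spec=spec,
            column_names=tuple(d["column_names"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            train_mean_p=float(d["train_mean_p"]),
            knots={k: np.asarray(v, dtype=float) for k, v in d["knots"].items()},
            selected_features=(
                tuple(d["selected_features"]) if d.get("selected_features") else None
            ),
        )


def _bernoulli_loglik(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Maximum-likelihood logistic fit with a weak ridge on the slopes.

    Under (near-)complete separation the weak ridge keeps the optimum
    finite but extremely flat; the fit then stops at the iteration cap and
    is reported converged-with-warning via the log, which leaves the
    predicted probabilities unchanged to working precision.
    """
    if X.shape[1] == 0:
        prev = float(np.mean(y))
        return np.empty(0), float(np.log(prev / (1 - prev)))
    lr = LogisticRegression(
        C=1.0 / RIDGE_LAMBDA, solver="lbfgs", max_iter=2000, tol=1e-8
    )
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        lr.fit(X, y)
    if lr.n_iter_[0] >= 2000:
        logger.warning(
            "logistic fit hit the iteration cap (near-separation under the "
            "weak ridge); treating as converged-with-warning"
        )
    return lr.coef_[0].copy(), float(lr.intercept_[0])


def fit_model(
    design: pd.DataFrame,
    labels: np.ndarray,
    spec: RiskModelSpec,
    knots: dict[str, np.ndarray] | None = None,
) -> FittedRiskModel:
    """Fit the logistic model (optionally with forward stepwise selection).

    ``design`` is the output of :func:`make_basis` on the development
    features.  ``train_mean_p`` is the mean predicted probability on this
    development set, stored as the relative-risk denominator.
    Raises ``ValueError`` when only one class is present.
    """
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class; cannot fit")
    if spec.selection == "forward-stepwise":
        cols = _forward_stepwise(design, y, spec)
        selected = tuple(
            f for f in spec.feature_names if any(c == f or c.startswith(f + "_rcs") for c in cols)
        )
    else:
        cols = list(design.columns)
        selected = None
    X = design[cols].to_numpy(dtype=float)
    coef, intercept = _fit_logistic(X, y)
    eta = intercept + (X @ coef if coef.size else 0.0)
    p = expit(eta)
    return FittedRiskModel(
        spec=spec,
        column_names=tuple(cols),
        coefficients=coef,
        intercept=intercept,
        train_mean_p=float(np.mean(p)),
        knots=dict(knots or {}),
        selected_features=selected,
    )


def _feature_column_blocks(design: pd.DataFrame, spec: RiskModelSpec) -> dict[str, list[str]]:
    blocks: dict[str, list[str]] = {}
    for f in spec.feature_names:
        blocks[f] = [c for c in design.columns if c == f or c.startswith(f + "_rcs")]
    return blocks


def _forward_stepwise(design: pd.DataFrame, y: np.ndarray, spec: RiskModelSpec) -> list[str]:
    """Greedy forward selection over whole feature blocks by AIC."""
    blocks = _feature_column_blocks(design, spec)
    chosen: list[str] = []
    remaining = [f for f in spec.feature_names if blocks[f]]

    def aic(cols: list[str]) -> float:
        X = design[cols].to_numpy(dtype=float)
        coef, intercept = _fit_logistic(X, y)
        eta = intercept + (X @ coef if coef.size else 0.0)
        p = expit(eta)
        k = 1 + len(cols)
        return 2 * k - 2 * _bernoulli_loglik(y, p)

    current_cols: list[str] = []
    current_aic = aic(current_cols)
    while remaining:
        trials = [(aic(current_cols + blocks[f]), f) for f in remaining]
        best_aic, best_f = min(trials)
        if best_aic >= current_aic:
            break
        chosen.append(best_f)
        current_cols = current_cols + blocks[best_f]
        current_aic = best_aic
        remaining.remove(best_f)
    logger.info("forward stepwise selected %s (AIC %.2f)", chosen, current_aic)
    return current_cols


def predict_relative_risk(
    model: FittedRiskModel,
    features: pd.DataFrame,
    censored: np.ndarray | None = None,
    cap: float | None = None,
) -> pd.DataFrame:
    """Relative-risk series: predicted probability / development mean.

    ``features`` must carry ``admission_id`` and ``window_end_min`` columns
    plus the (imputed) model features.  ``cap``, when given, truncates
    relative risks from above — motivated by the tendency of such models
    to overshoot in the highest decile.
    """
    missing = [f for f in model.spec.feature_names if f not in features.columns]
    if missing:
        raise ValueError(f"features table lacks model inputs: {missing}")
    design, _ = make_basis(features, model.spec, knots=model.knots or None)
    p = model.predict_proba(design)
    rr = p / model.train_mean_p
    if cap is not None:
        rr = np.minimum(rr, cap)
    out = pd.DataFrame(
        {
            "admission_id": features["admission_id"].to_numpy(),
            "window_end_min": features["window_end_min"].to_numpy(dtype=float),
            "relative_risk": rr,
            "censored": (
                np.zeros(len(features), dtype=bool)
                if censored is None
                else np.asarray(censored, dtype=bool)
            ),
        }
    )
    return out
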