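"""Multiple-linear-regression QSAR on precomputed molecular descriptors.

Models take the form ``pIC50 = c + a1*x1 + ... + an*xn`` over a descriptor
matrix computed externally (constitutional, electrotopological, Jurs,
quantum-chemical descriptors and so on are inputs, never computed here).
Provides ordinary-least-squares fitting, the validation-statistic suite
(r2, adjusted r2, leave-one-out q2, predictive r2, RMSE, maximum error,
Friedman lack-of-fit), relative descriptor contributions, and exhaustive
small-subset search.  The ten published triazine models ship as fixtures.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorMatrix",
    "LinearModel",
    "FitStats",
    "ContributionResult",
    "evaluate_linear_model",
    "fit_mlr",
    "goodness_of_fit",
    "validation_stats",
    "descriptor_contribution",
    "subset_search",
    "load_published_models",
    "read_descriptor_matrix",
]


class FitError(RuntimeError):
    """Raised when an OLS fit is ill-posed (rank deficiency, n <= p)."""


@dataclass
class DescriptorMatrix:
    """Dense compounds x descriptors matrix with named rows and columns."""

    compound_ids: list[int]
    descriptor_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if n != len(self.compound_ids) or p != len(self.descriptor_names):
            raise ValueError("matrix shape does not match id/name lists")
        if len(set(self.descriptor_names)) != p:
            raise ValueError("descriptor names must be unique")
        if len(set(self.compound_ids)) != n:
            raise ValueError("compound ids must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("descriptor matrix contains missing/non-finite values")

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.compound_ids, columns=self.descriptor_names
        )

    def columns(self, names: Sequence[str]) -> np.ndarray:
        missing = [n for n in names if n not in self.descriptor_names]
        if missing:
            raise KeyError(f"descriptors not in matrix: {missing}")
        idx = [self.descriptor_names.index(n) for n in names]
        return self.values[:, idx]

    def subset_rows(self, ids: Sequence[int]) -> "DescriptorMatrix":
        pos = {cid: i for i, cid in enumerate(self.compound_ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"compound ids not in matrix: {missing}")
        rows = [pos[i] for i in ids]
        return DescriptorMatrix(list(ids), list(self.descriptor_names), self.values[rows])


@dataclass
class LinearModel:
    """Intercept plus named descriptor coefficients."""

    intercept: float
    coefficients: dict[str, float]

    def predict(self, X: DescriptorMatrix) -> np.ndarray:
        names = list(self.coefficients)
        a = np.array([self.coefficients[n] for n in names])
        return self.intercept + X.columns(names) @ a


@dataclass
class FitStats:
    r2: float
    r2_adj: float
    q2_loo: float
    pred_r2: float
    rmse: float
    max_error: float
    lof: float
    n_train: int
    n_test: int
    n_descriptors: int

    def as_dict(self) -> dict[str, float | int]:
        return dict(self.__dict__)


@dataclass
class ContributionResult:
    """Relative descriptor contributions in percent (may be signed); the
    sub-model r2 values used are retained for audit."""

    alpha: dict[str, float]
    r2_full: float
    r2_without: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.alpha.values())
        if abs(total - 100.0) > 1e-6 * max(1.0, abs(total)):
            raise ValueError(f"contributions must sum to 100%, got {total}")


def evaluate_linear_model(model: LinearModel, X: DescriptorMatrix) -> pd.Series:
    """Evaluate ``y_i = c + sum_j a_j x_ij`` for every compound, in row order."""
    return pd.Series(model.predict(X), index=X.compound_ids, name="predicted")


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def fit_mlr(X: DescriptorMatrix, y: Sequence[float]) -> LinearModel:
    """Ordinary least squares fit of pIC50 on the given descriptors."""
    y = np.asarray(y, dtype=float)
    n, p = X.values.shape
    if n != len(y):
        raise ValueError("y length does not match the descriptor matrix")
    if n <= p + 1:
        raise FitError(f"need n > p + 1 compounds, got n={n}, p={p}")
    D = _design(X.values)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise FitError("descriptor matrix is rank deficient (collinear columns)")
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    return LinearModel(
        intercept=float(beta[0]),
        coefficients={name: float(b) for name, b in zip(X.descriptor_names, beta[1:])},
    )


def goodness_of_fit(y_obs: Sequence[float], y_pred: Sequence[float]) -> dict[str, float]:
    """r2 = 1 - SS_res/SS_tot, sdec = sqrt(SS_res/N), and max |residual|.

    The same kernel scores calibration (SDEC) and, fed held-out predictions,
    cross-validation (q2/SDEP): both use the mean of the observed vector and
    an N (not N-1) divisor.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape or y_obs.ndim != 1 or len(y_obs) < 2:
        raise ValueError("y_obs and y_pred must be equal-length vectors (n >= 2)")
    ss_tot = float(((y_obs - y_obs.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("y_obs has zero variance")
    resid = y_obs - y_pred
    ss_res = float((resid**2).sum())
    return {
        "r2": 1.0 - ss_res / ss_tot,
        "sdec": float(np.sqrt(ss_res / len(y_obs))),
        "max_error": float(np.abs(resid).max()),
    }


def _q2(y_obs: np.ndarray, y_pred: np.ndarray, y_mean: float | None = None) -> float:
    """q2 = 1 - sum (obs - pred)^2 / sum (obs - mean)^2."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    mean = float(np.mean(y_obs)) if y_mean is None else y_mean
    ss_tot = float(((y_obs - mean) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("observed values have zero variance about the mean")
    return 1.0 - float(((y_obs - y_pred) ** 2).sum()) / ss_tot


def friedman_lof(ss_res: float, n: int, p: int, d: float = 0.5) -> float:
    """Friedman lack-of-fit: (SS_res/N) / (1 - (p + 1 + d*p)/N)**2.

    ``d`` is the smoothing penalty (0.5 by default, the usual GFA setting);
    the statistic penalizes descriptor count on top of raw residual error.
    """
    penalty = 1.0 - (p + 1 + d * p) / n
    if penalty <= 0:
        return float("inf")
    return (ss_res / n) / penalty**2


def q2_loo_mlr(X: DescriptorMatrix, y: Sequence[float]) -> float:
    """Leave-one-out q2 by literally refitting the model n times."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        Xi = DescriptorMatrix(
            [X.compound_ids[j] for j in keep], list(X.descriptor_names), X.values[keep]
        )
        model = fit_mlr(Xi, y[keep])
        preds[i] = model.predict(X)[i]
    return _q2(y, preds)


def validation_stats(
    descriptor_names: Sequence[str],
    X_train: DescriptorMatrix,
    y_train: Sequence[float],
    X_test: DescriptorMatrix,
    y_test: Sequence[float],
    lof_d: float = 0.5,
) -> tuple[LinearModel, FitStats]:
    """Fit on the training set and compute the full statistic suite.

    q2_loo refits per left-out training compound; pred_r2 scores the test
    predictions with the r2 formula (SS_tot about the test mean); r2_adj uses
    the n - p - 1 correction; RMSE is the training sdec; max_error spans
    train and test.
    """
    names = list(descriptor_names)
    Xtr = DescriptorMatrix(
        list(X_train.compound_ids), names, X_train.columns(names)
    )
    Xte = DescriptorMatrix(list(X_test.compound_ids), names, X_test.columns(names))
    y_train = np.asarray(y_train, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    model = fit_mlr(Xtr, y_train)
    n, p = len(y_train), len(names)

    train_pred = model.predict(Xtr)
    gof = goodness_of_fit(y_train, train_pred)
    test_pred = model.predict(Xte)
    pred_r2 = goodness_of_fit(y_test, test_pred)["r2"]
    max_err = max(
        gof["max_error"], float(np.abs(y_test - test_pred).max()) if len(y_test) else 0.0
    )
    ss_res = float(((y_train - train_pred) ** 2).sum())
    stats = FitStats(
        r2=gof["r2"],
        r2_adj=1.0 - (1.0 - gof["r2"]) * (n - 1) / (n - p - 1),
        q2_loo=q2_loo_mlr(Xtr, y_train),
        pred_r2=pred_r2,
        rmse=gof["sdec"],
        max_error=max_err,
        lof=friedman_lof(ss_res, n, p, d=lof_d),
        n_train=n,
        n_test=len(y_test),
        n_descriptors=p,
    )
    return model, stats


def _r2_of_subset(X: DescriptorMatrix, y: np.ndarray, names: Sequence[str]) -> float:
    sub = DescriptorMatrix(list(X.compound_ids), list(names), X.columns(names))
    model = fit_mlr(sub, y)
    return goodness_of_fit(y, model.predict(sub))["r2"]


def descriptor_contribution(
    descriptor_names: Sequence[str], X: DescriptorMatrix, y: Sequence[float]
) -> ContributionResult:
    """Relative contribution of each descriptor via leave-one-descriptor-out r2.

    For k descriptors, alpha_i = [r2(all) - r2(all minus x_i)] /
    [k*r2(all) - sum_j r2(all minus x_j)] * 100.  At k = 3 this is exactly
    the three-descriptor difference quotient used for the published triazine
    models.  Values are signed and sum to 100% by construction.
    """
    names = list(descriptor_names)
    if len(names) < 2:
        raise ValueError("need at least 2 descriptors")
    y = np.asarray(y, dtype=float)
    r2_full = _r2_of_subset(X, y, names)
    r2_wo = {}
    for name in names:
        rest = [n for n in names if n != name]
        try:
            r2_wo[name] = _r2_of_subset(X, y, rest)
        except FitError as exc:
            raise FitError(f"sub-model without {name!r} ({rest}) failed: {exc}") from exc
    denom = len(names) * r2_full - sum(r2_wo.values())
    if denom == 0:
        raise ValueError("degenerate contribution denominator (all sub-models equal)")
    alpha = {n: (r2_full - r2_wo[n]) / denom * 100.0 for n in names}
    return ContributionResult(alpha=alpha, r2_full=r2_full, r2_without=r2_wo)


def subset_search(
    X_train: DescriptorMatrix,
    y_train: Sequence[float],
    X_test: DescriptorMatrix,
    y_test: Sequence[float],
    k: int,
    top_m: int = 10,
    pool: Sequence[str] | None = None,
) -> list[tuple[tuple[str, ...], FitStats]]:
    """Exhaustively rank all k-descriptor subsets by LOO q2.

    Ties break by pred_r2 (descending) then lexicographic names, so the
    ranking is fully deterministic.  Subsets whose fit is ill-posed
    (collinear columns) are skipped.  Intended for desk-scale pools (k <= 4).
    """
    names = list(pool) if pool is not None else list(X_train.descriptor_names)
    if k > len(names):
        raise ValueError(f"subset size {k} exceeds pool size {len(names)}")
    if k > 4:
        raise ValueError("subset_search is exhaustive; k <= 4 only")
    results = []
    for combo in combinations(sorted(names), k):
        try:
            _, stats = validation_stats(combo, X_train, y_train, X_test, y_test)
        except FitError:
            continue
        results.append((combo, stats))
    results.sort(key=lambda item: (-item[1].q2_loo, -item[1].pred_r2, item[0]))
    return results[:top_m]


def load_published_models() -> dict[str, LinearModel]:
    """The ten published triazine MLR models (five per antibody system),
    with coefficients exactly as printed."""
    ref = importlib.resources.files("triazqsar.data") / "published_models.json"
    raw = json.loads(ref.read_text())
    return {
        name: LinearModel(entry["intercept"], dict(entry["coefficients"]))
        for name, entry in raw.items()
    }


def read_descriptor_matrix(path: str | Path) -> DescriptorMatrix:
    """Read a descriptor CSV: first column compound id, remaining columns
    one descriptor each."""
    df = pd.read_csv(path)
    id_col = df.columns[0]
    ids = [int(i) for i in df[id_col]]
    names = [str(c) for c in df.columns[1:]]
    return DescriptorMatrix(ids, names, df[names].to_numpy(dtype=float))
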