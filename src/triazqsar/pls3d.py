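"""PLS regression on molecular-interaction-field matrices.

The latent-variable engine is NIPALS (non-linear iterative partial least
squares) with mean-centring, written for a single response (pIC50).
Predictive power is judged exactly as 3D-QSAR practice does:

* ``q2 = 1 - sum (y_obs - y_pred)^2 / sum (y_obs - y_mean)^2`` on held-out
  predictions, leave-one-out or repeated leave-many-out (75/25, 50 times);
* ``SDEP = sqrt(sum (y_obs - y_pred)^2 / N)`` and its calibration twin SDEC.

Variable selection follows the GOLPE lineage: smart region definition (SRD)
groups grid variables by spatial proximity, and a fractional factorial
design (FFD) over group inclusion — with interspersed dummy variables —
keeps only groups whose removal would not improve prediction beyond dummy
noise.  Model coefficients map back onto the grid for contour-map export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.linalg import hadamard

from .mif_engine import Grid, MifMatrix

__all__ = [
    "PLSModel",
    "CVResult",
    "FieldContribution",
    "SRDGroups",
    "FFDResult",
    "ContourMap",
    "fit_pls",
    "loo_cv",
    "lmo_cv",
    "choose_components",
    "model_summary",
    "summary_from_predictions",
    "field_contributions",
    "srd_group",
    "ffd_select",
    "export_contour",
]


def _as_matrix(X: MifMatrix | np.ndarray) -> np.ndarray:
    return X.X if isinstance(X, MifMatrix) else np.asarray(X, dtype=float)


@dataclass
class PLSModel:
    n_components: int
    x_weights: np.ndarray  # (p, A)
    x_loadings: np.ndarray  # (p, A)
    y_loadings: np.ndarray  # (A,)
    scores: np.ndarray  # (n, A)
    x_mean: np.ndarray
    y_mean: float
    coefficients: np.ndarray  # (p,) regression vector on centred X

    def predict(self, X: MifMatrix | np.ndarray) -> np.ndarray:
        M = _as_matrix(X)
        return (M - self.x_mean) @ self.coefficients + self.y_mean


@dataclass
class CVResult:
    method: Literal["LOO", "LMO"]
    q2: float
    sdep: float
    per_fold: list[tuple[list[int], np.ndarray]]
    fraction: float | None = None
    repetitions: int | None = None
    seed: int | None = None
    per_repetition_q2: list[float] = field(default_factory=list)


@dataclass
class FieldContribution:
    """Percent share of each field kind in the model, from sum |b_j|*SD(x_j)."""

    shares: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.shares.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"field shares must sum to 100, got {total}")


def fit_pls(
    X: MifMatrix | np.ndarray,
    y: Sequence[float],
    n_components: int,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> PLSModel:
    """NIPALS PLS1 with mean-centred X and y.

    The weight vector of each component is seeded from the covariance of the
    deflated X with the current response residual, so the fit is fully
    deterministic.  Components stop early if X is deflated to numerical zero.
    """
    M = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = M.shape
    if n != len(y):
        raise ValueError("X and y lengths differ")
    if np.isnan(M).any() or np.isnan(y).any():
        raise ValueError("NaN in inputs")
    if np.std(y) == 0:
        raise ValueError("y has zero variance")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
        )
    x_mean = M.mean(axis=0)
    y_mean = float(y.mean())
    E = M - x_mean
    f = y - y_mean
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    used = 0
    for a in range(n_components):
        cov = E.T @ f
        norm = np.linalg.norm(cov)
        if norm < 1e-14:
            break  # X residual carries no covariance with y
        w = cov / norm
        t = E @ w
        # for a single response NIPALS converges immediately; iterate to the
        # fixed point anyway so the invariants hold at tol
        for _ in range(max_iter):
            tt = float(t @ t)
            if tt == 0:
                raise RuntimeError(f"degenerate score vector at component {a + 1}")
            qa = float(f @ t) / tt
            u = f * qa  # y-side score for a single response
            w_new = E.T @ u
            w_norm = np.linalg.norm(w_new)
            if w_norm < 1e-14:
                break
            w_new /= w_norm
            if np.linalg.norm(w_new - w) < tol or np.linalg.norm(w_new + w) < tol:
                w = w_new
                t = E @ w
                break
            w = w_new
            t = E @ w
        else:
            raise RuntimeError(
                f"NIPALS failed to converge within {max_iter} iterations "
                f"at component {a + 1}"
            )
        tt = float(t @ t)
        p_a = E.T @ t / tt
        q_a = float(f @ t) / tt
        E = E - np.outer(t, p_a)
        f = f - t * q_a
        W[:, a], P[:, a], T[:, a], q[a] = w, p_a, t, q_a
        used += 1
    if used == 0:
        raise RuntimeError("no PLS component could be extracted")
    W, P, T, q = W[:, :used], P[:, :used], T[:, :used], q[:used]
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(
        n_components=used,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        x_mean=x_mean,
        y_mean=y_mean,
        coefficients=coef,
    )


def _q2(y_obs: np.ndarray, y_pred: np.ndarray, y_mean: float) -> float:
    ss_tot = float(((y_obs - y_mean) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero total sum of squares about y_mean")
    return 1.0 - float(((y_obs - y_pred) ** 2).sum()) / ss_tot


def loo_cv(
    X: MifMatrix | np.ndarray, y: Sequence[float], n_components: int
) -> CVResult:
    """Leave-one-out: refit per left-out molecule; q2 and SDEP on the n
    held-out predictions (y_mean is the full observed mean, divisor N)."""
    M = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 rows for LOO")
    preds = np.empty(n)
    folds = []
    for i in range(n):
        mask = np.arange(n) != i
        comps = min(n_components, mask.sum() - 1)
        model = fit_pls(M[mask], y[mask], comps)
        preds[i] = model.predict(M[i : i + 1])[0]
        folds.append(([i], preds[i : i + 1].copy()))
    q2 = _q2(y, preds, float(y.mean()))
    sdep = float(np.sqrt(((y - preds) ** 2).mean()))
    return CVResult(method="LOO", q2=q2, sdep=sdep, per_fold=folds)


def lmo_cv(
    X: MifMatrix | np.ndarray,
    y: Sequence[float],
    n_components: int,
    fraction: float = 0.75,
    repetitions: int = 50,
    seed: int = 0,
) -> CVResult:
    """Repeated leave-many-out: random 75/25 train/test splits, q2 on each
    held-out quarter, averaged over the repetitions; SDEP pooled over all
    held-out predictions.  Degenerate repetitions (constant training y) are
    skipped and the divisor adjusted."""
    M = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 rows for LMO")
    rng = np.random.default_rng(seed)
    y_mean = float(y.mean())
    q2s: list[float] = []
    folds = []
    ss_res_total, n_pred_total = 0.0, 0
    for _ in range(repetitions):
        perm = rng.permutation(n)
        n_train = max(2, int(round(fraction * n)))
        train, test = perm[:n_train], perm[n_train:]
        if len(test) == 0 or np.std(y[train]) == 0:
            continue
        ss_tot = float(((y[test] - y_mean) ** 2).sum())
        if ss_tot == 0:
            continue
        comps = min(n_components, len(train) - 1)
        model = fit_pls(M[train], y[train], comps)
        preds = model.predict(M[test])
        q2s.append(1.0 - float(((y[test] - preds) ** 2).sum()) / ss_tot)
        ss_res_total += float(((y[test] - preds) ** 2).sum())
        n_pred_total += len(test)
        folds.append((test.tolist(), preds))
    if not q2s:
        raise RuntimeError("all LMO repetitions were degenerate")
    return CVResult(
        method="LMO",
        q2=float(np.mean(q2s)),
        sdep=float(np.sqrt(ss_res_total / n_pred_total)),
        per_fold=folds,
        fraction=fraction,
        repetitions=repetitions,
        seed=seed,
        per_repetition_q2=q2s,
    )


def choose_components(
    X: MifMatrix | np.ndarray,
    y: Sequence[float],
    max_components: int = 5,
) -> int:
    """Default model size: the component count (1..max) maximizing LOO q2."""
    M = _as_matrix(X)
    upper = min(max_components, M.shape[0] - 2, M.shape[1])
    best_a, best_q2 = 1, -np.inf
    for a in range(1, upper + 1):
        q2 = loo_cv(M, y, a).q2
        if q2 > best_q2:
            best_a, best_q2 = a, q2
    return best_a


def summary_from_predictions(
    y_obs: Sequence[float], y_pred: Sequence[float], n_components: int
) -> dict[str, float]:
    """R2, SDEC and F for a set of calibration predictions.

    F = [r2/p] / [(1-r2)/(n-p-1)] with p = number of latent components; a
    perfect fit reports F = +inf.
    """
    from .qsar2d import goodness_of_fit

    gof = goodness_of_fit(y_obs, y_pred)
    n, p = len(np.asarray(y_obs)), n_components
    r2 = gof["r2"]
    f = float("inf") if r2 >= 1.0 else (r2 / p) / ((1.0 - r2) / (n - p - 1))
    return {"r2": r2, "sdec": gof["sdec"], "f_test": f}


def model_summary(
    model: PLSModel, X: MifMatrix | np.ndarray, y: Sequence[float]
) -> dict[str, float]:
    """Calibration statistics of a fitted PLS model on its training data."""
    return summary_from_predictions(y, model.predict(X), model.n_components)


def field_contributions(model: PLSModel, X: MifMatrix) -> FieldContribution:
    """Percent contribution of each field kind: the share of
    sum_j |b_j| * SD(x_j) carried by that kind's columns."""
    if not isinstance(X, MifMatrix):
        raise TypeError("field_contributions needs a MifMatrix with column kinds")
    sd = X.X.std(axis=0)
    weight = np.abs(model.coefficients) * sd
    total = weight.sum()
    if total == 0:
        raise ValueError("all coefficients are zero")
    kinds = X.kept_kinds
    shares = {
        str(kind): float(weight[kinds == kind].sum() / total * 100.0)
        for kind in dict.fromkeys(kinds)
    }
    return FieldContribution(shares)


@dataclass
class SRDGroups:
    """Column groups from smart region definition, as index lists into the
    kept columns of the MifMatrix."""

    groups: list[list[int]]
    seeds: list[int]

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def srd_group(
    X: MifMatrix,
    weights: np.ndarray,
    n_seeds: int | None = None,
    critical_radius: float | None = None,
    collapse_radius: float | None = None,
) -> SRDGroups:
    """Group grid variables by spatial proximity (smart region definition).

    Seeds are the columns of largest |weight| (typically from a preliminary
    PLS fit).  Every column within ``critical_radius`` of its nearest seed
    of the same field kind joins that seed's group; groups whose seeds lie
    within ``collapse_radius`` of each other merge; remaining columns stay
    singleton groups.  Radii default to 1 and 2 grid spacings.
    """
    if X.grid is None:
        raise ValueError("MifMatrix carries no grid")
    weights = np.asarray(weights, dtype=float)
    n_cols = X.X.shape[1]
    if len(weights) != n_cols:
        raise ValueError("one weight per kept column required")
    if n_cols == 0:
        raise ValueError("empty variable matrix")
    spacing = X.grid.spec.spacing
    critical = critical_radius if critical_radius is not None else 1.0 * spacing
    collapse = collapse_radius if collapse_radius is not None else 2.0 * spacing
    n_seeds = n_seeds if n_seeds is not None else max(1, n_cols // 10)

    coords = X.grid.origin + X.grid.linear_to_ijk(X.kept_indices) * spacing
    kinds = X.kept_kinds
    order = np.argsort(-np.abs(weights), kind="stable")
    seeds = list(order[:n_seeds])

    assignment = np.full(n_cols, -1, dtype=int)
    for j in range(n_cols):
        best, best_d = -1, np.inf
        for s_idx, s in enumerate(seeds):
            if kinds[s] != kinds[j]:
                continue
            d = float(np.linalg.norm(coords[j] - coords[s]))
            if d <= critical and (d < best_d or (d == best_d and s_idx < best)):
                best, best_d = s_idx, d
        assignment[j] = best

    # union-find over seeds closer than the collapse radius (same kind)
    parent = list(range(len(seeds)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a in range(len(seeds)):
        for b in range(a + 1, len(seeds)):
            if kinds[seeds[a]] != kinds[seeds[b]]:
                continue
            if np.linalg.norm(coords[seeds[a]] - coords[seeds[b]]) <= collapse:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    merged: dict[int, list[int]] = {}
    singletons: list[list[int]] = []
    for j in range(n_cols):
        if assignment[j] < 0:
            singletons.append([j])
        else:
            merged.setdefault(find(assignment[j]), []).append(j)
    groups = [sorted(g) for _, g in sorted(merged.items())] + sorted(singletons)
    return SRDGroups(groups=groups, seeds=[int(s) for s in seeds])


@dataclass
class FFDResult:
    kept_groups: list[int]
    dropped_groups: list[int]
    effects: np.ndarray  # per group: mean SDEP(in) - mean SDEP(out)
    dummy_effects: np.ndarray
    threshold: float
    design: np.ndarray
    kept_columns: np.ndarray  # indices into the kept columns of the MifMatrix


def ffd_select(
    X: MifMatrix | np.ndarray,
    y: Sequence[float],
    groups: SRDGroups | Sequence[Sequence[int]],
    n_components: int,
    dummy_ratio: float = 0.2,
    seed: int = 0,
    lmo_fraction: float = 0.75,
    lmo_repetitions: int = 5,
) -> FFDResult:
    """Fractional-factorial screening of variable groups against dummies.

    A two-level Hadamard design (+1 include / -1 exclude) plus its fold-over
    (mirror image, which frees main effects from two-factor-interaction
    aliasing) is laid over the real groups and ``dummy_ratio`` as many dummy
    variables, its columns shuffled by ``seed``.  Each design row's SDEP
    comes from leave-many-out cross-validation on the included columns; all
    rows share the same LMO partitions (common random numbers), so
    row-to-row SDEP differences are attributable to the variables, not to
    resampling noise.

    The effect of a variable is mean SDEP over rows including it minus mean
    SDEP over rows excluding it (negative = inclusion helps prediction).  A
    group is retained only when its effect beats the dummy significance
    band, effect < mean(dummy) - 2*SD(dummy): groups indistinguishable from
    dummies — including actively detrimental ones — are dropped.  If no
    group clears the band the screen is deemed uninformative and every
    group is retained.
    """
    M = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    group_list = list(groups.groups) if isinstance(groups, SRDGroups) else [list(g) for g in groups]
    n_groups = len(group_list)
    if n_groups < 2:
        kept_cols = np.array(sorted({c for g in group_list for c in g}), dtype=int)
        return FFDResult(list(range(n_groups)), [], np.zeros(n_groups), np.zeros(0),
                         0.0, np.zeros((0, n_groups)), kept_cols)
    n_dummies = max(2, int(round(dummy_ratio * n_groups)))
    n_vars = n_groups + n_dummies
    order = 1
    while order < n_vars + 1:
        order *= 2
    H = hadamard(order)
    rng = np.random.default_rng(seed)
    cols = rng.permutation(order - 1)[:n_vars] + 1  # skip the all-ones column
    design = np.vstack([H[:, cols], -H[:, cols]])  # fold-over: resolution IV
    if design.shape[0] < n_vars:
        raise ValueError("factorial design smaller than groups + dummies")

    lmo_seed = int(rng.integers(2**31 - 1))
    sdep = np.full(design.shape[0], np.nan)
    for r in range(design.shape[0]):
        included = [g for g, level in zip(group_list, design[r, :n_groups]) if level > 0]
        col_idx = sorted({c for g in included for c in g})
        if len(col_idx) == 0:
            continue
        comps = min(n_components, len(col_idx), len(y) - 2)
        try:
            cv = lmo_cv(
                M[:, col_idx], y, comps,
                fraction=lmo_fraction,
                repetitions=lmo_repetitions,
                seed=lmo_seed,
            )
        except (ValueError, RuntimeError):
            continue
        sdep[r] = cv.sdep

    def effect(v: int) -> float:
        inc = sdep[(design[:, v] > 0) & np.isfinite(sdep)]
        exc = sdep[(design[:, v] < 0) & np.isfinite(sdep)]
        if len(inc) == 0 or len(exc) == 0:
            return 0.0
        return float(inc.mean() - exc.mean())

    effects = np.array([effect(v) for v in range(n_groups)])
    dummy_effects = np.array([effect(v) for v in range(n_groups, n_vars)])
    threshold = float(dummy_effects.mean() - 2.0 * dummy_effects.std())
    kept = [g for g in range(n_groups) if effects[g] < threshold]
    if not kept:  # uninformative screen: do not discard the whole model
        kept = list(range(n_groups))
    dropped = [g for g in range(n_groups) if g not in kept]
    kept_cols = np.array(sorted({c for g in kept for c in group_list[g]}), dtype=int)
    return FFDResult(kept, dropped, effects, dummy_effects, threshold, design, kept_cols)


@dataclass
class ContourMap:
    """Per-field scalar grids for favorable/unfavorable contouring."""

    volumes: dict[str, np.ndarray]  # field kind -> (nx, ny, nz)
    levels: dict[str, dict[str, float]]  # kind -> {positive, negative}
    weighting: str


def export_contour(
    model: PLSModel,
    X: MifMatrix,
    out_dir: str | Path,
    percentile: float = 90.0,
    weighting: Literal["stdev_coeff", "coeff"] = "stdev_coeff",
    fmt: Literal["dx", "cube"] = "dx",
    basename: str = "mif",
) -> ContourMap:
    """Write one scalar grid per field kind plus a JSON levels sidecar.

    Grid values are coefficient * column SD (the usual CoMFA contour
    weighting; ``coeff`` exports raw coefficients).  Dropped columns are
    exact zero.  Levels give the ``percentile``-th percentile of the
    positive values (favorable) and the mirror percentile of the negative
    values (unfavorable) per field.
    """
    from . import molio

    if X.grid is None:
        raise ValueError("MifMatrix carries no grid for contour export")
    if len(model.coefficients) != X.X.shape[1]:
        raise ValueError("model and MifMatrix column counts differ")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sd = X.X.std(axis=0)
    col_values = model.coefficients * (sd if weighting == "stdev_coeff" else 1.0)
    volumes: dict[str, np.ndarray] = {}
    levels: dict[str, dict[str, float]] = {}
    for kind in dict.fromkeys(X.kinds.tolist()):
        full = np.zeros(X.grid.n_points)
        mask = X.kept_kinds == kind
        full[X.kept_indices[mask]] = col_values[mask]
        volumes[str(kind)] = X.grid.values_to_volume(full)
        pos = full[full > 0]
        neg = full[full < 0]
        levels[str(kind)] = {
            "positive": float(np.percentile(pos, percentile)) if len(pos) else 0.0,
            "negative": float(np.percentile(neg, 100.0 - percentile)) if len(neg) else 0.0,
        }
        path = out_dir / f"{basename}_{kind}.{ 'dx' if fmt == 'dx' else 'cube'}"
        if fmt == "dx":
            molio.write_dx(full, X.grid, path)
        else:
            molio.write_cube(full, X.grid, path)
    sidecar = {
        "weighting": weighting,
        "percentile": percentile,
        "levels": levels,
        "sign_convention": "positive = favorable for the probe, negative = unfavorable",
    }
    (out_dir / f"{basename}_levels.json").write_text(json.dumps(sidecar, indent=2))
    return ContourMap(volumes=volumes, levels=levels, weighting=weighting)
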