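"""Partial-least-squares QSAR regression of kcat/Km on site descriptors.

The response is the raw catalytic efficiency kcat/Km in M^-1 s^-1; the
design matrix holds position-specific descriptor values, where a
feature may span a single position (e.g. P10) or a pair of adjacent
positions (e.g. P2-P1), in which case the feature value is the sum of
the per-residue descriptor at the two member positions.

The fit is a NIPALS PLS1 on standardized predictors with the number of
latent components chosen by leave-one-out cross-validated r^2 (Xr^2);
with as many components as the predictor rank the fit coincides with
ordinary least squares, which the test suite uses as an oracle.  The
module also implements standardized-residual outlier exclusion with a
single refit, backward elimination under the Xr^2 > floor rule,
per-position delta-kcat/Km contribution profiles (pair partners
marginalized uniformly over the 20 residues), and additive subsequence
scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .binary_qsar import SelectionTrajectory
from .descriptors import (
    AMINO_ACIDS,
    MISSING,
    DescriptorTable,
    FeatureMatrix,
    SiteWindow,
)

__all__ = [
    "PlsFeature",
    "PlsQsarModel",
    "ContributionProfile",
    "design_matrix",
    "fit_pls",
    "loo_xr2",
    "exclude_outliers_and_refit",
    "backward_select_pls",
    "predict_kcat_km",
    "position_contribution",
    "score_subsequence",
    "evaluate_regression",
]

MODEL_FORMAT_VERSION = 1

#: (positions, descriptor id); positions is a 1- or 2-tuple of labels.
PlsFeature = tuple[tuple[str, ...], str]


def _as_feature(f) -> PlsFeature:
    positions, tid = f
    if isinstance(positions, str):
        positions = (positions,)
    return tuple(positions), tid


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def design_matrix(
    windows: Sequence[SiteWindow],
    features: Sequence[PlsFeature],
    tables: Mapping[str, DescriptorTable],
    response: Mapping[str, float] | pd.Series | None = None,
) -> FeatureMatrix:
    """Evaluate single- and paired-position features on windows.

    A paired feature sums the descriptor at both member positions.  A
    missing residue at any member position yields NaN (callers restrict
    to complete windows before fitting).
    """
    feats = [_as_feature(f) for f in features]
    cols = pd.MultiIndex.from_tuples(
        [("-".join(p), tid) for p, tid in feats],
        names=["position", "descriptor"],
    )
    data = np.empty((len(windows), len(feats)))
    for i, w in enumerate(windows):
        for j, (positions, tid) in enumerate(feats):
            table = tables[tid]
            v = 0.0
            for pos in positions:
                res = w.residues.get(pos, MISSING)
                if res is MISSING:
                    v = np.nan
                    break
                v += table.values[res]
            data[i, j] = v
    values = pd.DataFrame(data, index=[w.id for w in windows], columns=cols)
    resp = None
    if response is not None:
        resp = pd.Series(response).reindex(values.index)
    return FeatureMatrix(values=values, response=resp)


# ---------------------------------------------------------------------------
# NIPALS PLS1 core
# ---------------------------------------------------------------------------

def _nipals_pls1(X: np.ndarray, y: np.ndarray, k: int):
    """PLS1 regression coefficients (raw X units) with k components."""
    n, d = X.shape
    x_mean, y_mean = X.mean(axis=0), y.mean()
    x_std = X.std(axis=0, ddof=1)
    x_std[x_std == 0] = 1.0
    Xc = (X - x_mean) / x_std
    yc = y - y_mean
    W = np.zeros((d, k))
    P = np.zeros((d, k))
    q = np.zeros(k)
    Xr, yr = Xc.copy(), yc.copy()
    for a in range(k):
        w = Xr.T @ yr
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            k = a
            W, P, q = W[:, :k], P[:, :k], q[:k]
            break
        w /= norm
        t = Xr @ w
        tt = t @ t
        if tt < 1e-28:
            k = a
            W, P, q = W[:, :k], P[:, :k], q[:k]
            break
        p = (Xr.T @ t) / tt
        qa = (yr @ t) / tt
        Xr = Xr - np.outer(t, p)
        yr = yr - qa * t
        W[:, a], P[:, a], q[a] = w, p, qa
    if k == 0:
        raise ValueError("rank-deficient problem: zero usable components")
    beta_std = W @ np.linalg.solve(P.T @ W, q)
    coef = beta_std / x_std
    intercept = y_mean - x_mean @ coef
    return coef, float(intercept), k


def _effective_rank(X: np.ndarray) -> int:
    Z = X - X.mean(axis=0)
    s = np.linalg.svd(Z, compute_uv=False)
    if s.size == 0 or s[0] == 0:
        return 0
    return int(np.sum(s > s[0] * 1e-10))


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class PlsQsarModel:
    """A fitted (or literature-specified) PLS-QSAR efficiency model.

    Prediction is linear in raw descriptor values:
    ``kcat/Km = intercept + sum_k coefficient_k * x_k`` (M^-1 s^-1).
    A model can equally be constructed directly from published
    coefficients for contribution analysis without refitting.
    """

    features: list[PlsFeature]
    coefficients: np.ndarray
    intercept: float
    n_components: int = 0
    excluded_outliers: list[str] = field(default_factory=list)
    tables: dict[str, DescriptorTable] | None = None

    def __post_init__(self) -> None:
        self.features = [_as_feature(f) for f in self.features]
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.features) != len(self.coefficients):
            raise ValueError("features and coefficients differ in length")

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coefficients + self.intercept

    def to_json(self) -> str:
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "kind": "pls_qsar",
            "features": [[list(p), tid] for p, tid in self.features],
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "n_components": self.n_components,
            "excluded_outliers": list(self.excluded_outliers),
            "tables": None
            if self.tables is None
            else {
                tid: {"values": dict(t.values), "kind": t.kind,
                      "description": t.description}
                for tid, t in self.tables.items()
            },
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PlsQsarModel":
        doc = json.loads(text)
        if doc.get("kind") != "pls_qsar":
            raise ValueError("not a PLS-QSAR model document")
        tables = None
        if doc["tables"] is not None:
            tables = {
                tid: DescriptorTable(id=tid, values=spec["values"],
                                     kind=spec["kind"],
                                     description=spec.get("description", ""))
                for tid, spec in doc["tables"].items()
            }
        return cls(
            features=[(tuple(p), tid) for p, tid in doc["features"]],
            coefficients=np.array(doc["coefficients"]),
            intercept=doc["intercept"],
            n_components=doc["n_components"],
            excluded_outliers=doc["excluded_outliers"],
            tables=tables,
        )


@dataclass
class ContributionProfile:
    """Per-residue delta-kcat/Km at one position (intercept-free)."""

    position: str
    per_residue_delta: dict[str, float]

    @property
    def range(self) -> float:
        v = list(self.per_residue_delta.values())
        return max(v) - min(v)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_pls(
    matrix: FeatureMatrix,
    n_components: int | None = None,
    max_components: int = 8,
    tables: Mapping[str, DescriptorTable] | None = None,
) -> PlsQsarModel:
    """Fit the PLS-QSAR model, selecting components by LOO Xr^2.

    When ``n_components`` is None the component count maximizing the
    leave-one-out cross-validated r^2 is chosen, capped at
    ``min(max_components, rank)``.
    """
    X, y = _xy(matrix)
    rank = _effective_rank(X)
    if rank == 0:
        raise ValueError("rank-deficient problem: zero usable components")
    if n_components is None:
        cap = min(max_components, rank)
        best_k, best_xr2 = 1, -np.inf
        for k in range(1, cap + 1):
            xr2 = _loo_xr2_arrays(X, y, k)
            if xr2 > best_xr2:
                best_k, best_xr2 = k, xr2
        n_components = best_k
    coef, intercept, k = _nipals_pls1(X, y, n_components)
    return PlsQsarModel(
        features=[_col_to_feature(c) for c in matrix.values.columns],
        coefficients=coef,
        intercept=intercept,
        n_components=k,
        tables=None if tables is None else dict(tables),
    )


def _col_to_feature(col) -> PlsFeature:
    pos, tid = col
    return tuple(pos.split("-")), tid


def _xy(matrix: FeatureMatrix):
    if matrix.response is None:
        raise ValueError("matrix carries no kcat/Km response")
    X = matrix.values.to_numpy(dtype=float)
    y = matrix.response.to_numpy(dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing cells in predictors or response")
    if len(y) < X.shape[1] + 2:
        raise ValueError("need at least n_features + 2 rows")
    return X, y


def loo_xr2(matrix: FeatureMatrix, n_components: int) -> float:
    """Leave-one-out cross-validated r^2 of the PLS fit."""
    X, y = _xy(matrix)
    return _loo_xr2_arrays(X, y, n_components)


def _loo_xr2_arrays(X: np.ndarray, y: np.ndarray, k: int) -> float:
    n = len(y)
    pred = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            coef, icpt, _ = _nipals_pls1(X[mask], y[mask], k)
            pred[i] = X[i] @ coef + icpt
        except ValueError:
            pred[i] = y[mask].mean()
        mask[i] = True
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("zero-variance response")
    return float(1.0 - np.sum((y - pred) ** 2) / ss_tot)


def exclude_outliers_and_refit(
    model: PlsQsarModel,
    matrix: FeatureMatrix,
    z_threshold: float = 2.5,
    max_fraction: float = 0.2,
) -> PlsQsarModel:
    """Drop |standardized residual| > z rows and refit once.

    Residuals of the supplied model on the training matrix are
    standardized by their own standard deviation; rows beyond
    ``z_threshold`` are flagged, removed, and the model refit with the
    same component count.  Refuses (raises) when more than
    ``max_fraction`` of the rows would be dropped.
    """
    X, y = _xy(matrix)
    resid = y - model.predict(X)
    s = resid.std(ddof=1)
    if s == 0:
        return model
    flagged = np.abs(resid / s) > z_threshold
    ids = [matrix.values.index[i] for i in np.flatnonzero(flagged)]
    if not ids:
        return model
    if len(ids) > max_fraction * len(y):
        raise ValueError(
            f"{len(ids)} of {len(y)} rows flagged as outliers "
            f"(> {max_fraction:.0%}); refusing to refit"
        )
    keep = ~flagged
    sub = FeatureMatrix(
        values=matrix.values.loc[keep],
        response=matrix.response.loc[keep],
    )
    refit = fit_pls(sub, n_components=model.n_components, tables=model.tables)
    refit.excluded_outliers = ids
    return refit


def backward_select_pls(
    matrix: FeatureMatrix,
    floor: float = 0.6,
    n_components: int | None = None,
    max_components: int = 8,
) -> SelectionTrajectory:
    """Backward elimination under the LOO Xr^2 > floor rule.

    Mirrors the classifier's greedy elimination but scores each
    candidate feature set by leave-one-out cross-validated r^2 (with
    per-set component selection unless ``n_components`` pins it).
    """
    X, y = _xy(matrix)
    features = [tuple(c) for c in matrix.values.columns]
    if not features:
        raise ValueError("initial feature set is empty")

    def criterion(cols: list[int]) -> float:
        Xs = X[:, cols]
        rank = _effective_rank(Xs)
        if rank == 0:
            return -np.inf
        if n_components is not None:
            return _loo_xr2_arrays(Xs, y, min(n_components, rank))
        cap = min(max_components, rank)
        return max(_loo_xr2_arrays(Xs, y, k) for k in range(1, cap + 1))

    active = list(range(len(features)))
    steps = [(tuple(features[i] for i in active), criterion(active))]
    while len(active) > 1:
        best_val, best_drop = -np.inf, None
        for pos, _ in enumerate(active):
            trial = active[:pos] + active[pos + 1:]
            val = criterion(trial)
            if val > best_val:
                best_val, best_drop = val, pos
        active.pop(best_drop)
        steps.append((tuple(features[i] for i in active), best_val))

    above = [i for i, (_, v) in enumerate(steps) if v > floor]
    if above:
        return SelectionTrajectory(steps=steps, chosen_step=above[-1], floor_met=True)
    chosen = int(np.argmax([v for _, v in steps]))
    return SelectionTrajectory(steps=steps, chosen_step=chosen, floor_met=False)


# ---------------------------------------------------------------------------
# Prediction and contribution analysis
# ---------------------------------------------------------------------------

def _feature_value(
    feature: PlsFeature,
    tables: Mapping[str, DescriptorTable],
    resolve,
) -> float:
    """Evaluate one feature; ``resolve(pos)`` returns a residue or None.

    A position resolving to None contributes the table's 20-residue
    mean (uniform marginalization over the unknown partner/position).
    """
    positions, tid = feature
    table = tables[tid]
    v = 0.0
    for pos in positions:
        res = resolve(pos)
        v += table.values[res] if res is not None else table.mean()
    return v


def predict_kcat_km(
    model: PlsQsarModel,
    window: SiteWindow,
    tables: Mapping[str, DescriptorTable] | None = None,
) -> float:
    """Predicted kcat/Km (M^-1 s^-1) for a window.

    A missing residue at a single-position feature raises; a missing
    member of a paired feature is marginalized as the descriptor's
    20-residue average.
    """
    tables = tables or model.tables
    if tables is None:
        raise ValueError("descriptor tables required for prediction")
    total = model.intercept
    for coef, feature in zip(model.coefficients, model.features):
        positions, tid = feature

        def resolve(pos, _positions=positions):
            res = window.residues.get(pos, MISSING)
            if res is MISSING:
                if len(_positions) == 1:
                    raise ValueError(
                        f"window {window.id}: missing residue at {pos} for a "
                        "single-position feature"
                    )
                return None
            return res

        total += coef * _feature_value(feature, tables, resolve)
    return float(total)


def position_contribution(
    model: PlsQsarModel,
    position: str,
    tables: Mapping[str, DescriptorTable] | None = None,
) -> ContributionProfile:
    """Delta-kcat/Km per residue at one position, all else marginalized.

    For each residue the contributions of every model feature touching
    the position are summed, with paired-feature partner positions
    averaged uniformly over the 20 residues.  The profile is
    intercept-free; its max-min range summarizes how much the position
    can move the predicted efficiency.
    """
    tables = tables or model.tables
    if tables is None:
        raise ValueError("descriptor tables required")
    touching = [
        (c, f) for c, f in zip(model.coefficients, model.features)
        if position in f[0]
    ]
    if not touching:
        raise ValueError(f"position {position} not in the model")
    profile = {}
    for res in AMINO_ACIDS:
        total = 0.0
        for coef, feature in touching:
            total += coef * _feature_value(
                feature, tables,
                lambda pos: res if pos == position else None,
            )
        profile[res] = total
    return ContributionProfile(position=position, per_residue_delta=profile)


def score_subsequence(
    model: PlsQsarModel,
    residues: Mapping[str, str],
    positions: Sequence[str],
    tables: Mapping[str, DescriptorTable] | None = None,
) -> float:
    """Score a partial window over a position range (e.g. P3-P3').

    All in-range positions must be specified in ``residues``.  Feature
    positions outside the range -- whole features or pair partners --
    are replaced by the descriptor's 20-residue average, so scores of
    equal-range subsequences are directly comparable.
    """
    tables = tables or model.tables
    if tables is None:
        raise ValueError("descriptor tables required")
    in_range = set(positions)
    missing = in_range - set(residues)
    if missing:
        raise ValueError(f"unspecified in-range positions: {sorted(missing)}")
    if not any(set(f[0]) & in_range for f in model.features):
        raise ValueError("range excludes every model feature")
    total = model.intercept
    for coef, feature in zip(model.coefficients, model.features):
        total += coef * _feature_value(
            feature, tables,
            lambda pos: residues[pos] if pos in in_range else None,
        )
    return float(total)


def evaluate_regression(
    predictions: Sequence[float],
    measurements: Sequence[float],
) -> dict[str, float]:
    """Agreement between predicted and measured kcat/Km.

    Returns Pearson ``r``, the leave-one-out predicted correlation
    ``Xr`` of the predicted-on-measured least-squares line, and the
    line's ``slope``/``intercept`` (predicted = slope * measured +
    intercept).
    """
    yhat = np.asarray(predictions, dtype=float)
    y = np.asarray(measurements, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise ValueError("zero variance input")
    r = float(stats.pearsonr(y, yhat)[0])
    slope, intercept = np.polyfit(y, yhat, 1)
    # closed-form LOO for simple linear regression via leverages
    n = len(y)
    xc = y - y.mean()
    h = 1.0 / n + xc**2 / np.sum(xc**2)
    fitted = slope * y + intercept
    loo_pred = yhat - (yhat - fitted) / (1.0 - h)
    xr = float(stats.pearsonr(yhat, loo_pred)[0])
    return {"r": r, "Xr": xr, "slope": float(slope), "intercept": float(intercept)}
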