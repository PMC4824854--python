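"""Bayes-based binary QSAR classifier for cleavability.

The classifier follows the classical binary-QSAR construction: features
are z-scored, decorrelated by principal-component analysis, each
retained component is discretized into equal-width bins, and smoothed
class-conditional bin frequencies are combined under a
naive-independence assumption with the class prior through Bayes' rule,
yielding a cleavage probability in (0, 1).

On top of the model the module provides leave-one-out cross-validated
accuracy (XA), greedy backward variable elimination with the
"XA > floor with fewest descriptors" stopping rule, confusion-matrix
evaluation, reversed-sequence negative controls, whole-protein
scanning, and a P2 x P1 cooperativity count table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .descriptors import (
    MISSING,
    DescriptorTable,
    FeatureMatrix,
    Peptide,
    SiteWindow,
    SsInput,
    build_window,
    featurize,
)

__all__ = [
    "BinaryQsarModel",
    "PerformanceReport",
    "SelectionTrajectory",
    "fit_binary",
    "predict_probability",
    "loo_accuracy",
    "backward_select",
    "evaluate",
    "partial_dependence",
    "permutation_importance",
    "reverse_negatives",
    "scan_protein",
    "cooperativity_table",
]

MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class BinaryQsarModel:
    """A fitted binary-QSAR cleavability model.

    ``features`` are (position, descriptor id) pairs in training column
    order.  ``loadings`` holds the retained principal-component
    directions (one column per component) applied to z-scored features;
    ``bin_edges``/``log_p_pos``/``log_p_neg`` hold, per component, the
    histogram discretization and the log of the smoothed
    class-conditional bin probabilities.  ``cutoff`` is the response
    binarization value on the 0/1 coding of the training labels (the
    kcat/Km cut below which a sequence counts as uncleaved);
    ``threshold`` is the classification threshold on the posterior.
    """

    features: list[tuple[str, str]]
    mean: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray            # (n_features, n_components)
    bin_edges: list[np.ndarray]     # per component, bins + 1 edges
    log_p_pos: np.ndarray           # (n_components, bins)
    log_p_neg: np.ndarray
    prior: float
    n_components: int
    bins: int
    smoothing: float
    cutoff: float = 0.5
    threshold: float = 0.5
    tables: dict[str, DescriptorTable] | None = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Posterior P(cleaved | x) for raw feature rows ``X``."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if np.isnan(X).any():
            raise ValueError("incomplete window: missing feature values")
        Z = (X - self.mean) / self.scale
        T = Z @ self.loadings
        log_pos = np.full(len(X), np.log(self.prior))
        log_neg = np.full(len(X), np.log1p(-self.prior))
        for j in range(self.n_components):
            idx = np.searchsorted(self.bin_edges[j][1:-1], T[:, j], side="right")
            log_pos += self.log_p_pos[j, idx]
            log_neg += self.log_p_neg[j, idx]
        m = np.maximum(log_pos, log_neg)
        num = np.exp(log_pos - m)
        return num / (num + np.exp(log_neg - m))

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "kind": "binary_qsar",
            "features": [list(f) for f in self.features],
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "bin_edges": [e.tolist() for e in self.bin_edges],
            "log_p_pos": self.log_p_pos.tolist(),
            "log_p_neg": self.log_p_neg.tolist(),
            "prior": self.prior,
            "n_components": self.n_components,
            "bins": self.bins,
            "smoothing": self.smoothing,
            "cutoff": self.cutoff,
            "threshold": self.threshold,
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
    def from_json(cls, text: str) -> "BinaryQsarModel":
        doc = json.loads(text)
        if doc.get("kind") != "binary_qsar":
            raise ValueError("not a binary-QSAR model document")
        tables = None
        if doc["tables"] is not None:
            tables = {
                tid: DescriptorTable(id=tid, values=spec["values"],
                                     kind=spec["kind"],
                                     description=spec.get("description", ""))
                for tid, spec in doc["tables"].items()
            }
        return cls(
            features=[tuple(f) for f in doc["features"]],
            mean=np.array(doc["mean"]),
            scale=np.array(doc["scale"]),
            loadings=np.array(doc["loadings"]),
            bin_edges=[np.array(e) for e in doc["bin_edges"]],
            log_p_pos=np.array(doc["log_p_pos"]),
            log_p_neg=np.array(doc["log_p_neg"]),
            prior=doc["prior"],
            n_components=doc["n_components"],
            bins=doc["bins"],
            smoothing=doc["smoothing"],
            cutoff=doc["cutoff"],
            threshold=doc["threshold"],
            tables=tables,
        )


@dataclass(frozen=True)
class PerformanceReport:
    """Confusion-matrix counts and the five derived proportions."""

    TP: int
    FP: int
    TN: int
    FN: int
    threshold: float

    @property
    def sensitivity(self) -> float:
        return _ratio(self.TP, self.TP + self.FN)

    @property
    def specificity(self) -> float:
        return _ratio(self.TN, self.TN + self.FP)

    @property
    def ppv(self) -> float:
        return _ratio(self.TP, self.TP + self.FP)

    @property
    def npv(self) -> float:
        return _ratio(self.TN, self.TN + self.FN)

    @property
    def accuracy(self) -> float:
        return _ratio(self.TP + self.TN, self.TP + self.FP + self.TN + self.FN)


def _ratio(num: int, den: int) -> float:
    return float("nan") if den == 0 else num / den


@dataclass
class SelectionTrajectory:
    """Record of a backward-elimination run.

    ``steps`` lists (feature set, criterion value) with strictly
    decreasing set sizes; ``chosen_step`` indexes the selected model
    (smallest set whose criterion exceeds the floor).  ``floor_met`` is
    False when no step cleared the floor, in which case the
    best-criterion step is chosen instead.
    """

    steps: list[tuple[tuple[tuple[str, str], ...], float]]
    chosen_step: int
    floor_met: bool = True

    @property
    def chosen_features(self) -> tuple[tuple[str, str], ...]:
        return self.steps[self.chosen_step][0]

    @property
    def chosen_criterion(self) -> float:
        return self.steps[self.chosen_step][1]


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _fit_arrays(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int | str = "auto",
    bins: int = 10,
    smoothing: float = 0.5,
    var_explained: float = 0.98,
):
    """Core fit on plain arrays; returns the model pieces.

    Kept free of pandas so that leave-one-out and backward selection
    can call it thousands of times cheaply.
    """
    n, d = X.shape
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing cells")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present in the training data")
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale

    cov = (Z.T @ Z) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    for j in range(evecs.shape[1]):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    total = evals.sum()
    if n_components == "auto":
        if total <= 0:
            k = 1
        else:
            frac = np.cumsum(evals) / total
            k = int(np.searchsorted(frac, var_explained) + 1)
            k = min(k, d)
    else:
        k = int(n_components)
        if k < 1 or k > d:
            raise ValueError(f"n_components must be in [1, {d}]")
    if n <= k:
        raise ValueError("fewer rows than retained components")
    loadings = evecs[:, :k]
    T = Z @ loadings

    pos = y == 1
    n_pos = int(pos.sum())
    prior = n_pos / n
    edges_list, logp, logn = [], np.empty((k, bins)), np.empty((k, bins))
    for j in range(k):
        lo, hi = T[:, j].min(), T[:, j].max()
        if hi <= lo:
            hi = lo + 1.0
        edges = np.linspace(lo, hi, bins + 1)
        idx = np.searchsorted(edges[1:-1], T[:, j], side="right")
        cp = np.bincount(idx[pos], minlength=bins).astype(float)
        cn = np.bincount(idx[~pos], minlength=bins).astype(float)
        logp[j] = np.log((cp + smoothing) / (n_pos + smoothing * bins))
        logn[j] = np.log((cn + smoothing) / ((n - n_pos) + smoothing * bins))
        edges_list.append(edges)
    return mean, scale, loadings, edges_list, logp, logn, prior, k


def fit_binary(
    matrix: FeatureMatrix,
    n_components: int | str = "auto",
    bins: int = 10,
    smoothing: float = 0.5,
    var_explained: float = 0.98,
    cutoff: float = 0.5,
    threshold: float = 0.5,
    tables: Mapping[str, DescriptorTable] | None = None,
) -> BinaryQsarModel:
    """Fit the Bayes/PCA/histogram cleavability classifier.

    Labels are taken from ``matrix.labels`` (already 0/1) or, when a
    response is attached instead, binarized at ``cutoff`` (the kcat/Km
    value separating cleaved from uncleaved on the 0/1 coding).
    ``n_components="auto"`` retains components explaining at least
    ``var_explained`` of the variance.  ``smoothing`` is the
    pseudo-count added per histogram bin.
    """
    y = _labels_from(matrix, cutoff)
    X = matrix.values.to_numpy(dtype=float)
    mean, scale, loadings, edges, logp, logn, prior, k = _fit_arrays(
        X, y, n_components, bins, smoothing, var_explained
    )
    return BinaryQsarModel(
        features=[tuple(c) for c in matrix.values.columns],
        mean=mean, scale=scale, loadings=loadings,
        bin_edges=edges, log_p_pos=logp, log_p_neg=logn,
        prior=prior, n_components=k, bins=bins, smoothing=smoothing,
        cutoff=cutoff, threshold=threshold,
        tables=None if tables is None else dict(tables),
    )


def _labels_from(matrix: FeatureMatrix, cutoff: float) -> np.ndarray:
    if matrix.labels is not None:
        return matrix.labels.to_numpy(dtype=int)
    if matrix.response is not None:
        return (matrix.response.to_numpy(dtype=float) > cutoff).astype(int)
    raise ValueError("matrix carries neither labels nor a response")


def predict_probability(
    model: BinaryQsarModel,
    window: SiteWindow,
    ss: SsInput | None = None,
) -> float:
    """Cleavage probability for one window under a fitted model.

    Every model feature must be resolvable; a missing residue at a
    model position raises (incomplete window).  The model must carry
    its descriptor tables (``tables``) to featurize the window.
    """
    if model.tables is None:
        raise ValueError("model carries no descriptor tables")
    x = _window_vector(model, window, ss)
    return float(model.predict_proba(x)[0])


def _window_vector(
    model: BinaryQsarModel, window: SiteWindow, ss: SsInput | None
) -> np.ndarray:
    x = np.empty(len(model.features))
    for i, (pos, tid) in enumerate(model.features):
        table = model.tables[tid]
        if table.residue_keyed:
            res = window.residues.get(pos, MISSING)
            if res is MISSING:
                raise ValueError(
                    f"incomplete window {window.id}: missing residue at {pos}"
                )
            x[i] = table.values[res]
        else:
            if ss is None or (window.id, pos) not in ss.get(tid, {}):
                raise ValueError(
                    f"incomplete window {window.id}: no secondary-structure "
                    f"probability for {tid!r} at {pos}"
                )
            x[i] = ss[tid][(window.id, pos)]
    return x


# ---------------------------------------------------------------------------
# Cross-validation and feature selection
# ---------------------------------------------------------------------------

def loo_accuracy(
    matrix: FeatureMatrix,
    cutoff: float = 0.5,
    threshold: float = 0.5,
    **fit_config,
) -> float:
    """Leave-one-out cross-validated accuracy (XA).

    Each fold refits the full model (preprocessing, PCA, histograms) on
    the remaining rows and scores the held-out row at ``threshold``.
    When a fold degenerates to a single class, the held-out row is
    predicted from the class prior alone.
    """
    y = _labels_from(matrix, cutoff)
    X = matrix.values.to_numpy(dtype=float)
    return _loo_accuracy_arrays(X, y, threshold=threshold, **fit_config)


def _loo_accuracy_arrays(
    X: np.ndarray,
    y: np.ndarray,
    threshold: float = 0.5,
    **fit_config,
) -> float:
    n = len(y)
    if n < 10:
        raise ValueError("leave-one-out needs n >= 10")
    correct = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        Xi, yi = X[mask], y[mask]
        if len(np.unique(yi)) < 2:
            p = float(yi.mean())
        else:
            pieces = _fit_arrays(Xi, yi, **fit_config)
            p = _predict_from_pieces(pieces, X[i][None, :])[0]
        correct += int((p >= threshold) == bool(y[i]))
        mask[i] = True
    return correct / n


def _predict_from_pieces(pieces, X: np.ndarray) -> np.ndarray:
    mean, scale, loadings, edges, logp, logn, prior, k = pieces
    T = ((X - mean) / scale) @ loadings
    lp = np.full(len(X), np.log(prior))
    ln = np.full(len(X), np.log1p(-prior))
    for j in range(k):
        idx = np.searchsorted(edges[j][1:-1], T[:, j], side="right")
        lp += logp[j, idx]
        ln += logn[j, idx]
    m = np.maximum(lp, ln)
    num = np.exp(lp - m)
    return num / (num + np.exp(ln - m))


def backward_select(
    matrix: FeatureMatrix,
    floor: float = 0.7,
    criterion: Callable[[np.ndarray, np.ndarray], float] | None = None,
    cutoff: float = 0.5,
    threshold: float = 0.5,
    **fit_config,
) -> SelectionTrajectory:
    """Greedy backward variable elimination under the XA criterion.

    Starting from the full feature set, each step removes the feature
    whose removal maximizes the criterion (default: leave-one-out
    accuracy); ties go to the higher criterion, then to the earliest
    feature in column order.  The chosen model is the smallest feature
    set whose criterion exceeds ``floor``; when no step clears the
    floor the best-criterion step is returned flagged
    ``floor_met=False``.
    """
    y = _labels_from(matrix, cutoff)
    X = matrix.values.to_numpy(dtype=float)
    features = [tuple(c) for c in matrix.values.columns]
    if not features:
        raise ValueError("initial feature set is empty")
    if criterion is None:
        def criterion(Xs, ys):
            return _loo_accuracy_arrays(Xs, ys, threshold=threshold, **fit_config)

    active = list(range(len(features)))
    steps = []
    steps.append((tuple(features[i] for i in active), criterion(X[:, active], y)))
    while len(active) > 1:
        best_val, best_drop = -np.inf, None
        for pos_in_active, _ in enumerate(active):
            trial = active[:pos_in_active] + active[pos_in_active + 1:]
            val = criterion(X[:, trial], y)
            if val > best_val:
                best_val, best_drop = val, pos_in_active
        active.pop(best_drop)
        steps.append((tuple(features[i] for i in active), best_val))

    above = [i for i, (_, v) in enumerate(steps) if v > floor]
    if above:
        # set sizes strictly decrease with the step index, so the last
        # step above the floor is the smallest qualifying feature set
        return SelectionTrajectory(steps=steps, chosen_step=above[-1], floor_met=True)
    chosen = int(np.argmax([v for _, v in steps]))
    return SelectionTrajectory(steps=steps, chosen_step=chosen, floor_met=False)


# ---------------------------------------------------------------------------
# Evaluation and application
# ---------------------------------------------------------------------------

def evaluate(
    probabilities: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
) -> PerformanceReport:
    """Confusion counts and derived proportions at a threshold."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.size == 0:
        raise ValueError("empty input")
    if p.shape != y.shape:
        raise ValueError("probabilities and labels differ in length")
    called = p >= threshold
    return PerformanceReport(
        TP=int(np.sum(called & (y == 1))),
        FP=int(np.sum(called & (y == 0))),
        TN=int(np.sum(~called & (y == 0))),
        FN=int(np.sum(~called & (y == 1))),
        threshold=threshold,
    )


def partial_dependence(
    model: BinaryQsarModel,
    matrix: FeatureMatrix,
    feature: tuple[str, str],
    grid: Sequence[float],
) -> pd.DataFrame:
    """Average cleavage probability as one feature sweeps a grid.

    For each grid value the feature column is clamped to it and the
    posterior is averaged over the rows of ``matrix`` — i.e. over the
    observed joint distribution of the remaining features.
    """
    try:
        j = model.features.index(tuple(feature))
    except ValueError:
        raise ValueError(f"feature {feature!r} not in the model") from None
    X = matrix.values[list(model.features)].to_numpy(dtype=float)
    rows = []
    for v in grid:
        Xv = X.copy()
        Xv[:, j] = v
        rows.append((float(v), float(model.predict_proba(Xv).mean())))
    return pd.DataFrame(rows, columns=["value", "probability"])


def permutation_importance(
    model: BinaryQsarModel,
    matrix: FeatureMatrix,
    n_repeats: int = 20,
    threshold: float = 0.5,
    seed: int = 0,
) -> pd.Series:
    """Accuracy drop when one feature column is shuffled.

    An interpretability statistic for fitted models: the mean decrease
    in classification accuracy over ``n_repeats`` shuffles of each
    feature column, larger meaning more influential.
    """
    y = _labels_from(matrix, model.cutoff)
    X = matrix.values.to_numpy(dtype=float)
    base = np.mean((model.predict_proba(X) >= threshold) == (y == 1))
    rng = np.random.default_rng(seed)
    drops = {}
    for j, feat in enumerate(model.features):
        accs = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            accs.append(
                np.mean((model.predict_proba(Xp) >= threshold) == (y == 1)))
        drops[feat] = float(base - np.mean(accs))
    return pd.Series(drops, name="importance")


def reverse_negatives(windows: Sequence[SiteWindow]) -> list[SiteWindow]:
    """Reversed-sequence negative controls.

    Reversing a peptide and re-centering the bond mirrors the window:
    the residue at Pk moves to Pk' and vice versa.  Applying the
    operation twice returns the original windows.
    """
    out = []
    for w in windows:
        residues = {}
        for lab, res in w.residues.items():
            mirror = lab[:-1] if lab.endswith("p") else lab + "p"
            residues[mirror] = res
        out.append(
            SiteWindow(
                peptide_id=f"{w.peptide_id}-rev",
                bond_after=w.bond_after,
                residues=residues,
                enzyme=w.enzyme,
                status="uncleaved",
            )
        )
    return out


def scan_protein(
    model: BinaryQsarModel,
    sequence: str,
    protein_id: str = "protein",
    threshold: float = 0.95,
    ss: SsInput | None = None,
    flank: int = 10,
) -> pd.DataFrame:
    """Slide the model along a protein and score every scorable bond.

    Returns a DataFrame with one row per bond (``bond_after``, ``p1``,
    ``probability``, ``called``, ``scored``); bonds whose window lacks
    a residue at a model position are reported unscored (NaN
    probability) rather than silently dropped.
    """
    needed = sorted(
        {pos for pos, tid in model.features
         if model.tables is None or model.tables[tid].residue_keyed}
    )
    peptide = Peptide(id=protein_id, sequence=sequence)
    rows = []
    for bond in range(1, len(sequence)):
        w = build_window(peptide, bond, flank=flank)
        if not w.is_complete(needed):
            rows.append((bond, sequence[bond - 1], np.nan, False, False))
            continue
        p = predict_probability(model, w, ss=ss)
        rows.append((bond, sequence[bond - 1], p, p >= threshold, True))
    return pd.DataFrame(
        rows, columns=["bond_after", "p1", "probability", "called", "scored"]
    )


def cooperativity_table(
    windows: Sequence[SiteWindow],
    labels: Mapping[str, int],
    p2_set: Sequence[str],
    p1_set: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cleaved/total counts per P2 x P1 residue pair.

    A purely descriptive contingency count over labelled windows -- no
    model involved.  Returns ``(cleaved, total)`` DataFrames indexed by
    P2 residue with P1 residues as columns.
    """
    cleaved = pd.DataFrame(0, index=list(p2_set), columns=list(p1_set))
    total = cleaved.copy()
    for w in windows:
        r2, r1 = w.residues.get("P2"), w.residues.get("P1")
        if r2 in p2_set and r1 in p1_set:
            total.loc[r2, r1] += 1
            cleaved.loc[r2, r1] += int(labels[w.id])
    return cleaved, total
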