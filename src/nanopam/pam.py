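"""Nearest-shrunken-centroid (PAM) training and prediction.

Training shrinks per-class centroids toward the overall centroid by
soft-thresholding standardized centroid differences; prediction assigns a
sample to the class with the smallest standardized squared distance to
its shrunken centroid, penalized by the class prior.  The model also
reports the Pearson correlation of the sample with each shrunken centroid
and a symmetric 0-1 score of relative basal affinity:

    basal_score = (1 + r_basal - r_luminal) / 2, clipped to [0, 1].

All quantities needed to reproduce predictions are serialized to JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PamModel",
    "SubtypeCall",
    "train_pam",
    "predict",
    "predict_matrix",
    "predict_labels",
    "choose_delta",
    "classification_error",
    "ClassificationError",
    "round_half_away",
]

MODEL_SCHEMA_VERSION = 1

_TIE_RTOL = 1e-12


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of printed percentages)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)


@dataclass
class PamModel:
    """Serializable nearest-shrunken-centroid classifier."""

    classes: list[str]
    genes: list[str]
    overall_centroid: pd.Series  # x̄_j
    centroids: pd.DataFrame  # x̄_kj, genes x classes
    shrunken_centroids: pd.DataFrame  # x̄'_kj, genes x classes
    s: pd.Series  # pooled within-class deviation s_j
    s0: float  # fudge factor (median of s_j)
    delta: float  # shrinkage amount
    m: dict[str, float]  # per-class offset sqrt(1/n_k - 1/n)
    priors: dict[str, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.priors.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"priors must sum to 1, got {total}")
        if (self.s < 0).any() or self.s0 < 0:
            raise ValueError("dispersions must be non-negative")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "classes": self.classes,
            "genes": self.genes,
            "overall_centroid": self.overall_centroid.tolist(),
            "centroids": {k: self.centroids[k].tolist() for k in self.classes},
            "shrunken_centroids": {k: self.shrunken_centroids[k].tolist() for k in self.classes},
            "s": self.s.tolist(),
            "s0": self.s0,
            "delta": self.delta,
            "m": self.m,
            "priors": self.priors,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "PamModel":
        version = doc.get("schema_version")
        if version != MODEL_SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema version {version!r}")
        genes = list(doc["genes"])
        idx = pd.Index(genes, name="gene")
        return cls(
            classes=list(doc["classes"]),
            genes=genes,
            overall_centroid=pd.Series(doc["overall_centroid"], index=idx),
            centroids=pd.DataFrame(doc["centroids"], index=idx)[list(doc["classes"])],
            shrunken_centroids=pd.DataFrame(doc["shrunken_centroids"], index=idx)[
                list(doc["classes"])
            ],
            s=pd.Series(doc["s"], index=idx),
            s0=float(doc["s0"]),
            delta=float(doc["delta"]),
            m={k: float(v) for k, v in doc["m"].items()},
            priors={k: float(v) for k, v in doc["priors"].items()},
            provenance=dict(doc.get("provenance", {})),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PamModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class SubtypeCall:
    """Per-sample classifier output."""

    sample_id: str
    label: str
    deltas: dict[str, float]  # discriminant scores δ_k (smaller = closer)
    posteriors: dict[str, float]
    correlations: dict[str, float]  # Pearson r to each shrunken centroid
    basal_score: float | None
    tie: bool = False
    degenerate_correlation: bool = False

    def as_row(self) -> dict:
        row = {"sample": self.sample_id, "label": self.label}
        for k, v in self.deltas.items():
            row[f"delta_{k}"] = v
        for k, v in self.posteriors.items():
            row[f"p_{k}"] = v
        for k, v in self.correlations.items():
            row[f"r_{k}"] = v
        row["basal_score"] = self.basal_score
        row["tie"] = self.tie
        return row


def _as_frame(X, labels) -> tuple[pd.DataFrame, pd.Series]:
    X = pd.DataFrame(X)
    if isinstance(labels, pd.Series) and set(labels.index) == set(X.columns):
        labels = labels.reindex(X.columns)
    else:
        labels = list(labels)
        if len(labels) != X.shape[1]:
            raise ValueError(f"{len(labels)} labels for {X.shape[1]} samples")
        labels = pd.Series(labels, index=X.columns)
    return X, labels.astype(str)


def train_pam(
    X: pd.DataFrame,
    labels: Sequence[str] | pd.Series,
    delta: float = 0.0,
    priors: Literal["empirical", "uniform"] | Mapping[str, float] = "empirical",
    provenance: Mapping | None = None,
) -> PamModel:
    """Train a nearest-shrunken-centroid model.

    Parameters
    ----------
    X:
        Log-expression matrix, genes x samples.
    labels:
        Class label per sample (column-aligned).  Each class needs >= 2
        samples.
    delta:
        Soft-threshold shrinkage amount (>= 0); 0 keeps class means.
    priors:
        ``"empirical"`` (class frequencies), ``"uniform"``, or an explicit
        mapping.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    X, labels = _as_frame(X, labels)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError(f"need >= 2 classes, got {classes}")
    counts = labels.value_counts()
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"classes with < 2 samples: {small.to_dict()}")

    n = X.shape[1]
    n_k = {k: int(counts[k]) for k in classes}
    overall = X.mean(axis=1)
    centroids = pd.DataFrame(
        {k: X.loc[:, (labels == k).to_numpy()].mean(axis=1) for k in classes}
    )

    # pooled within-class variance, divisor n - K
    ss = np.zeros(X.shape[0])
    for k in classes:
        block = X.loc[:, (labels == k).to_numpy()]
        ss += ((block.sub(centroids[k], axis=0)) ** 2).sum(axis=1).to_numpy()
    s = pd.Series(np.sqrt(ss / (n - len(classes))), index=X.index)
    s0 = float(np.median(s.to_numpy()))
    if s0 == 0.0:
        # noiseless degenerate limit (every gene has zero pooled dispersion):
        # a tiny uniform fudge keeps the discriminant finite while preserving
        # its argmin (nearest class mean under the common scaling)
        s0 = max(1e-6 * float(s.mean()), 1e-6)

    m = {k: float(np.sqrt(1.0 / n_k[k] - 1.0 / n)) for k in classes}

    denom_base = (s + s0).to_numpy()
    shrunken = {}
    for k in classes:
        denom = m[k] * denom_base
        diff = (centroids[k] - overall).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
        if np.any((denom == 0) & (diff != 0)):
            raise ValueError("zero pooled dispersion with nonzero centroid difference")
        d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
        shrunken[k] = overall + m[k] * (s + s0) * d_shrunk
    shrunken_centroids = pd.DataFrame(shrunken)

    if priors == "empirical":
        prior_map = {k: n_k[k] / n for k in classes}
    elif priors == "uniform":
        prior_map = {k: 1.0 / len(classes) for k in classes}
    else:
        prior_map = {k: float(priors[k]) for k in classes}
        total = sum(prior_map.values())
        prior_map = {k: v / total for k, v in prior_map.items()}

    prov = dict(provenance or {})
    prov.setdefault("n_per_class", n_k)
    prov.setdefault("n_samples", n)

    return PamModel(
        classes=classes,
        genes=list(X.index),
        overall_centroid=overall,
        centroids=centroids,
        shrunken_centroids=shrunken_centroids,
        s=s,
        s0=s0,
        delta=float(delta),
        m=m,
        priors=prior_map,
        provenance=prov,
    )


def _align_vector(model: PamModel, x: pd.Series, impute_missing: bool) -> pd.Series:
    x = pd.Series(x)
    missing = [g for g in model.genes if g not in x.index]
    if missing:
        if not impute_missing:
            raise ValueError(f"input is missing model genes: {missing}")
        warnings.warn(
            f"imputing {len(missing)} missing genes from the overall centroid: {missing}",
            stacklevel=3,
        )
        x = pd.concat([x, model.overall_centroid[missing]])
    return x[model.genes].astype(float)


def _discriminants(model: PamModel, X: np.ndarray) -> np.ndarray:
    """delta_k(x) for columns of X; returns (K, n_samples)."""
    scale = (model.s + model.s0).to_numpy()[:, None]
    out = np.empty((len(model.classes), X.shape[1]))
    for i, k in enumerate(model.classes):
        resid = (X - model.shrunken_centroids[k].to_numpy()[:, None]) / scale
        out[i] = (resid**2).sum(axis=0) - 2.0 * np.log(model.priors[k])
    return out


def _resolve_label(model: PamModel, deltas: np.ndarray) -> tuple[str, bool]:
    """argmin with deterministic tie rule: larger prior, then later label."""
    best = deltas.min()
    tied = np.flatnonzero(np.abs(deltas - best) <= _TIE_RTOL * max(1.0, abs(best)))
    if len(tied) == 1:
        return model.classes[tied[0]], False
    candidates = sorted(
        (model.classes[i] for i in tied),
        key=lambda k: (model.priors[k], k),
        reverse=True,
    )
    return candidates[0], True


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return np.nan
    return float((xc * yc).sum() / denom)


def predict(
    model: PamModel, x: pd.Series, sample_id: str = "sample", impute_missing: bool = False
) -> SubtypeCall:
    """Classify one expression vector; the call depends only on (model, x)."""
    vec = _align_vector(model, x, impute_missing).to_numpy()[:, None]
    deltas = _discriminants(model, vec)[:, 0]
    label, tie = _resolve_label(model, deltas)

    shifted = -0.5 * (deltas - deltas.min())
    w = np.exp(shifted)
    posteriors = w / w.sum()

    degenerate = False
    correlations = {}
    for i, k in enumerate(model.classes):
        r = _pearson(vec[:, 0], model.shrunken_centroids[k].to_numpy())
        if np.isnan(r):
            degenerate = True
            r = 0.0
        correlations[k] = r
    if degenerate:
        warnings.warn(f"{sample_id}: zero-variance profile, correlations set to 0", stacklevel=2)

    basal_score = None
    if {"basal", "luminal"} <= set(model.classes):
        basal_score = float(
            np.clip((1.0 + correlations["basal"] - correlations["luminal"]) / 2.0, 0.0, 1.0)
        )

    return SubtypeCall(
        sample_id=sample_id,
        label=label,
        deltas={k: float(d) for k, d in zip(model.classes, deltas)},
        posteriors={k: float(p) for k, p in zip(model.classes, posteriors)},
        correlations=correlations,
        basal_score=basal_score,
        tie=tie,
        degenerate_correlation=degenerate,
    )


def predict_matrix(
    model: PamModel, X: pd.DataFrame, impute_missing: bool = False
) -> list[SubtypeCall]:
    """Classify every column of ``X``; identical to per-sample calls."""
    return [predict(model, X[s], sample_id=str(s), impute_missing=impute_missing) for s in X.columns]


def predict_labels(model: PamModel, X: pd.DataFrame) -> pd.Series:
    """Fast label-only batch prediction (used by the resampling loops)."""
    missing = [g for g in model.genes if g not in X.index]
    if missing:
        raise ValueError(f"input is missing model genes: {missing}")
    arr = X.loc[model.genes].to_numpy(dtype=float)
    deltas = _discriminants(model, arr)
    labels = [_resolve_label(model, deltas[:, j])[0] for j in range(arr.shape[1])]
    return pd.Series(labels, index=X.columns, name="label")


def _stratified_folds(labels: pd.Series, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Per-class shuffled round-robin assignment; every fold sees each class
    when possible (folds is capped at the smallest class size)."""
    counts = labels.value_counts()
    folds = int(min(folds, counts.min()))
    if folds < 2:
        raise ValueError("not enough samples per class for cross-validation")
    assignment = np.empty(len(labels), dtype=int)
    for k in counts.index:
        idx = np.flatnonzero((labels == k).to_numpy())
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    return [np.flatnonzero(assignment == f) for f in range(folds)]


def choose_delta(
    X: pd.DataFrame,
    labels: Sequence[str] | pd.Series,
    grid: Sequence[float],
    folds: int = 10,
    seed: int | None = None,
    priors: Literal["empirical", "uniform"] = "empirical",
) -> tuple[float, pd.DataFrame]:
    """Pick the shrinkage by stratified K-fold CV.

    Returns the largest delta attaining the minimum CV error (fewest
    genes) and the full error curve.
    """
    grid = sorted(set(float(d) for d in grid))
    if not grid:
        raise ValueError("empty delta grid")
    X, labels = _as_frame(X, labels)
    rng = np.random.default_rng(seed)
    fold_indices = _stratified_folds(labels, folds, rng)

    errors = np.zeros(len(grid))
    total = 0
    per_fold = []
    for test_idx in fold_indices:
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[test_idx] = True
        X_train, y_train = X.loc[:, ~mask], labels[~mask]
        X_test, y_test = X.loc[:, mask], labels[mask]
        fold_err = []
        for i, d in enumerate(grid):
            model = train_pam(X_train, y_train, delta=d, priors=priors)
            pred = predict_labels(model, X_test)
            wrong = int((pred.to_numpy() != y_test.to_numpy()).sum())
            errors[i] += wrong
            fold_err.append(wrong)
        total += len(test_idx)
        per_fold.append(fold_err)

    curve = pd.DataFrame({"delta": grid, "cv_error_rate": errors / total})
    best = curve["cv_error_rate"].min()
    delta_star = float(curve.loc[curve["cv_error_rate"] <= best, "delta"].max())
    return delta_star, curve


@dataclass(frozen=True)
class ClassificationError:
    errors: int
    n: int

    @property
    def rate(self) -> float:
        """Misclassification rate in percent."""
        return 100.0 * self.errors / self.n

    def percent(self, decimals: int = 0) -> float:
        """Printed-style rate: round half away from zero."""
        return round_half_away(self.rate, decimals)


def classification_error(calls: Sequence[str], truth: Sequence[str]) -> ClassificationError:
    """Count discordant calls against the truth labels."""
    calls = list(calls)
    truth = list(truth)
    if len(calls) != len(truth):
        raise ValueError(f"length mismatch: {len(calls)} calls vs {len(truth)} truth")
    if not calls:
        raise ValueError("empty input")
    errors = sum(1 for a, b in zip(calls, truth) if a != b)
    return ClassificationError(errors=errors, n=len(calls))
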