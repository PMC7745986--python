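"""Classifier evaluation machinery.

Monte Carlo cross-validation of the centroid classifier, McNemar
concordance between paired classifiers, replicate coefficient of
variance, Pearson cross-platform correlation, contingency-table
enrichment tests, and average-linkage cluster ordering with a centered
correlation distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from nanopam.pam import predict_labels, round_half_away, train_pam

__all__ = [
    "MonteCarloResult",
    "monte_carlo_cv",
    "McNemarResult",
    "mcnemar_test",
    "CoVResult",
    "coefficient_of_variance",
    "PearsonResult",
    "pearson_correlation",
    "EnrichmentResult",
    "enrichment_test",
    "ProportionResult",
    "subtype_proportion",
    "ClusterResult",
    "cluster_order",
]

#: exact binomial McNemar below this many discordant pairs, chi-square above.
MCNEMAR_EXACT_CUTOFF = 25


@dataclass
class MonteCarloResult:
    """Outcome of repeated random train/test splitting."""

    iterations: int
    train_frac: float
    per_iteration_error: np.ndarray  # percent, one entry per iteration
    confusion: pd.DataFrame  # true x predicted, row-normalized percentages
    error_estimate: float  # mean per-iteration error, percent
    seed: int | None
    redraws: int  # splits rejected because a class was (nearly) absent

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_estimate <= 100.0:
            raise ValueError("error estimate outside [0, 100]")
        sums = self.confusion.sum(axis=1)
        if not np.allclose(sums, 100.0):
            raise ValueError("confusion rows must sum to 100")

    @property
    def error_se(self) -> float:
        """Standard error of the estimate over iterations (percent)."""
        return float(self.per_iteration_error.std(ddof=1) / np.sqrt(self.iterations))


def monte_carlo_cv(
    X: pd.DataFrame,
    labels: Sequence[str] | pd.Series,
    train_frac: float = 2.0 / 3.0,
    iterations: int = 10_000,
    delta: float = 0.0,
    seed: int | None = None,
    priors: Literal["empirical", "uniform"] = "empirical",
) -> MonteCarloResult:
    """Estimate expected classification error by Monte Carlo splitting.

    Each iteration assigns ``round(train_frac * n)`` samples uniformly at
    random to a training matrix, trains the centroid classifier on it, and
    classifies the held-out complement against the supplied labels.
    Splits are simple random (not stratified); draws leaving a class with
    fewer than the 2 training samples needed to pool variances are
    rejected, redrawn, and counted.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    X = pd.DataFrame(X)
    labels = pd.Series(np.asarray(labels, dtype=object), index=X.columns).astype(str)
    n = X.shape[1]
    if n < 6:
        raise ValueError("need at least 6 samples")
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    train_size = int(round(train_frac * n))
    if not 0 < train_size < n:
        raise ValueError("train fraction leaves an empty train or test set")

    rng = np.random.default_rng(seed)
    label_arr = labels.to_numpy()
    per_iter = np.empty(iterations)
    confusion_counts = pd.DataFrame(0, index=classes, columns=classes, dtype=np.int64)
    redraws = 0

    for it in range(iterations):
        while True:
            train_idx = rng.choice(n, size=train_size, replace=False)
            counts = pd.Series(label_arr[train_idx]).value_counts()
            if len(counts) == len(classes) and counts.min() >= 2:
                break
            redraws += 1
        mask = np.zeros(n, dtype=bool)
        mask[train_idx] = True
        model = train_pam(X.loc[:, mask], labels[mask], delta=delta, priors=priors)
        pred = predict_labels(model, X.loc[:, ~mask])
        truth = label_arr[~mask]
        per_iter[it] = 100.0 * np.mean(pred.to_numpy() != truth)
        for t, p in zip(truth, pred):
            confusion_counts.loc[t, p] += 1

    row_sums = confusion_counts.sum(axis=1)
    confusion = confusion_counts.div(row_sums, axis=0) * 100.0

    return MonteCarloResult(
        iterations=iterations,
        train_frac=train_frac,
        per_iteration_error=per_iter,
        confusion=confusion,
        error_estimate=float(per_iter.mean()),
        seed=seed,
        redraws=redraws,
    )


@dataclass(frozen=True)
class McNemarResult:
    b: int  # A correct, B wrong
    c: int  # A wrong, B correct
    statistic: float
    p_value: float
    method: str  # "exact" | "chi2" | "degenerate"
    degenerate: bool = False


def mcnemar_test(
    calls_a: Sequence[str], calls_b: Sequence[str], truth: Sequence[str]
) -> McNemarResult:
    """Paired concordance test on discordant error counts.

    Exact two-sided binomial ``p = min(1, 2 P(Bin(b+c, 1/2) <= min(b,c)))``
    when ``b + c < 25``; otherwise the continuity-corrected chi-square
    ``(|b - c| - 1)^2 / (b + c)`` on 1 df.
    """
    a, b_, t = (np.asarray(v, dtype=object) for v in (calls_a, calls_b, truth))
    if not len(a) == len(b_) == len(t):
        raise ValueError("call and truth vectors must be aligned")
    a_correct = a == t
    b_correct = b_ == t
    b = int(np.sum(a_correct & ~b_correct))
    c = int(np.sum(~a_correct & b_correct))
    n_disc = b + c
    if n_disc == 0:
        return McNemarResult(b, c, 0.0, 1.0, "degenerate", degenerate=True)
    if n_disc < MCNEMAR_EXACT_CUTOFF:
        p = min(1.0, 2.0 * float(sps.binom.cdf(min(b, c), n_disc, 0.5)))
        return McNemarResult(b, c, float(min(b, c)), p, "exact")
    stat = (abs(b - c) - 1) ** 2 / n_disc
    p = float(sps.chi2.sf(stat, df=1))
    return McNemarResult(b, c, float(stat), p, "chi2")


@dataclass
class CoVResult:
    per_gene: pd.Series  # sd(ddof=1) / mean; NaN where mean <= 0
    median: float
    max: float
    undefined: list[str] = field(default_factory=list)


def coefficient_of_variance(replicates: pd.DataFrame) -> CoVResult:
    """Per-gene coefficient of variance across technical replicates."""
    if replicates.shape[1] < 2:
        raise ValueError("need >= 2 replicates")
    means = replicates.mean(axis=1)
    sds = replicates.std(axis=1, ddof=1)
    cov = sds / means
    undefined = list(cov.index[means <= 0])
    cov[means <= 0] = np.nan
    valid = cov.dropna()
    return CoVResult(
        per_gene=cov,
        median=float(valid.median()) if len(valid) else np.nan,
        max=float(valid.max()) if len(valid) else np.nan,
        undefined=undefined,
    )


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p_value: float
    n: int
    degenerate: bool = False


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Product-moment correlation with the two-sided t-transform p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need >= 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return PearsonResult(np.nan, np.nan, len(x), degenerate=True)
    res = sps.pearsonr(x, y)
    return PearsonResult(float(res.statistic), float(res.pvalue), len(x))


@dataclass(frozen=True)
class EnrichmentResult:
    statistic: float  # odds ratio (fisher) or Pearson chi-square statistic
    p_value: float
    method: str


def enrichment_test(
    table: Sequence[Sequence[int]] | pd.DataFrame,
    method: Literal["fisher", "chi2"] = "fisher",
) -> EnrichmentResult:
    """Contingency-table association test.

    ``fisher``: two-sided exact test on a 2x2 table (p sums hypergeometric
    probabilities of tables no more likely than the observed one).
    ``chi2``: Pearson chi-square without continuity correction on r x c.
    """
    arr = np.asarray(pd.DataFrame(table).to_numpy(), dtype=float)
    if (arr < 0).any():
        raise ValueError("negative cell count")
    if method == "fisher":
        if arr.shape != (2, 2):
            raise ValueError("fisher requires a 2x2 table")
        odds, p = sps.fisher_exact(arr, alternative="two-sided")
        return EnrichmentResult(float(odds), float(p), "fisher")
    if method == "chi2":
        res = sps.chi2_contingency(arr, correction=False)
        return EnrichmentResult(float(res.statistic), float(res.pvalue), "chi2")
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class ProportionResult:
    count: int
    total: int

    @property
    def rate(self) -> float:
        return 100.0 * self.count / self.total

    def percent(self, decimals: int = 0) -> float:
        return round_half_away(self.rate, decimals)


def subtype_proportion(count: int, total: int) -> ProportionResult:
    """Share of a row total, in percent, with printed-style rounding."""
    if total <= 0:
        raise ValueError("total must be positive")
    if count < 0 or count > total:
        raise ValueError("count must lie in [0, total]")
    return ProportionResult(int(count), int(total))


@dataclass
class ClusterResult:
    order: list  # leaf order (labels)
    linkage: np.ndarray  # scipy linkage matrix
    labels: list


def cluster_order(X: pd.DataFrame, axis: Literal["genes", "samples"] = "samples") -> ClusterResult:
    """Average-linkage (UPGMA) ordering under centered-correlation distance.

    Item profiles are rows (``axis="genes"``) or columns (``axis="samples"``);
    the dissimilarity is 1 minus the Pearson correlation between profiles.
    Constant profiles have undefined correlation and are an error.
    """
    profiles = X if axis == "genes" else X.T
    if profiles.shape[0] < 2:
        raise ValueError("need >= 2 items to cluster")
    arr = profiles.to_numpy(dtype=float)
    constant = profiles.index[np.ptp(arr, axis=1) == 0].tolist()
    if constant:
        raise ValueError(f"constant profiles, correlation distance undefined: {constant}")
    dist = pdist(arr, metric="correlation")  # 1 - centered Pearson
    dist = np.clip(dist, 0.0, None)  # guard tiny negative float error
    link = hierarchy.linkage(dist, method="average")
    leaves = hierarchy.leaves_list(link)
    labels = list(profiles.index)
    return ClusterResult(order=[labels[i] for i in leaves], linkage=link, labels=labels)
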