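"""Count-to-expression normalization chain.

Per sample, independently of every other sample:

1. floor negative-control counts at 1 read and take their geometric mean
   — the background ``B_s``;
2. set every housekeeping / endogenous count strictly below ``B_s`` to 0;
3. exclude the sample if any housekeeping value is 0 after thresholding;
4. scale endogenous counts by ``F_s = 100 / geomean(housekeeping)`` so the
   housekeeping geometric mean becomes exactly 100;
5. log-transform (default log2 with pseudocount 1).

Because each step uses only within-sample quantities, a sample's
normalized expression never depends on which other samples were run with
it — the property that makes the downstream classifier single-sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nanopam.io import CountMatrix, ProbePanel

__all__ = [
    "QCReport",
    "NormalizedMatrix",
    "geometric_mean",
    "background_threshold",
    "qc_filter",
    "housekeeping_normalize",
    "log_transform",
    "median_center",
    "normalize_counts",
]


@dataclass
class QCReport:
    """Per-sample audit trail of the normalization chain.

    ``table`` is indexed by sample id with columns:

    - ``background``: geometric mean of floored negative-control counts (B_s)
    - ``hk_geomean``: geometric mean of thresholded housekeeping counts (H_s)
    - ``norm_factor``: 100 / H_s (NaN for excluded samples)
    - ``excluded``: bool
    - ``reason``: exclusion reason or empty string
    """

    table: pd.DataFrame

    @property
    def excluded_samples(self) -> list[str]:
        return list(self.table.index[self.table["excluded"]])

    @property
    def retained_samples(self) -> list[str]:
        return list(self.table.index[~self.table["excluded"]])

    def validate(self) -> None:
        retained = self.table[~self.table["excluded"]]
        if (retained["norm_factor"] <= 0).any():
            raise ValueError("retained sample with non-positive normalization factor")
        if (self.table["background"] < 1).any():
            raise ValueError("background below the read floor of 1")


@dataclass
class NormalizedMatrix:
    """Housekeeping-scaled endogenous expression with a paired log layer."""

    linear: pd.DataFrame  # endogenous probes x retained samples
    log: pd.DataFrame | None = None
    log_base: float | None = None
    pseudocount: float | None = None
    #: housekeeping counts (thresholded) scaled by the same per-sample factor;
    #: their per-sample geometric mean is 100 by construction.
    housekeeping_scaled: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def samples(self) -> list[str]:
        return list(self.linear.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.linear.index)


def geometric_mean(values, floor: float = 1.0) -> float:
    """exp(mean(log(max(v, floor)))) — with the default floor, zeros count as 1."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of empty input")
    if floor < 0:
        raise ValueError("floor must be >= 0")
    arr = np.maximum(arr, floor)
    if (arr <= 0).any():
        raise ValueError("geometric mean undefined for non-positive values with floor 0")
    return float(np.exp(np.mean(np.log(arr))))


def background_threshold(
    matrix: CountMatrix, panel: ProbePanel
) -> tuple[pd.DataFrame, pd.Series]:
    """Zero out sub-background counts, per sample.

    Returns the thresholded matrix (float frame over all panel probes) and
    the per-sample background ``B_s`` (geometric mean of negative-control
    counts floored at 1).  Values strictly below ``B_s`` are set to 0;
    values equal to ``B_s`` are kept.  Idempotent.
    """
    panel.require_normalizable()
    matrix.check_panel(panel)
    counts = matrix.counts.loc[panel.probes].astype(float)
    neg = counts.loc[panel.negative]
    backgrounds = pd.Series(
        {s: geometric_mean(neg[s], floor=1.0) for s in counts.columns}, name="background"
    )
    out = counts.copy()
    target = panel.housekeeping + panel.endogenous
    sub = out.loc[target]
    out.loc[target] = sub.where(sub.ge(backgrounds, axis=1), 0.0)
    return out, backgrounds


def qc_filter(
    thresholded: pd.DataFrame, panel: ProbePanel, backgrounds: pd.Series | None = None
) -> tuple[pd.DataFrame, QCReport]:
    """Drop samples whose housekeeping signal fell below background.

    A sample is excluded iff any housekeeping probe is 0 after
    thresholding.  Excluded samples stay in the report (never silently
    dropped); all samples excluded is an error.
    """
    hk = thresholded.loc[panel.housekeeping]
    failed = hk.eq(0).any(axis=0)
    reasons = []
    for s in thresholded.columns:
        if failed[s]:
            low = hk.index[hk[s] == 0].tolist()
            reasons.append(f"housekeeping below background: {','.join(low)}")
        else:
            reasons.append("")
    report = QCReport(
        pd.DataFrame(
            {
                "background": backgrounds if backgrounds is not None else np.nan,
                "hk_geomean": np.nan,
                "norm_factor": np.nan,
                "excluded": failed,
                "reason": reasons,
            },
            index=thresholded.columns,
        )
    )
    if failed.all():
        raise ValueError(
            "all samples excluded by housekeeping QC:\n" + report.table.to_string()
        )
    retained = thresholded.loc[:, ~failed]
    return retained, report


def housekeeping_normalize(
    thresholded: pd.DataFrame, panel: ProbePanel, report: QCReport | None = None
) -> tuple[NormalizedMatrix, QCReport]:
    """Scale endogenous counts by ``F_s = 100 / geomean(housekeeping)``.

    Expects QC-filtered input (every housekeeping value positive); a zero
    housekeeping geometric mean is a defensive error.
    """
    hk = thresholded.loc[panel.housekeeping]
    hk_geomean = pd.Series(
        {s: geometric_mean(hk[s], floor=1.0) for s in thresholded.columns}, name="hk_geomean"
    )
    if (hk.eq(0).any(axis=0)).any() or (hk_geomean <= 0).any():
        raise ValueError("housekeeping signal at/below zero: run qc_filter first")
    factors = 100.0 / hk_geomean
    linear = thresholded.loc[panel.endogenous].mul(factors, axis=1)
    hk_scaled = hk.mul(factors, axis=1)
    if report is None:
        report = QCReport(
            pd.DataFrame(
                {
                    "background": np.nan,
                    "hk_geomean": np.nan,
                    "norm_factor": np.nan,
                    "excluded": False,
                    "reason": "",
                },
                index=thresholded.columns,
            )
        )
    report.table.loc[thresholded.columns, "hk_geomean"] = hk_geomean
    report.table.loc[thresholded.columns, "norm_factor"] = factors
    return NormalizedMatrix(linear=linear, housekeeping_scaled=hk_scaled), report


def log_transform(
    values: pd.DataFrame, base: float = 2, pseudocount: float = 1.0
) -> pd.DataFrame:
    """x -> log_base(x + pseudocount); with pseudocount 1, zeros map to 0."""
    if base not in (2, np.e, 10):
        raise ValueError("base must be one of 2, e, 10")
    arr = values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("log transform requires non-negative values")
    if pseudocount <= 0 and (arr == 0).any():
        raise ValueError("pseudocount <= 0 with zeros present")
    return pd.DataFrame(
        np.log(arr + pseudocount) / np.log(base), index=values.index, columns=values.columns
    )


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract the per-gene (row-wise, across samples) median. Idempotent."""
    if matrix.shape[1] < 1:
        raise ValueError("median centering needs at least one sample")
    return matrix.sub(matrix.median(axis=1), axis=0)


def normalize_counts(
    matrix: CountMatrix,
    panel: ProbePanel,
    log_base: float = 2,
    pseudocount: float = 1.0,
) -> tuple[NormalizedMatrix, QCReport]:
    """Run the full chain: threshold, QC-filter, scale to 100, log transform."""
    thresholded, backgrounds = background_threshold(matrix, panel)
    retained, report = qc_filter(thresholded, panel, backgrounds)
    normalized, report = housekeeping_normalize(retained, panel, report)
    normalized.log = log_transform(normalized.linear, base=log_base, pseudocount=pseudocount)
    normalized.log_base = log_base
    normalized.pseudocount = pseudocount
    report.validate()
    return normalized, report
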