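"""Synthetic nCounter cohorts with known ground truth.

Generates two-subtype cohorts with the geometry of the bundled codeset:
endogenous genes split into basal-high / luminal-high / neutral blocks
with a subtype-specific log2 mean shift, stable housekeeping probes,
per-sample lane scale factors, Poisson count noise on a log-normal rate,
per-sample negative-control background, and a correlated paired
pseudo-RNAseq log-expression layer for label-transfer experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from nanopam.io import CountMatrix, ProbePanel
from nanopam.normalization import normalize_counts
from nanopam.pam import predict_labels, train_pam
from nanopam.panel import HOUSEKEEPING_GENES

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_technical_replicates",
    "LabelTransferFixture",
    "make_label_transfer_fixture",
    "label_transfer_disagreement",
]


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator; ``validate`` lists every violation."""

    n_samples: int = 60
    basal_fraction: float = 0.5
    n_basal_high: int = 20
    n_luminal_high: int = 20
    n_neutral: int = 7
    n_housekeeping: int = 4
    n_negative: int = 8
    baseline_log2_mean: float | Sequence[float] = 8.0
    housekeeping_log2_mean: float = 10.0
    effect_size: float = 2.0  # subtype log2 shift, split +/- effect_size/2
    biological_sd: float = 1.0
    lane_scale_range: tuple[float, float] = (0.7, 1.4)
    background_mean: float = 4.0  # Poisson rate of negative-control probes
    technical_sd: float = 0.1
    platform_correlation: float = 0.9  # per-gene rho of the paired layer
    race_basal_odds_ratio: float = 1.0  # 1.0 = null enrichment
    seed: int = 0

    @property
    def n_endogenous(self) -> int:
        return self.n_basal_high + self.n_luminal_high + self.n_neutral

    def violations(self) -> list[str]:
        v = []
        if self.n_samples < 2:
            v.append("n_samples must be >= 2")
        if not 0.0 < self.basal_fraction < 1.0:
            v.append("basal_fraction must be in (0, 1)")
        if min(self.n_basal_high, self.n_luminal_high) < 1:
            v.append("need >= 1 basal-high and >= 1 luminal-high gene")
        if self.n_neutral < 0:
            v.append("n_neutral must be >= 0")
        if self.n_housekeeping < 1 or self.n_negative < 1:
            v.append("need >= 1 housekeeping and >= 1 negative probe")
        if self.effect_size < 0:
            v.append("effect_size must be >= 0")
        if self.biological_sd < 0 or self.technical_sd < 0:
            v.append("noise sds must be >= 0")
        lo, hi = self.lane_scale_range
        if not 0 < lo <= hi:
            v.append("lane_scale_range must satisfy 0 < lo <= hi")
        if self.background_mean < 0:
            v.append("background_mean must be >= 0")
        if not -1.0 <= self.platform_correlation <= 1.0:
            v.append("platform_correlation must be in [-1, 1]")
        if self.race_basal_odds_ratio <= 0:
            v.append("race_basal_odds_ratio must be > 0")
        if not np.isscalar(self.baseline_log2_mean):
            if len(self.baseline_log2_mean) != self.n_endogenous:
                v.append("per-gene baseline_log2_mean length must equal n_endogenous")
        return v

    def validate(self) -> None:
        v = self.violations()
        if v:
            raise ValueError("invalid simulation config: " + "; ".join(v))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "lane_scale_range" in doc:
            doc["lane_scale_range"] = tuple(doc["lane_scale_range"])
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["lane_scale_range"] = list(doc["lane_scale_range"])
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


@dataclass
class SimulatedCohort:
    counts: CountMatrix  # all probes x samples, raw nCounter-like counts
    panel: ProbePanel
    paired_log: pd.DataFrame  # pseudo-RNAseq log layer, endogenous x samples
    truth: pd.Series  # true subtype per sample
    metadata: pd.DataFrame
    true_log2: pd.DataFrame = field(repr=False, default=None)
    lane_scale: pd.Series = field(repr=False, default=None)
    config: SimulationConfig = None


def _panel_for(config: SimulationConfig) -> ProbePanel:
    basal = [f"BAS{i + 1:02d}" for i in range(config.n_basal_high)]
    luminal = [f"LUM{i + 1:02d}" for i in range(config.n_luminal_high)]
    neutral = [f"NEU{i + 1:02d}" for i in range(config.n_neutral)]
    if config.n_housekeeping == len(HOUSEKEEPING_GENES):
        hk = list(HOUSEKEEPING_GENES)
    else:
        hk = [f"HK{i + 1:02d}" for i in range(config.n_housekeeping)]
    neg = [f"NEG_{i + 1:02d}" for i in range(config.n_negative)]
    return ProbePanel.from_records(
        [(g, "endogenous", "basal") for g in basal]
        + [(g, "endogenous", "luminal") for g in luminal]
        + [(g, "endogenous", "none") for g in neutral]
        + [(g, "housekeeping", "none") for g in hk]
        + [(p, "negative", "none") for p in neg]
    )


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw one cohort; bit-identical for identical configs (same seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel = _panel_for(config)
    n = config.n_samples
    samples = [f"S{i + 1:03d}" for i in range(n)]

    labels = np.where(rng.random(n) < config.basal_fraction, "basal", "luminal")
    truth = pd.Series(labels, index=samples, name="true_subtype")

    endo = panel.endogenous
    node = np.array([panel.subtype_node(g) for g in endo])
    # block sign per (gene, sample): +1 where block matches subtype
    sign = np.zeros((len(endo), n))
    is_basal = labels == "basal"
    sign[node == "basal"] = np.where(is_basal, 1.0, -1.0)
    sign[node == "luminal"] = np.where(is_basal, -1.0, 1.0)

    baseline = (
        np.full(len(endo), float(config.baseline_log2_mean))
        if np.isscalar(config.baseline_log2_mean)
        else np.asarray(config.baseline_log2_mean, dtype=float)
    )
    true_log2 = (
        baseline[:, None]
        + sign * (config.effect_size / 2.0)
        + rng.normal(0.0, config.biological_sd, size=(len(endo), n))
    )

    lo, hi = config.lane_scale_range
    scale = rng.uniform(lo, hi, size=n)

    endo_counts = rng.poisson(scale[None, :] * np.exp2(true_log2))
    hk_rate = scale[None, :] * np.exp2(config.housekeeping_log2_mean)
    hk_counts = rng.poisson(np.broadcast_to(hk_rate, (config.n_housekeeping, n)))
    neg_counts = rng.poisson(config.background_mean, size=(config.n_negative, n))

    counts = pd.DataFrame(
        np.vstack([endo_counts, hk_counts, neg_counts]),
        index=pd.Index(endo + panel.housekeeping + panel.negative, name="probe"),
        columns=samples,
    )

    # paired pseudo-RNAseq layer: per-gene standardized truth mixed with
    # independent noise so corr(true, paired) ~= rho per gene
    sd = true_log2.std(axis=1, ddof=0)
    mean = true_log2.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd[:, None] > 0, (true_log2 - mean[:, None]) / np.where(sd > 0, sd, 1.0)[:, None], 0.0)
    rho = config.platform_correlation
    noise = rng.normal(0.0, 1.0, size=z.shape)
    paired = rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * noise
    paired_log = pd.DataFrame(paired, index=pd.Index(endo, name="gene"), columns=samples)

    # metadata: independent of subtype unless an odds ratio is requested
    p_luminal_black = 0.3
    odds = config.race_basal_odds_ratio * p_luminal_black / (1 - p_luminal_black)
    p_basal_black = odds / (1 + odds)
    p_black = np.where(is_basal, p_basal_black, p_luminal_black)
    race = np.where(rng.random(n) < p_black, "black", "white")
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    smoking = rng.choice(["never", "former", "current"], size=n)
    t_stage = rng.choice(["T1", "T2", "T3", "T4"], size=n)
    metadata = pd.DataFrame(
        {
            "cohort": "synthetic",
            "race": race,
            "sex": sex,
            "smoking": smoking,
            "t_stage": t_stage,
            "true_subtype": labels,
        },
        index=pd.Index(samples, name="sample_id"),
    )

    return SimulatedCohort(
        counts=CountMatrix(counts),
        panel=panel,
        paired_log=paired_log,
        truth=truth,
        metadata=metadata,
        true_log2=pd.DataFrame(true_log2, index=pd.Index(endo, name="gene"), columns=samples),
        lane_scale=pd.Series(scale, index=samples, name="lane_scale"),
        config=config,
    )


def simulate_technical_replicates(
    base_counts: pd.Series, technical_sd: float, k: int, seed: int | None = None
) -> CountMatrix:
    """k technical replicates: Poisson around the base rate jittered on log2.

    Replicate counts for probe j are Poisson(2 ** (log2 base_j + N(0, sd))).
    """
    if k < 2:
        raise ValueError("need k >= 2 replicates")
    if technical_sd < 0:
        raise ValueError("technical_sd must be >= 0")
    rng = np.random.default_rng(seed)
    base = np.asarray(base_counts, dtype=float)
    if (base < 0).any():
        raise ValueError("base counts must be non-negative")
    rates = base[:, None] * np.exp2(rng.normal(0.0, technical_sd, size=(len(base), k)))
    counts = rng.poisson(rates)
    return CountMatrix(
        pd.DataFrame(
            counts,
            index=pd.Index(base_counts.index, name="probe"),
            columns=[f"rep{i + 1:02d}" for i in range(k)],
        )
    )


@dataclass
class LabelTransferFixture:
    """In-silico two-platform workflow: platform A supplies 'true' calls."""

    platform_a: pd.DataFrame  # median-centered log expression, genes x samples
    calls_a: pd.Series  # classifier calls on platform A (the supervising labels)
    platform_b_counts: CountMatrix  # raw nCounter-like counts for retraining
    panel: ProbePanel
    truth: pd.Series


def make_label_transfer_fixture(config: SimulationConfig) -> LabelTransferFixture:
    """Emulate parallel profiling: train on platform A, label everything,
    hand platform-B counts over for de novo retraining."""
    if config.platform_correlation <= 0:
        warnings.warn("platform_correlation <= 0: platform A carries no signal", stacklevel=2)
    cohort = simulate_cohort(config)
    centered = cohort.paired_log.sub(cohort.paired_log.median(axis=1), axis=0)
    model_a = train_pam(centered, cohort.truth, delta=0.0)
    calls_a = predict_labels(model_a, centered)
    return LabelTransferFixture(
        platform_a=centered,
        calls_a=calls_a,
        platform_b_counts=cohort.counts,
        panel=cohort.panel,
        truth=cohort.truth,
    )


def label_transfer_disagreement(
    fixture: LabelTransferFixture, delta: float = 0.0
) -> tuple[float, int]:
    """Retrain on platform B against platform-A calls; return the percent
    of samples where the retrained classifier disagrees with those calls."""
    normalized, report = normalize_counts(fixture.platform_b_counts, fixture.panel)
    retained = normalized.log.columns
    supervising = fixture.calls_a[retained]
    model_b = train_pam(normalized.log, supervising, delta=delta)
    calls_b = predict_labels(model_b, normalized.log)
    disagree = float(np.mean(calls_b.to_numpy() != supervising.to_numpy()) * 100.0)
    return disagree, len(retained)
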