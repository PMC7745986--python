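"""Readers/writers for nCounter data and the shared data model.

Covers the RCC single-sample raw format, delimited probe x sample count
tables, panel definitions (YAML or TSV) and sample metadata tables.  All
count values are non-negative integers by contract; fractional input is
rejected rather than rounded.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

PROBE_CLASSES = ("endogenous", "housekeeping", "negative", "positive")
SUBTYPE_NODES = ("basal", "luminal", "none")

#: RCC CodeClass -> panel probe class.  Matching is case-insensitive and
#: tolerant of the "Endogenous1" style suffixes some instrument versions emit.
_CODECLASS_MAP = {
    "endogenous": "endogenous",
    "housekeeping": "housekeeping",
    "negative": "negative",
    "positive": "positive",
}

METADATA_VOCABULARIES: dict[str, tuple[str, ...]] = {
    "race": ("black", "white", "other", "unknown"),
    "sex": ("male", "female", "unknown"),
    "smoking": ("never", "former", "current", "unknown"),
    "t_stage": ("T0", "Ta", "Tis", "T1", "T2", "T3", "T4", "unknown"),
    "true_subtype": ("basal", "luminal"),
}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class PanelError(ValueError):
    """Raised when a probe panel violates its invariants."""


@dataclass(frozen=True)
class ProbePanel:
    """Probe panel: maps each probe to a class and optional subtype node.

    Parameters
    ----------
    table:
        DataFrame indexed by probe name with columns ``probe_class``
        (one of {endogenous, housekeeping, negative, positive}) and
        ``subtype_node`` (one of {basal, luminal, none}).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        tbl = self.table
        if not {"probe_class", "subtype_node"} <= set(tbl.columns):
            raise PanelError("panel table needs 'probe_class' and 'subtype_node' columns")
        if tbl.index.duplicated().any():
            dups = tbl.index[tbl.index.duplicated()].unique().tolist()
            raise PanelError(f"duplicate probe names in panel: {dups}")
        bad = set(tbl["probe_class"]) - set(PROBE_CLASSES)
        if bad:
            raise PanelError(f"unknown probe classes: {sorted(bad)}")
        bad = set(tbl["subtype_node"]) - set(SUBTYPE_NODES)
        if bad:
            raise PanelError(f"unknown subtype nodes: {sorted(bad)}")

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str]] | Iterable[Mapping[str, str]]
    ) -> "ProbePanel":
        rows = []
        for rec in records:
            if isinstance(rec, Mapping):
                rows.append((rec["probe"], rec["class"], rec.get("subtype_node", "none")))
            else:
                rows.append(tuple(rec))
        tbl = pd.DataFrame(rows, columns=["probe", "probe_class", "subtype_node"])
        return cls(tbl.set_index("probe"))

    # -- convenience views -------------------------------------------------
    @property
    def probes(self) -> list[str]:
        return list(self.table.index)

    def probes_of_class(self, probe_class: str) -> list[str]:
        if probe_class not in PROBE_CLASSES:
            raise PanelError(f"unknown probe class {probe_class!r}")
        return list(self.table.index[self.table["probe_class"] == probe_class])

    @property
    def endogenous(self) -> list[str]:
        return self.probes_of_class("endogenous")

    @property
    def housekeeping(self) -> list[str]:
        return self.probes_of_class("housekeeping")

    @property
    def negative(self) -> list[str]:
        return self.probes_of_class("negative")

    def subtype_node(self, probe: str) -> str:
        return str(self.table.at[probe, "subtype_node"])

    def require_normalizable(self) -> None:
        """Check the invariants needed by the normalization chain."""
        if not self.negative:
            raise PanelError("panel has no negative-control probes")
        if not self.housekeeping:
            raise PanelError("panel has no housekeeping probes")

    # -- serialisation -----------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProbePanel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "probes" not in doc:
            raise FormatError(f"{path}: panel YAML must contain a top-level 'probes' list")
        return cls.from_records(doc["probes"])

    def to_yaml(self, path: str | Path) -> None:
        probes = [
            {"probe": name, "class": row["probe_class"], "subtype_node": row["subtype_node"]}
            for name, row in self.table.iterrows()
        ]
        with open(path, "w") as fh:
            yaml.safe_dump({"probes": probes}, fh, sort_keys=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProbePanel":
        tbl = pd.read_csv(path, sep="\t", dtype=str)
        required = {"probe", "class"}
        if not required <= set(tbl.columns):
            raise FormatError(f"{path}: panel TSV needs columns {sorted(required)}")
        if "subtype_node" not in tbl.columns:
            tbl["subtype_node"] = "none"
        tbl["subtype_node"] = tbl["subtype_node"].fillna("none")
        return cls.from_records(tbl[["probe", "class", "subtype_node"]].itertuples(index=False))

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.rename(columns={"probe_class": "class"}).reset_index(names="probe")
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "ProbePanel":
        path = Path(path)
        if path.suffix.lower() in {".yaml", ".yml"}:
            return cls.from_yaml(path)
        return cls.from_tsv(path)

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ProbePanel) and self.table.equals(other.table)


@dataclass(frozen=True)
class CountMatrix:
    """Probes x samples matrix of non-negative integer barcode counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe rows: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise FormatError("counts must be integers; fractional values are rejected")
            object.__setattr__(self, "counts", df.astype(np.int64))
        if values.size and (self.counts.to_numpy() < 0).any():
            raise FormatError("counts must be non-negative")

    @property
    def probes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample(self, sample_id: str) -> pd.Series:
        return self.counts[sample_id]

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)].copy())

    def check_panel(self, panel: ProbePanel) -> None:
        missing = set(panel.probes) - set(self.probes)
        if missing:
            raise PanelError(f"count matrix is missing panel probes: {sorted(missing)}")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountMatrix) and self.counts.equals(other.counts)


@dataclass(frozen=True)
class RccSample:
    """One parsed RCC file: a single-sample count slice plus lane attributes."""

    sample_id: str
    counts: CountMatrix
    probe_classes: pd.Series
    lane_attributes: dict = field(default_factory=dict)


_SECTION_RE = re.compile(r"^<\s*(/?)\s*([^<>]+?)\s*>$")


def _split_sections(text: str) -> dict[str, list[str]]:
    """Split RCC text into {lower-cased section name: payload lines}."""
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for raw in text.splitlines():
        line = raw.rstrip("\r\n")
        m = _SECTION_RE.match(line.strip())
        if m:
            closing, name = m.groups()
            current = None if closing else name.strip().lower()
            if current is not None:
                sections.setdefault(current, [])
            continue
        if current is not None and line.strip():
            sections[current].append(line)
    return sections


def read_rcc(path: str | Path) -> RccSample:
    """Parse a single-sample RCC file.

    Probe classes are inferred from the CodeClass column; unknown sections
    are ignored and both CRLF and LF line endings are accepted.

    Raises
    ------
    FormatError
        If the code-summary section is missing, lacks the required columns,
        or contains a non-integer count.
    """
    path = Path(path)
    text = path.read_text()
    sections = _split_sections(text)
    if "code_summary" not in sections:
        raise FormatError(f"{path}: no Code_Summary section")

    lane_attributes: dict[str, str] = {}
    sample_attributes: dict[str, str] = {}
    for sec in ("header", "sample_attributes", "lane_attributes"):
        for line in sections.get(sec, []):
            key, _, value = line.partition(",")
            if not key:
                continue
            if sec == "sample_attributes":
                sample_attributes[key.strip()] = value.strip()
            else:
                lane_attributes[key.strip()] = value.strip()

    lines = sections["code_summary"]
    header = [h.strip() for h in lines[0].split(",")]
    required = {"CodeClass", "Name", "Count"}
    if not required <= set(header):
        raise FormatError(f"{path}: Code_Summary needs columns {sorted(required)}, got {header}")
    icls, iname, icount = header.index("CodeClass"), header.index("Name"), header.index("Count")

    names, classes, counts = [], [], []
    for line in lines[1:]:
        fields = [f.strip() for f in line.split(",")]
        if len(fields) < len(header):
            raise FormatError(f"{path}: short Code_Summary row: {line!r}")
        raw_class = fields[icls].lower()
        probe_class = next(
            (v for k, v in _CODECLASS_MAP.items() if raw_class.startswith(k)), None
        )
        if probe_class is None:
            continue  # SpikeIn / Binding / other instrument classes: pass over
        try:
            count = int(fields[icount])
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer count {fields[icount]!r}") from exc
        names.append(fields[iname])
        classes.append(probe_class)
        counts.append(count)

    sample_id = sample_attributes.get("ID") or path.stem
    lane_attributes = {**sample_attributes, **{k: v for k, v in lane_attributes.items() if k != "ID"}}
    frame = pd.DataFrame({sample_id: counts}, index=pd.Index(names, name="probe"))
    return RccSample(
        sample_id=sample_id,
        counts=CountMatrix(frame),
        probe_classes=pd.Series(classes, index=names, name="probe_class"),
        lane_attributes=lane_attributes,
    )


def combine_rcc(samples: Sequence[RccSample], panel: ProbePanel | None = None) -> tuple[CountMatrix, ProbePanel]:
    """Column-bind parsed RCC samples into one CountMatrix.

    When ``panel`` is given it is authoritative for probe classes; conflicts
    with the RCC CodeClass annotations are logged as warnings.  Otherwise a
    panel is inferred from the RCC annotations of the first sample.
    """
    if not samples:
        raise ValueError("no RCC samples to combine")
    frames = [s.counts.counts for s in samples]
    merged = pd.concat(frames, axis=1)
    if merged.isna().any().any():
        raise FormatError("RCC files do not share a common probe set")
    matrix = CountMatrix(merged)
    if panel is None:
        first = samples[0]
        panel = ProbePanel.from_records(
            (probe, cls, "none") for probe, cls in first.probe_classes.items()
        )
    else:
        for s in samples:
            common = [p for p in s.probe_classes.index if p in panel.table.index]
            rcc_cls = s.probe_classes.loc[common]
            panel_cls = panel.table.loc[common, "probe_class"]
            conflicts = rcc_cls[rcc_cls != panel_cls]
            for probe, cls in conflicts.items():
                warnings.warn(
                    f"{s.sample_id}: probe {probe} annotated {cls} in RCC but "
                    f"{panel_cls[probe]} in panel; panel wins",
                    stacklevel=2,
                )
    return matrix, panel


def read_count_table(
    path: str | Path, panel: ProbePanel | None = None, sep: str | None = None
) -> CountMatrix:
    """Read a delimited probe x sample count table.

    Probes are matched to ``panel`` by name and reordered to panel order;
    probes absent from the panel trigger a warning and are dropped.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "probe"
    matrix = CountMatrix(df)
    if panel is not None:
        unmatched = [p for p in matrix.probes if p not in panel.table.index]
        if unmatched:
            warnings.warn(f"{path}: probes not in panel (dropped): {unmatched}", stacklevel=2)
        matrix.check_panel(panel)
        matrix = CountMatrix(df.loc[panel.probes].copy())
    return matrix


def write_count_table(matrix: CountMatrix, path: str | Path, sep: str = "\t") -> None:
    matrix.counts.to_csv(path, sep=sep)


def read_metadata(path: str | Path, strict: bool = True) -> pd.DataFrame:
    """Read a sample metadata TSV keyed by ``sample_id``.

    Known categorical columns are validated against their declared
    vocabularies (case-insensitively); unknown levels raise unless
    ``strict`` is False, in which case they warn.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: metadata needs a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id rows")
    df = df.set_index("sample_id")
    for col, vocab in METADATA_VOCABULARIES.items():
        if col not in df.columns:
            continue
        values = df[col].dropna().str.lower()
        bad = sorted(set(values) - set(vocab))
        if bad:
            msg = f"{path}: column {col!r} has values outside vocabulary: {bad}"
            if strict:
                raise FormatError(msg)
            warnings.warn(msg, stacklevel=2)
        df[col] = df[col].str.lower()
    return df


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")
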