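from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nanopam.io import CountMatrix, ProbePanel
from nanopam.normalization import normalize_counts
from nanopam.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def small_panel() -> ProbePanel:
    """2 endogenous + 2 housekeeping + 4 negative probes."""
    return ProbePanel.from_records(
        [
            ("GENE_A", "endogenous", "basal"),
            ("GENE_B", "endogenous", "luminal"),
            ("HK_1", "housekeeping", "none"),
            ("HK_2", "housekeeping", "none"),
            ("NEG_1", "negative", "none"),
            ("NEG_2", "negative", "none"),
            ("NEG_3", "negative", "none"),
            ("NEG_4", "negative", "none"),
        ]
    )


@pytest.fixture
def small_counts(small_panel) -> CountMatrix:
    return CountMatrix(
        pd.DataFrame(
            {
                "s1": [10, 200, 120, 80, 1, 2, 4, 8],
                "s2": [50, 2, 150, 90, 2, 2, 2, 2],
            },
            index=pd.Index(small_panel.probes, name="probe"),
        )
    )


def write_rcc(path, sample_id: str, rows, lane_attrs=None, crlf=False) -> None:
    """rows: iterable of (CodeClass, Name, Count)."""
    lines = ["<Header>", "FileVersion,1.7", "</Header>", "<Sample_Attributes>", f"ID,{sample_id}", "</Sample_Attributes>", "<Lane_Attributes>"]
    for k, v in (lane_attrs or {"ID": "1", "FovCount": "280"}).items():
        lines.append(f"{k},{v}")
    lines += ["</Lane_Attributes>", "<Code_Summary>", "CodeClass,Name,Accession,Count"]
    for code_class, name, count in rows:
        lines.append(f"{code_class},{name},NM_0000,{count}")
    lines += ["</Code_Summary>"]
    sep = "\r\n" if crlf else "\n"
    path.write_text(sep.join(lines) + sep)


@pytest.fixture
def rcc_writer():
    return write_rcc


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def normalized_cohort(default_cohort):
    normalized, report = normalize_counts(default_cohort.counts, default_cohort.panel)
    return default_cohort, normalized, report


@pytest.fixture
def rng():
    return np.random.default_rng(0)
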