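"""Bundled default probe panel for the 47-gene basal/luminal signature.

The bundled panel carries 47 endogenous signature genes annotated with
their basal/luminal node, the 4 housekeeping genes used for scaling
(AMMECR1L, SRPRA, XRCC6, EIF2B4), 8 negative-control probes and 6
positive-control probes (present for completeness; no operation consumes
them).  Gene-node assignments are metadata only — training is always
de novo — so users applying the toolkit to their own codeset should load
their own panel file.
"""

from __future__ import annotations

from nanopam.io import ProbePanel

_BASAL_GENES = (
    "AHNAK2", "CD14", "CD44", "CDH3", "COL17A1", "DSC3", "DSG3", "EMP3",
    "IL6", "KRT1", "KRT14", "KRT16", "KRT5", "KRT6A", "KRT6B", "KRT6C",
    "MSN", "PI3", "S100A7", "S100A8", "SERPINB5", "TP63",
)

_LUMINAL_GENES = (
    "ADIRF", "CD24", "CYP2J2", "ERBB2", "ERBB3", "FGFR3", "FOXA1", "GATA3",
    "GPX2", "KRT18", "KRT19", "KRT20", "KRT7", "KRT8", "PPARG", "SCNN1B",
    "TBX2", "TBX3", "TMEM30B", "UPK1A", "UPK1B", "UPK2", "UPK3A", "UPK3B",
    "XBP1",
)

HOUSEKEEPING_GENES = ("AMMECR1L", "SRPRA", "XRCC6", "EIF2B4")

_NEGATIVE_PROBES = tuple(f"NEG_{c}" for c in "ABCDEFGH")
_POSITIVE_PROBES = tuple(f"POS_{c}" for c in "ABCDEF")


def base47_panel(include_positive: bool = True) -> ProbePanel:
    """Return the bundled 47-gene signature panel.

    Invariants: 47 endogenous probes (22 basal node, 25 luminal node),
    exactly the 4 housekeeping probes AMMECR1L, SRPRA, XRCC6, EIF2B4,
    and 8 negative controls.
    """
    records = (
        [(g, "endogenous", "basal") for g in _BASAL_GENES]
        + [(g, "endogenous", "luminal") for g in _LUMINAL_GENES]
        + [(g, "housekeeping", "none") for g in HOUSEKEEPING_GENES]
        + [(p, "negative", "none") for p in _NEGATIVE_PROBES]
        + ([(p, "positive", "none") for p in _POSITIVE_PROBES] if include_positive else [])
    )
    return ProbePanel.from_records(records)
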