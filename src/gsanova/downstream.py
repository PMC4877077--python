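"""Temporal response-pattern classification and qPCR quantification.

A gene measured at two post-treatment time points is placed in one of
four quadrants by the signs of its log2 fold changes (treatment vs
control): up at both times (I, sustained up), down then up (II,
transient down then up), down at both (III, sustained down), up then
down (IV, transient up then down).  Exact zeros sit on a boundary and
are reported as unclassified.

qPCR expression is quantified as a relative copy number
``(1 + E/100)^(-Ct)`` from the primer efficiency E (percent) and the
threshold cycle Ct, and normalized to a stably expressed reference gene.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "ResponsePattern",
    "QpcrMeasurement",
    "QUADRANT_LABELS",
    "classify_quadrant",
    "classify_table",
    "qpcr_relative_copy_number",
    "normalize_to_reference",
]

QUADRANT_LABELS = {
    "I": "sustained_up",
    "II": "transient_down_up",
    "III": "sustained_down",
    "IV": "transient_up_down",
}


@dataclass
class ResponsePattern:
    gene_id: str
    lfc_t1: float
    lfc_t2: float
    quadrant: str | None  # None on a zero boundary
    label: str


@dataclass
class QpcrMeasurement:
    """Primer efficiency E in percent (0, 100] and threshold cycle Ct >= 0."""

    E: float
    Ct: float

    def __post_init__(self) -> None:
        if not 0 < self.E <= 100:
            raise ValueError(f"primer efficiency must be in (0, 100], got {self.E}")
        if self.E <= 1:
            warnings.warn(
                f"primer efficiency {self.E} looks like a fraction; "
                "this formula expects percent (e.g. 90, not 0.9)",
                stacklevel=2,
            )
        if self.Ct < 0:
            raise ValueError(f"threshold cycle must be non-negative, got {self.Ct}")


def classify_quadrant(lfc_t1: float, lfc_t2: float) -> tuple[str | None, str]:
    """Quadrant and label from the signs of two log2 fold changes.

    Returns ``(None, "unclassified")`` when either value is exactly zero.
    """
    if not (math.isfinite(lfc_t1) and math.isfinite(lfc_t2)):
        raise ValueError("log2 fold changes must be finite")
    if lfc_t1 == 0 or lfc_t2 == 0:
        return None, "unclassified"
    if lfc_t1 > 0 and lfc_t2 > 0:
        quadrant = "I"
    elif lfc_t1 < 0 and lfc_t2 > 0:
        quadrant = "II"
    elif lfc_t1 < 0 and lfc_t2 < 0:
        quadrant = "III"
    else:
        quadrant = "IV"
    return quadrant, QUADRANT_LABELS[quadrant]


def classify_table(rows: list[tuple[str, float, float]]) -> list[ResponsePattern]:
    """Classify ``(gene_id, lfc_t1, lfc_t2)`` rows into response patterns."""
    out = []
    for gene_id, lfc1, lfc2 in rows:
        quadrant, label = classify_quadrant(lfc1, lfc2)
        out.append(ResponsePattern(gene_id, lfc1, lfc2, quadrant, label))
    return out


def qpcr_relative_copy_number(m: QpcrMeasurement) -> float:
    """Relative copy number (1 + E/100)^(-Ct).

    Efficiency E is in percent: E = 100 means perfect doubling per cycle,
    so one cycle halves the inferred starting amount.
    """
    return (1.0 + m.E / 100.0) ** (-m.Ct)


def normalize_to_reference(target: float, reference: float) -> float:
    """Target relative copy number divided by the reference gene's."""
    if reference <= 0:
        raise ValueError("reference relative copy number must be positive")
    return target / reference
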