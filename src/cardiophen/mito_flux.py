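"""Extracellular-flux (Seahorse) OCR normalization and mitostress metrics.

A mitostress assay measures oxygen consumption rate (OCR) through four
injection segments: basal, after oligomycin (ATP-synthase inhibitor), after
FCCP (uncoupler) and after antimycin A + rotenone (ETC inhibitors).  With
segment summaries b, o, f, a the decomposition is:

* maximal OCR        = f - o   (FCCP response relative to post-oligomycin)
* ATP production     = b - o
* proton leak        = o - a
* non-mitochondrial  = a

so that ATP production + proton leak + non-mitochondrial = basal exactly.
A palmitate assay (baseline, two palmitate additions, etomoxir) yields the
palmitate-utilization capacity: mean OCR over the second palmitate segment
minus the final value before the second addition.  OCR is normalized per cell
by each well's cell count before metrics are taken.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MITOSTRESS_SEGMENTS",
    "PALMITATE_SEGMENTS",
    "OCRAssay",
    "MitoMetrics",
    "normalize_ocr",
    "mitostress_metrics",
    "palmitate_utilization",
]

MITOSTRESS_SEGMENTS = ("basal", "oligomycin", "FCCP", "antimycin_rotenone")
PALMITATE_SEGMENTS = ("baseline", "palmitate1", "palmitate2", "etomoxir")


@dataclass
class OCRAssay:
    """Per-well OCR time course with injection-segment labels.

    ``ocr`` is (wells, timepoints) in pmol O2/min (or pmol/min/cell once
    normalized); ``segments`` labels each timepoint and must follow injection
    order; ``cell_counts`` is per well.
    """

    wells: list[str]
    time: np.ndarray
    ocr: np.ndarray
    segments: list[str]
    cell_counts: np.ndarray | None = None
    per_cell: bool = False
    segment_order: tuple[str, ...] = field(default=MITOSTRESS_SEGMENTS)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ocr = np.atleast_2d(np.asarray(self.ocr, dtype=float))
        if self.ocr.shape != (len(self.wells), self.time.size):
            raise ValueError("ocr must have shape (wells, timepoints)")
        if len(self.segments) != self.time.size:
            raise ValueError("one segment label per timepoint required")
        seen: list[str] = []
        for s in self.segments:
            if not seen or seen[-1] != s:
                seen.append(s)
        if len(seen) != len(set(seen)):
            raise ValueError("segment labels must appear in contiguous blocks")
        order = [s for s in self.segment_order if s in seen]
        if seen != order:
            raise ValueError(
                f"segments {seen} do not follow injection order {self.segment_order}"
            )
        counts = {s: self.segments.count(s) for s in seen}
        thin = [s for s, c in counts.items() if c < 2]
        if thin:
            warnings.warn(
                f"segments {thin} have fewer than 2 timepoints", stacklevel=2
            )
        if self.cell_counts is not None:
            self.cell_counts = np.asarray(self.cell_counts, dtype=float)
            if self.cell_counts.shape != (len(self.wells),):
                raise ValueError("one cell count per well required")
            if np.any(self.cell_counts <= 0):
                raise ValueError("cell counts must be positive")

    def segment_values(self, segment: str) -> np.ndarray:
        sel = [i for i, s in enumerate(self.segments) if s == segment]
        if not sel:
            raise ValueError(f"missing segment {segment!r}")
        return self.ocr[:, sel]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view (columns: well, time_s, value, segment,
        cell_count)."""
        rows = []
        for i, w in enumerate(self.wells):
            count = None if self.cell_counts is None else self.cell_counts[i]
            for j, t in enumerate(self.time):
                rows.append(
                    {
                        "well": w,
                        "time_s": t,
                        "value": self.ocr[i, j],
                        "segment": self.segments[j],
                        "cell_count": count,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class MitoMetrics:
    """Mitostress decomposition; units follow the input assay."""

    basal: float
    max_ocr: float
    atp_production: float
    proton_leak: float
    non_mito: float

    def __post_init__(self) -> None:
        parts = (self.basal, self.max_ocr, self.atp_production,
                 self.proton_leak, self.non_mito)
        if not all(np.isfinite(parts)):
            raise ValueError("all mitostress metrics must be finite")


def normalize_ocr(assay: OCRAssay) -> OCRAssay:
    """Divide each well's OCR by its cell count (units become per cell)."""
    if assay.cell_counts is None:
        raise ValueError("cell counts are required for normalization")
    if assay.per_cell:
        warnings.warn("assay is already per-cell normalized", stacklevel=2)
    return replace(
        assay,
        ocr=assay.ocr / assay.cell_counts[:, None],
        per_cell=True,
    )


def _segment_summary(values: np.ndarray, summary: str) -> np.ndarray:
    if summary == "mean":
        return values.mean(axis=1)
    if summary == "last":
        return values[:, -1]
    raise ValueError("summary must be 'mean' or 'last'")


def mitostress_metrics(
    assay: OCRAssay, *, summary: str = "mean"
) -> tuple[list[MitoMetrics], MitoMetrics]:
    """Per-well mitostress metrics and their group mean.

    ``summary`` selects the within-segment reduction: ``"mean"`` (default,
    noise-robust) or ``"last"`` (the vendor's last-rate-before-injection
    convention).
    """
    levels = {}
    for seg in MITOSTRESS_SEGMENTS:
        vals = _segment_summary(assay.segment_values(seg), summary)
        if np.any(vals < 0):
            warnings.warn(f"negative {seg} OCR summary; computing anyway",
                          stacklevel=2)
        levels[seg] = vals
    per_well = [
        MitoMetrics(
            basal=float(levels["basal"][i]),
            max_ocr=float(levels["FCCP"][i] - levels["oligomycin"][i]),
            atp_production=float(levels["basal"][i] - levels["oligomycin"][i]),
            proton_leak=float(
                levels["oligomycin"][i] - levels["antimycin_rotenone"][i]
            ),
            non_mito=float(levels["antimycin_rotenone"][i]),
        )
        for i in range(len(assay.wells))
    ]
    mean = MitoMetrics(
        basal=float(np.mean([m.basal for m in per_well])),
        max_ocr=float(np.mean([m.max_ocr for m in per_well])),
        atp_production=float(np.mean([m.atp_production for m in per_well])),
        proton_leak=float(np.mean([m.proton_leak for m in per_well])),
        non_mito=float(np.mean([m.non_mito for m in per_well])),
    )
    return per_well, mean


def palmitate_utilization(assay: OCRAssay) -> tuple[np.ndarray, float]:
    """Palmitate-utilization capacity per well and its group mean.

    Mean OCR over the second palmitate segment minus the final respiration
    value before the second palmitate addition.
    """
    p2 = assay.segment_values("palmitate2").mean(axis=1)
    p1_last = assay.segment_values("palmitate1")[:, -1]
    per_well = p2 - p1_last
    return per_well, float(per_well.mean())
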