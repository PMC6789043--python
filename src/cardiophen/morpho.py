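"""Image morphometrics: object shape, colocalization and nucleation counts.

Shape metrics follow the conventions used for cell-area and mitochondrial
morphology measurements: area is the pixel count scaled by the squared pixel
size, and the circularity index is ``4*pi*area / perimeter**2`` (1 for a
perfect disc).  The perimeter comes from a subpixel marching-squares boundary
with a short circular moving-average corner correction, because raw pixel
boundaries systematically overestimate the perimeter of smooth objects and
bias circularity low.

Colocalization reports the Pearson correlation of two channels within a mask
together with Manders' overlap coefficients M1/M2 (fraction of each channel's
intensity residing in pixels where the other channel is above threshold) and
the masked mean intensities.  The nucleation test is the Pearson chi-square
on a 2 x 4 contingency table of cells with 1, 2, 3 or >= 4 nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.stats import chi2_contingency
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label, regionprops

__all__ = [
    "NUCLEATION_CATEGORIES",
    "ColocalizationResult",
    "NucleationTestResult",
    "shape_metrics",
    "colocalization",
    "nucleation_test",
]

#: Nucleation histogram categories: 1, 2, 3, or >= 4 nuclei per cell.
NUCLEATION_CATEGORIES = ("1", "2", "3", "4+")

#: Window (contour points) of the circular moving average that corrects the
#: staircase bias of the marching-squares boundary.
_SMOOTH_WINDOW = 5


def _object_perimeter(mask: np.ndarray) -> float:
    """Perimeter of a single binary object in pixel units.

    Uses the 0.5-level marching-squares contour smoothed with a short
    circular moving average; the raw contour over-measures smooth boundaries
    (a rasterized disc comes out ~5% long), and the smoothing removes that
    staircase bias while barely shortening straight edges.
    """
    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:  # pragma: no cover - non-empty object always has one
        return 0.0
    contour = max(contours, key=len)[:-1]  # closed: drop duplicate point
    if len(contour) > _SMOOTH_WINDOW:
        contour = np.column_stack(
            [
                uniform_filter1d(contour[:, i], _SMOOTH_WINDOW, mode="wrap")
                for i in range(2)
            ]
        )
    closed = np.vstack([contour, contour[:1]])
    steps = np.diff(closed, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def shape_metrics(mask: np.ndarray, pixel_size: float = 1.0) -> pd.DataFrame:
    """Per-object area (um^2) and circularity from a binary or labeled mask.

    Circularity is clipped to <= 1 (discretization can push the raw value
    slightly above 1 for near-perfect discs).

    Returns a DataFrame with columns ``label``, ``area_px``, ``area_um2``,
    ``perimeter_um``, ``circularity``.
    """
    mask = np.asarray(mask)
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    labeled = label(mask > 0) if mask.dtype == bool or mask.max() <= 1 else mask
    if labeled.max() == 0:
        raise ValueError("empty mask: nothing to measure")
    rows = []
    for prop in regionprops(labeled):
        obj = labeled[prop.slice] == prop.label
        per_px = _object_perimeter(obj)
        area_px = int(prop.area)
        circ = 4 * np.pi * area_px / per_px**2 if per_px > 0 else np.nan
        rows.append(
            {
                "label": prop.label,
                "area_px": area_px,
                "area_um2": area_px * pixel_size**2,
                "perimeter_um": per_px * pixel_size,
                "circularity": min(float(circ), 1.0),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ColocalizationResult:
    """Two-channel colocalization summary within a mask.

    ``pearson_r`` is ``None`` (with ``constant_channel`` set) when either
    channel has zero variance in the mask.
    """

    pearson_r: float | None
    m1: float
    m2: float
    mean_a: float
    mean_b: float
    n_pixels: int
    constant_channel: bool = False


def colocalization(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    mask: np.ndarray | None = None,
    *,
    thresholds: tuple[float, float] | str | None = None,
) -> ColocalizationResult:
    """Pearson and Manders colocalization of two intensity images.

    Manders M1 is the fraction of channel-A intensity in pixels where channel
    B exceeds its threshold (M2 symmetric).  The default threshold is 0
    (classic Manders overlap: any positive signal counts), so identical
    all-positive channels give M1 = M2 = 1; pass ``thresholds="otsu"`` for
    per-channel Otsu within the mask, or an explicit ``(ta, tb)`` pair.
    """
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channels must have equal shapes")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != a.shape:
        raise ValueError("mask shape must match the channels")
    av, bv = a[mask], b[mask]
    if av.size == 0:
        raise ValueError("mask selects no pixels")

    constant = np.ptp(av) == 0 or np.ptp(bv) == 0
    r = None if constant else float(np.corrcoef(av, bv)[0, 1])

    if thresholds is None:
        ta = tb = 0.0
    elif thresholds == "otsu":
        ta = threshold_otsu(av) if np.ptp(av) > 0 else av[0]
        tb = threshold_otsu(bv) if np.ptp(bv) > 0 else bv[0] - 1
    else:
        ta, tb = thresholds
    sum_a, sum_b = av.sum(), bv.sum()
    m1 = float(av[bv > tb].sum() / sum_a) if sum_a > 0 else np.nan
    m2 = float(bv[av > ta].sum() / sum_b) if sum_b > 0 else np.nan
    return ColocalizationResult(
        pearson_r=r,
        m1=m1,
        m2=m2,
        mean_a=float(av.mean()),
        mean_b=float(bv.mean()),
        n_pixels=int(av.size),
        constant_channel=constant,
    )


@dataclass
class NucleationTestResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray


def nucleation_test(
    counts_a,
    counts_b,
    *,
    on_zero: str = "error",
) -> NucleationTestResult:
    """Pearson chi-square comparing two nucleation histograms.

    Each argument is the 4-vector of cell counts with 1, 2, 3 and >= 4 nuclei
    for one group; expected counts come from the pooled margins, so a 2 x 4
    table has 3 degrees of freedom.  A category empty in both groups makes
    the expected count zero: ``on_zero="error"`` raises, ``"collapse"``
    merges the empty category into its left neighbour before testing (which
    reduces df).
    """
    table = np.asarray([counts_a, counts_b], dtype=float)
    if table.shape != (2, len(NUCLEATION_CATEGORIES)):
        raise ValueError(
            f"each group needs exactly {len(NUCLEATION_CATEGORIES)} categories"
        )
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be non-negative integers")
    col_totals = table.sum(axis=0)
    if (col_totals == 0).any():
        if on_zero == "error":
            raise ValueError(
                "category with zero pooled count; pass on_zero='collapse' "
                "to merge it"
            )
        if on_zero != "collapse":
            raise ValueError("on_zero must be 'error' or 'collapse'")
        keep_cols = []
        for j in range(table.shape[1]):
            if col_totals[j] == 0 and keep_cols:
                table[:, keep_cols[-1]] += table[:, j]
            elif col_totals[j] > 0:
                keep_cols.append(j)
        table = table[:, keep_cols]
    res = chi2_contingency(table, correction=False)
    return NucleationTestResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        expected=res.expected_freq,
    )
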