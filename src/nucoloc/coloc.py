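"""Per-nucleus pixel-intensity colocalization.

For each segmented nucleus the Pearson correlation coefficient of raw
pixel intensities is computed between the query-protein channel and a
nucleolar-marker channel, over the nucleus mask pixels only:

    r = sum_i (K_i - Kbar)(G_i - Gbar)
        / sqrt[ sum_i (K_i - Kbar)^2 * sum_i (G_i - Gbar)^2 ]

where K_i and G_i are the query and marker intensities at mask pixel i.
r is +1 for ideal colocalization, -1 for ideal anti-colocalization, and
is independent of channel gain and offset — it measures spatial
coincidence, not interaction.  Intensities enter raw: no background
subtraction or normalization, and saturated pixels are retained (their
fraction is reported as a QC column instead).

The assay's dynamic range is calibrated with simulated controls: a
positive pair (two independent noisy renderings of the same nucleolar
structure) and a negative pair (marker vs the DAPI counterstain, which
is depleted inside nucleoli).

A per-cell nucleolar call complements the coefficient: the nucleolus
submask is taken by global Otsu on the marker within the nucleus, and a
cell is called nucleolar-localized when mean query intensity inside the
submask exceeds ``tau`` times the mean over the rest of the nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .segment import LabelMap
from .simgen import FieldImage

__all__ = [
    "CellRecord",
    "ControlCalibration",
    "CalibrationError",
    "pearson_within_mask",
    "score_cells",
    "calibrate_controls",
    "nucleolar_call",
    "records_table",
]

DEFAULT_MIN_PIXELS = 20
DEFAULT_TAU = 1.5


class CalibrationError(RuntimeError):
    """Raised when the positive/negative controls fail their ordering."""


@dataclass
class CellRecord:
    """Measurements for one nucleus."""

    cell_id: int
    area_px: int
    centroid: tuple[float, float]
    pearson_r: float | None
    undefined_reason: str  # none | too_few_pixels | zero_variance
    mean_query: float
    mean_marker: float
    nucleolar_enrichment_ratio: float | None
    nucleolar_call: bool | None
    saturation_fraction: float
    condition: str = ""


@dataclass(frozen=True)
class ControlCalibration:
    """Summary of the assay's dynamic range from control cells."""

    pos_mean: float
    pos_sd: float
    neg_mean: float
    neg_sd: float
    n_pos: int
    n_neg: int

    @property
    def dynamic_range(self) -> float:
        return self.pos_mean - self.neg_mean


def pearson_within_mask(
    query: np.ndarray,
    marker: np.ndarray,
    mask: np.ndarray,
    min_pixels: int = DEFAULT_MIN_PIXELS,
) -> tuple[float | None, str]:
    """Pearson coefficient over mask pixels; (value, reason) pair.

    Only the pixels where ``mask`` is True enter the sums — never the
    rectangular crop around the region, whose background pixels would
    inflate the correlation.  Returns ``(None, reason)`` instead of
    raising when the coefficient is undefined: fewer than ``min_pixels``
    mask pixels (``too_few_pixels``) or a constant channel over the mask
    (``zero_variance``).
    """
    query = np.asarray(query)
    marker = np.asarray(marker)
    mask = np.asarray(mask, dtype=bool)
    if query.shape != marker.shape or query.shape != mask.shape:
        raise ValueError("query, marker and mask must share one shape")
    k = query[mask].astype(float)
    g = marker[mask].astype(float)
    if k.size < min_pixels:
        return None, "too_few_pixels"
    k = k - k.mean()
    g = g - g.mean()
    denom = np.sqrt((k @ k) * (g @ g))
    if denom == 0.0:
        return None, "zero_variance"
    r = float((k @ g) / denom)
    # guard against rounding drift just outside [-1, 1]
    return max(-1.0, min(1.0, r)), "none"


def nucleolar_call(
    query: np.ndarray,
    nucleus_mask: np.ndarray,
    nucleolus_submask: np.ndarray,
    tau: float = DEFAULT_TAU,
    min_pixels: int = DEFAULT_MIN_PIXELS,
) -> tuple[float | None, bool | None]:
    """Enrichment ratio and nucleolar-localization flag for one cell.

    ratio = mean query inside the nucleolus submask / mean query over
    the rest of the nucleus; the cell is called nucleolar-localized when
    ratio >= tau.  Undefined (None, None) when either compartment has
    fewer than ``min_pixels`` pixels or the nucleoplasm mean is zero.
    """
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    sub = np.asarray(nucleolus_submask, dtype=bool) & nucleus_mask
    rest = nucleus_mask & ~sub
    if sub.sum() < min_pixels or rest.sum() < min_pixels:
        return None, None
    query = np.asarray(query, dtype=float)
    inside = float(query[sub].mean())
    outside = float(query[rest].mean())
    if outside == 0.0:
        return None, None
    ratio = inside / outside
    return ratio, bool(ratio >= tau)


def _marker_submask(marker: np.ndarray, nucleus_mask: np.ndarray) -> np.ndarray:
    """Nucleolus submask: global Otsu on the marker restricted to the nucleus."""
    vals = marker[nucleus_mask]
    if vals.size == 0 or vals.min() == vals.max():
        return np.zeros_like(nucleus_mask)
    t = threshold_otsu(vals)
    return nucleus_mask & (marker > t)


def score_cells(
    field: FieldImage,
    labels: LabelMap | np.ndarray,
    query_role: str = "query",
    marker_role: str = "marker",
    condition: str = "",
    min_pixels: int = DEFAULT_MIN_PIXELS,
    tau: float = DEFAULT_TAU,
) -> list[CellRecord]:
    """Score every labelled nucleus in a field.

    One :class:`CellRecord` per label, in label order.  The coefficient
    follows :func:`pearson_within_mask` on the raw channels; the
    nucleolar call uses a marker-derived submask per nucleus.
    """
    for role in (query_role, marker_role):
        if role not in field.channels:
            raise KeyError(f"channel role {role!r} missing from field")
    if not isinstance(labels, LabelMap):
        labels = LabelMap(labels)
    if labels.shape != field.shape:
        raise ValueError("label map and channels must share one shape")
    query = field.channels[query_role]
    marker = field.channels[marker_role]
    sat_level = 2**field.bit_depth - 1

    records: list[CellRecord] = []
    for lab, mask in labels.masks():
        npx = int(mask.sum())
        rows, cols = np.nonzero(mask)
        centroid = (float(rows.mean()), float(cols.mean())) if npx else (np.nan, np.nan)
        r, reason = pearson_within_mask(query, marker, mask, min_pixels=min_pixels)
        sub = _marker_submask(marker, mask)
        ratio, call = nucleolar_call(query, mask, sub, tau=tau, min_pixels=min_pixels)
        sat = float(
            np.mean((query[mask] >= sat_level) | (marker[mask] >= sat_level))
        ) if npx else 0.0
        records.append(
            CellRecord(
                cell_id=lab,
                area_px=npx,
                centroid=centroid,
                pearson_r=r,
                undefined_reason=reason,
                mean_query=float(query[mask].mean()) if npx else float("nan"),
                mean_marker=float(marker[mask].mean()) if npx else float("nan"),
                nucleolar_enrichment_ratio=ratio,
                nucleolar_call=call,
                saturation_fraction=sat,
                condition=condition,
            )
        )
    return records


def calibrate_controls(
    pos_records: Sequence[CellRecord | float],
    neg_records: Sequence[CellRecord | float],
) -> ControlCalibration:
    """Summarize positive/negative control coefficients.

    Accepts CellRecord lists or bare coefficient sequences; undefined
    coefficients are excluded.  Raises :class:`CalibrationError` when
    the positive mean does not exceed the negative mean — the signature
    of swapped inputs or broken controls.
    """
    pos = _coeffs(pos_records)
    neg = _coeffs(neg_records)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both control groups need at least one defined coefficient")
    cal = ControlCalibration(
        pos_mean=float(pos.mean()),
        pos_sd=float(pos.std(ddof=1)) if pos.size > 1 else 0.0,
        neg_mean=float(neg.mean()),
        neg_sd=float(neg.std(ddof=1)) if neg.size > 1 else 0.0,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )
    if cal.pos_mean <= cal.neg_mean:
        raise CalibrationError(
            f"positive-control mean ({cal.pos_mean:.3f}) does not exceed "
            f"negative-control mean ({cal.neg_mean:.3f}); controls look broken"
        )
    return cal


def _coeffs(records) -> np.ndarray:
    vals = []
    for r in records:
        v = r.pearson_r if isinstance(r, CellRecord) else r
        if v is not None and np.isfinite(v):
            vals.append(float(v))
    return np.asarray(vals)


def records_table(records: Sequence[CellRecord]) -> pd.DataFrame:
    """CellRecords as the per-cell CSV table."""
    return pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "condition": r.condition,
                "area_px": r.area_px,
                "centroid_row": r.centroid[0],
                "centroid_col": r.centroid[1],
                "pearson_r": np.nan if r.pearson_r is None else r.pearson_r,
                "undefined_reason": r.undefined_reason,
                "mean_query": r.mean_query,
                "mean_marker": r.mean_marker,
                "enrichment_ratio": np.nan
                if r.nucleolar_enrichment_ratio is None
                else r.nucleolar_enrichment_ratio,
                "nucleolar_call": r.nucleolar_call,
                "saturation_fraction": r.saturation_fraction,
            }
            for r in records
        ],
        columns=[
            "cell_id", "condition", "area_px", "centroid_row", "centroid_col",
            "pearson_r", "undefined_reason", "mean_query", "mean_marker",
            "enrichment_ratio", "nucleolar_call", "saturation_fraction",
        ],
    )
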