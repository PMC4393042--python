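"""Diversity and community-stability statistics on DGGE fingerprints.

Implemented indices, in the field's standard notation:

* species richness ``S`` — the number of bands in a lane (each band class
  standing in for one dominant phylotype);
* Shannon diversity ``H' = −Σ p_i ln p_i`` over relative band
  intensities (the only statistic here that uses intensities —
  comparison statistics are deliberately binary);
* pairwise % similarity between two lanes from shared band classes
  (Dice/Sørensen by default, ``2·common/(S_a+S_b)·100``);
* % change ``= 100 − % similarity`` between consecutive samples, its
  moving-window curve over a time series, and the rate of community
  change ``Δt`` (the curve mean);
* range-weighted richness ``Rr = N² × Dg``, where ``Dg`` is the fraction
  of the gel's denaturing gradient spanned between a lane's first and
  last band — a carrying-capacity-style index rewarding both band number
  and melting-range spread;
* unique-band counts: classes present in exactly one lane of the matrix,
  tallied over a focal subset (e.g. the thermophilic lanes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .model_io import BandMatrix, Fingerprint, GradientSpec

__all__ = [
    "richness",
    "shannon",
    "pairwise_similarity",
    "percent_change",
    "moving_window",
    "rate_of_change",
    "range_weighted_richness",
    "unique_band_counts",
    "DiversityReport",
    "build_report",
]

logger = logging.getLogger(__name__)


def richness(row) -> int:
    """Species richness S of a band-matrix lane row: its presence count."""
    return int(np.asarray(row).sum())


def shannon(fp: Fingerprint, base: float | None = None) -> float:
    """Shannon diversity H' = −Σ p_i log p_i over a lane's relative band
    intensities (natural log by default; pass ``base`` to change).

    Undefined for an empty fingerprint: returns NaN (distinct from the
    legitimate single-band value 0).
    """
    if not fp.bands:
        return math.nan
    p = np.array([b.rel_intensity for b in fp.bands], dtype=float)
    if np.any(np.isnan(p)):
        raise ValueError(f"lane {fp.lane_id!r}: rel_intensity not set")
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def pairwise_similarity(row_a, row_b, method: str = "dice") -> float:
    """% similarity between two lanes from shared band classes.

    Dice (default): 100 × 2·common / (S_a + S_b); ``method="jaccard"``
    uses 100 × common / (S_a + S_b − common).  Two empty lanes are
    defined as 100% similar (with a warning).
    """
    a = np.asarray(row_a, dtype=int)
    b = np.asarray(row_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("rows must come from the same band matrix")
    common = int((a & b).sum())
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        logger.warning("similarity of two empty lanes defined as 100%%")
        return 100.0
    if method == "dice":
        return 100.0 * 2.0 * common / (sa + sb)
    if method == "jaccard":
        return 100.0 * common / (sa + sb - common)
    raise ValueError(f"unknown similarity method {method!r}")


def percent_change(row_a, row_b, method: str = "dice") -> float:
    """% change between two lanes: 100 − % similarity."""
    return 100.0 - pairwise_similarity(row_a, row_b, method=method)


def moving_window(
    bm: BandMatrix, order: list[str], method: str = "dice"
) -> list[tuple[str, float]]:
    """Moving-window curve: % change between each pair of consecutive
    samples in ``order``, labelled "a->b"."""
    if len(order) < 2:
        raise ValueError("moving window needs at least 2 lanes")
    rows = {lane: bm.row(lane) for lane in order}
    return [
        (f"{a}->{b}", percent_change(rows[a], rows[b], method=method))
        for a, b in zip(order, order[1:])
    ]


def rate_of_change(curve: list[tuple[str, float]]) -> float:
    """Rate of community change Δt: the mean of the moving-window curve."""
    if not curve:
        raise ValueError("rate_of_change needs a non-empty curve")
    return float(np.mean([v for _, v in curve]))


def range_weighted_richness(bands, gradient: GradientSpec) -> tuple[float, float]:
    """Range-weighted richness: returns (Rr, Dg) with Rr = N² × Dg.

    ``bands`` is either a normalized :class:`Fingerprint` or an array of
    the denaturant positions of a lane's present band classes.  Dg is the
    fraction (in [0, 1]) of the gel's denaturing gradient between the
    first and last band; with N ≤ 1 the span is degenerate and Rr = 0.
    """
    if isinstance(bands, Fingerprint):
        dens = bands.denaturants()
    else:
        dens = np.asarray(bands, dtype=float)
        if np.any(np.isnan(dens)):
            raise ValueError("denaturant positions contain NaN")
    n = int(dens.size)
    if n <= 1:
        return 0.0, 0.0
    dg = float((dens.max() - dens.min()) / gradient.span)
    return float(n * n * dg), dg


def unique_band_counts(bm: BandMatrix, focal: list[str]) -> dict:
    """Bands exclusive to single lanes, tallied over a focal lane subset.

    A class is unique to lane L iff L is the only lane in the whole
    matrix containing it.  Returns per-lane counts for the focal lanes
    and their total (the number of classes unique to exactly one focal
    lane — identical to the per-lane sum, since uniqueness is exclusive).
    """
    for lane in focal:
        if lane not in bm.lane_ids:
            raise KeyError(f"unknown lane id {lane!r}")
    col_sums = bm.presence.sum(axis=0)
    per_lane = {}
    for lane in focal:
        row = bm.row(lane)
        per_lane[lane] = int(((row == 1) & (col_sums == 1)).sum())
    return {"per_lane": per_lane, "total": sum(per_lane.values())}


@dataclass
class DiversityReport:
    """Per-lane indices, the similarity matrix, the moving-window curve and
    the summary rate of change — the full numeric output of one analysis."""

    lane_ids: list[str]
    per_lane: dict  # lane_id -> {"S": int, "H_prime": float, "Rr": float, "Dg": float}
    similarity: np.ndarray
    mwa_curve: list[tuple[str, float]]
    Dt: float
    unique_counts: dict

    def to_dict(self) -> dict:
        def finite(v):
            return v if not isinstance(v, float) or math.isfinite(v) else None

        per_lane = {
            lane: {k: finite(v) for k, v in row.items()}
            for lane, row in self.per_lane.items()
        }
        return {
            "lane_ids": list(self.lane_ids),
            "per_lane": per_lane,
            "similarity": [[round(v, 9) for v in row] for row in self.similarity.tolist()],
            "mwa_curve": [{"step": s, "percent_change": round(v, 9)} for s, v in self.mwa_curve],
            "Dt": round(self.Dt, 9),
            "unique_counts": self.unique_counts,
        }


def build_report(
    bm: BandMatrix,
    fps: list[Fingerprint],
    gradient: GradientSpec,
    order: list[str] | None = None,
    focal: list[str] | None = None,
    method: str = "dice",
) -> DiversityReport:
    """Assemble the full diversity report for one matched gel.

    ``order`` is the time series used for the moving-window analysis
    (defaults to all matrix lanes in order); ``focal`` the subset for
    unique-band counting (defaults to ``order``).  H' is computed from
    the normalized fingerprints, everything else from the band matrix.
    """
    if order is None:
        order = list(bm.lane_ids)
    if focal is None:
        focal = list(order)
    fp_by_lane = {fp.lane_id: fp for fp in fps}
    per_lane = {}
    for lane in bm.lane_ids:
        row = bm.row(lane)
        rr, dg = range_weighted_richness(bm.class_positions[row == 1], gradient)
        fp = fp_by_lane.get(lane)
        per_lane[lane] = {
            "S": richness(row),
            "H_prime": shannon(fp.with_rel_intensity()) if fp is not None else math.nan,
            "Rr": rr,
            "Dg": dg,
        }
    n = len(bm.lane_ids)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            sim[i, j] = pairwise_similarity(bm.presence[i], bm.presence[j], method=method)
    curve = moving_window(bm, order, method=method)
    return DiversityReport(
        lane_ids=list(bm.lane_ids),
        per_lane=per_lane,
        similarity=sim,
        mwa_curve=curve,
        Dt=rate_of_change(curve),
        unique_counts=unique_band_counts(bm, focal),
    )
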