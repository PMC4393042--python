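"""Marker-based lane normalization and cross-lane band matching.

Electrophoretic mobility differs slightly from lane to lane (gel smile,
local gradient inhomogeneity), so raw migration positions are not
comparable across lanes.  Following standard fingerprint practice, each
gel carries one or two reference marker lanes — a mixture of amplicons
from known species with known melting positions.  A piecewise-linear map
is fitted through the observed marker bands onto the known reference
positions; sample lanes are warped through that map (or, with two
flanking markers, through a position-weighted blend of the two fitted
maps) and every band is then assigned a denaturant percentage.

After normalization, bands from different lanes lying within a small
denaturant tolerance are considered the same amplicon ("band class");
:func:`match_bands` builds the lanes × classes presence/absence matrix
that all diversity and clustering statistics consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .model_io import (
    Band,
    BandMatrix,
    Fingerprint,
    Gel,
    GradientSpec,
    denaturant_to_position,
    position_to_denaturant,
)

__all__ = [
    "PiecewiseMap",
    "fit_lane_warp",
    "normalize_fingerprint",
    "normalize_gel",
    "match_bands",
    "DEFAULT_TOLERANCE",
]

logger = logging.getLogger(__name__)

#: default band-matching tolerance in denaturant-% — below a typical DGGE
#: band width, above the marker-normalization residual
DEFAULT_TOLERANCE = 0.5


@dataclass(frozen=True)
class PiecewiseMap:
    """Strictly increasing piecewise-linear map through matched knot pairs,
    extended linearly beyond the terminal knots with the endpoint slopes."""

    knots_in: np.ndarray
    knots_out: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "knots_in", np.asarray(self.knots_in, dtype=float))
        object.__setattr__(self, "knots_out", np.asarray(self.knots_out, dtype=float))
        kin, kout = self.knots_in, self.knots_out
        if kin.ndim != 1 or kin.shape != kout.shape or kin.size < 2:
            raise ValueError("need >= 2 knot pairs of equal length")
        if np.any(np.diff(kin) <= 0) or np.any(np.diff(kout) <= 0):
            raise ValueError("knots must be strictly ascending (map must be monotone)")

    @classmethod
    def identity(cls) -> "PiecewiseMap":
        return cls(np.array([0.0, 1.0]), np.array([0.0, 1.0]))

    def __call__(self, x):
        kin, kout = self.knots_in, self.knots_out
        x = np.asarray(x, dtype=float)
        y = np.interp(x, kin, kout)
        lo_slope = (kout[1] - kout[0]) / (kin[1] - kin[0])
        hi_slope = (kout[-1] - kout[-2]) / (kin[-1] - kin[-2])
        y = np.where(x < kin[0], kout[0] + (x - kin[0]) * lo_slope, y)
        y = np.where(x > kin[-1], kout[-1] + (x - kin[-1]) * hi_slope, y)
        return float(y) if y.ndim == 0 else y


def fit_lane_warp(
    observed_marker: Fingerprint, reference_positions
) -> PiecewiseMap:
    """Fit the observed→reference coordinate map from a marker lane.

    Observed marker bands and reference positions are paired 1:1 in
    position order.  If the detector found exactly one band too many
    (e.g. a contaminant), the weakest observed band is dropped with a
    warning; any other count mismatch is a hard "marker mismatch" error,
    since the correct pairing is then unknowable.
    """
    ref = np.sort(np.asarray(reference_positions, dtype=float))
    if np.any(np.diff(ref) <= 0):
        raise ValueError("reference positions must be distinct")
    bands = list(observed_marker.bands)
    if len(bands) == len(ref) + 1:
        weakest = min(bands, key=lambda b: b.height)
        logger.warning(
            "marker lane %s: %d bands for %d references; dropping weakest "
            "(position %.4f, height %.3g)",
            observed_marker.lane_id, len(bands), len(ref), weakest.position,
            weakest.height,
        )
        bands.remove(weakest)
    elif len(bands) != len(ref):
        raise ValueError(
            f"marker mismatch: lane {observed_marker.lane_id!r} has "
            f"{len(bands)} bands for {len(ref)} reference positions"
        )
    obs = np.array([b.position for b in bands])
    return PiecewiseMap(knots_in=obs, knots_out=ref)


def normalize_fingerprint(
    fp: Fingerprint, warp_map: PiecewiseMap, gradient: GradientSpec
) -> Fingerprint:
    """Map a fingerprint's band positions into reference coordinates and
    assign denaturant values.

    Positions that the linear extension carries marginally outside [0, 1]
    are clamped to the gel boundary.  Heights and relative intensities
    are untouched; band order is preserved (the map is monotone).
    """
    new_bands = []
    for b in fp.bands:
        pos = float(np.clip(warp_map(b.position), 0.0, 1.0))
        new_bands.append(
            replace(b, position=pos, denaturant=position_to_denaturant(pos, gradient))
        )
    return replace(fp, bands=new_bands)


def normalize_gel(
    fps: list[Fingerprint],
    reference_denaturants,
    gradient: GradientSpec,
) -> list[Fingerprint]:
    """Normalize every lane of a gel using its marker lane(s).

    With one marker lane (``is_marker``), its fitted map is applied to
    all lanes.  With two or more, the first and last marker lanes anchor
    the gel and each lane gets a blend of the two fitted maps weighted by
    its index between them — the standard flanking-marker correction for
    distortion that varies smoothly across the gel.
    """
    ref_pos = np.array(
        [denaturant_to_position(d, gradient) for d in reference_denaturants]
    )
    marker_idx = [i for i, fp in enumerate(fps) if fp.is_marker]
    if not marker_idx:
        raise ValueError("normalize_gel requires at least one marker lane")
    first, last = marker_idx[0], marker_idx[-1]
    map_a = fit_lane_warp(fps[first], ref_pos)
    map_b = fit_lane_warp(fps[last], ref_pos) if last != first else map_a

    out = []
    for i, fp in enumerate(fps):
        if last == first:
            lane_map = map_a
        else:
            alpha = float(np.clip((i - first) / (last - first), 0.0, 1.0))
            lane_map = _BlendedMap(map_a, map_b, alpha)
        out.append(normalize_fingerprint(fp, lane_map, gradient))
    return out


class _BlendedMap:
    """Pointwise convex combination of two monotone maps (itself monotone)."""

    def __init__(self, map_a: PiecewiseMap, map_b: PiecewiseMap, alpha: float):
        self.map_a, self.map_b, self.alpha = map_a, map_b, alpha

    def __call__(self, x):
        return (1.0 - self.alpha) * self.map_a(x) + self.alpha * self.map_b(x)


# ---------------------------------------------------------------------------
# cross-lane band matching
# ---------------------------------------------------------------------------

#: single-linkage classes wider than this multiple of the tolerance are
#: split at their largest internal gap (bounds pathological chaining)
_MAX_SPAN_FACTOR = 3.0


def match_bands(
    fps: list[Fingerprint], tolerance: float = DEFAULT_TOLERANCE
) -> BandMatrix:
    """Group normalized bands from all lanes into band classes.

    Bands are pooled and clustered in one dimension by single linkage,
    cutting every link wider than ``tolerance`` denaturant-%.  Single
    linkage cannot split a run of mutually close bands, so chained
    classes wider than 3× the tolerance are re-split at their largest
    internal gap.  Each class's consensus position is the mean member
    denaturant; a lane contributing two bands to one class keeps the
    taller one (with a warning).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    lane_ids = [fp.lane_id for fp in fps]
    pool = []  # (denaturant, lane_index, rel_intensity, height)
    for i, fp in enumerate(fps):
        fp = fp.with_rel_intensity()
        for b in fp.bands:
            if b.denaturant is None:
                raise ValueError(
                    f"lane {fp.lane_id!r}: bands must be normalized "
                    "(denaturant set) before matching"
                )
            pool.append((b.denaturant, i, b.rel_intensity or 0.0, b.height))
    if not pool:
        return BandMatrix(
            lane_ids=lane_ids,
            class_positions=np.empty(0),
            presence=np.zeros((len(fps), 0), dtype=int),
            intensity=np.zeros((len(fps), 0)),
        )
    pool.sort(key=lambda t: t[0])
    dens = np.array([t[0] for t in pool])

    # single linkage in 1-D: a class boundary wherever the gap exceeds tolerance
    breaks = np.flatnonzero(np.diff(dens) > tolerance) + 1
    clusters = [list(rng) for rng in np.split(np.arange(len(pool)), breaks)]

    def split_wide(idx: list) -> list[list]:
        span = dens[idx[-1]] - dens[idx[0]]
        if tolerance == 0 or span <= _MAX_SPAN_FACTOR * tolerance or len(idx) < 2:
            return [idx]
        gaps = np.diff(dens[idx])
        cut = int(np.argmax(gaps)) + 1
        return split_wide(idx[:cut]) + split_wide(idx[cut:])

    clusters = [part for cl in clusters for part in split_wide(cl)]

    n_lanes, n_classes = len(fps), len(clusters)
    presence = np.zeros((n_lanes, n_classes), dtype=int)
    intensity = np.zeros((n_lanes, n_classes))
    height_seen = np.zeros((n_lanes, n_classes))
    class_positions = np.array([dens[cl].mean() for cl in clusters])
    for k, cl in enumerate(clusters):
        for j in cl:
            d, lane, rel, h = pool[j]
            if presence[lane, k]:
                logger.warning(
                    "lane %s contributes 2 bands to class at %.3f%%; keeping taller",
                    lane_ids[lane], class_positions[k],
                )
                if height_seen[lane, k] >= h:
                    continue
            presence[lane, k] = 1
            intensity[lane, k] = rel if rel > 0 else h
            height_seen[lane, k] = h
    return BandMatrix(
        lane_ids=lane_ids,
        class_positions=class_positions,
        presence=presence,
        intensity=intensity,
    )


def detect_and_match(
    gel: Gel, detection_cfg, tolerance: float = DEFAULT_TOLERANCE
) -> BandMatrix:
    """Convenience: detect, normalize against the gel's marker reference,
    and match, in one call."""
    from .band_detection import detect_gel

    fps = detect_gel(gel, detection_cfg)
    if gel.marker_reference is None or gel.gradient is None:
        raise ValueError("gel needs marker_reference and gradient")
    fps = normalize_gel(fps, gel.marker_reference, gel.gradient)
    return match_bands(fps, tolerance=tolerance)
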