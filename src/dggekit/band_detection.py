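"""Band calling on densitometric lane profiles.

A lane trace is first freed of its smooth background (rolling-minimum
baseline followed by smoothing — a 1-D morphological opening), then
scanned for peaks.  Local maxima must clear a prominence floor and a
minimum mutual separation (below gel resolution two peaks are one band);
finally the per-lane relative-height rule is applied: only bands whose
peak height exceeds a fraction (default 1.0%) of the strongest band in
the same lane are kept.  Peak height, not area, is the intensity
measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from scipy.ndimage import minimum_filter1d, uniform_filter1d

from .model_io import Band, Fingerprint, Gel, LaneProfile

__all__ = ["DetectionConfig", "subtract_background", "detect_bands", "detect_gel"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionConfig:
    """Band-search parameters.

    ``background_window`` (migration units) is the span of the
    rolling-minimum baseline estimator and must exceed the band width;
    ``min_rel_height`` is the relative inclusion threshold (0.01 = the
    1.0%-of-strongest-band rule); ``min_separation`` (migration units)
    merges sub-resolution peaks; ``min_prominence`` is an absolute
    prominence floor against noise (intensity units — unlike the
    relative rule it is deliberately not scale-invariant).
    """

    background_window: float = 0.05
    min_rel_height: float = 0.01
    min_separation: float = 0.008
    min_prominence: float = 5.0

    def __post_init__(self) -> None:
        if self.background_window <= 0:
            raise ValueError("background_window must be > 0")
        if not 0.0 < self.min_rel_height < 1.0:
            raise ValueError("min_rel_height must be in (0, 1)")
        if self.min_separation < 0 or self.min_prominence < 0:
            raise ValueError("min_separation and min_prominence must be >= 0")


def _window_points(span: float, positions: np.ndarray) -> int:
    step = float(np.median(np.diff(positions)))
    return max(1, int(round(span / step)))


def subtract_background(profile: LaneProfile, cfg: DetectionConfig) -> LaneProfile:
    """Remove the smooth baseline from a lane trace.

    Baseline = rolling minimum over ``background_window`` followed by a
    moving-average smooth of the same span; the result is clipped at
    zero.  A constant trace maps to flat zero."""
    w = _window_points(cfg.background_window, profile.positions)
    baseline = minimum_filter1d(profile.intensities, size=w, mode="nearest")
    baseline = uniform_filter1d(baseline, size=w, mode="nearest")
    cleaned = np.clip(profile.intensities - baseline, 0.0, None)
    return replace(profile, intensities=cleaned)


def detect_bands(profile: LaneProfile, cfg: DetectionConfig) -> Fingerprint:
    """Call bands on a background-subtracted lane.

    Peaks are local maxima with prominence ≥ ``min_prominence`` and
    pairwise separation ≥ ``min_separation``; of those, any with height
    below ``min_rel_height`` × (tallest surviving peak) are dropped.
    An empty lane yields an empty fingerprint.
    """
    x = profile.intensities
    distance = max(1, _window_points(cfg.min_separation, profile.positions))
    prominence = cfg.min_prominence if cfg.min_prominence > 0 else None
    peaks, _ = sps.find_peaks(x, prominence=prominence, distance=distance)
    bands: list[Band] = []
    if peaks.size:
        heights = x[peaks]
        keep = heights >= cfg.min_rel_height * heights.max()
        bands = [
            Band(position=float(profile.positions[i]), height=float(x[i]))
            for i in peaks[keep]
        ]
    fp = Fingerprint(
        lane_id=profile.lane_id,
        bands=bands,
        sample_meta=profile.sample_meta,
        is_marker=profile.is_marker,
    )
    return fp.with_rel_intensity()


def detect_gel(gel: Gel, cfg: DetectionConfig) -> list[Fingerprint]:
    """Background-subtract and band-call every lane, preserving lane order
    and metadata (marker lanes included)."""
    out = []
    for lane in gel.lanes:
        if not isinstance(lane, LaneProfile):
            raise TypeError("detect_gel expects a gel of LaneProfile lanes")
        out.append(detect_bands(subtract_background(lane, cfg), cfg))
    return out
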