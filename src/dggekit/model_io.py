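"""Shared data model and plain-text I/O for DGGE fingerprint analysis.

The objects here mirror the stages of a denaturing gradient gel
electrophoresis (DGGE) community-fingerprint workflow:

``LaneProfile``
    densitometric intensity versus migration position for one gel lane —
    the raw input surface of the pipeline.
``Band`` / ``Fingerprint``
    a detected band (position, background-subtracted peak height,
    relative intensity) and the ordered per-lane band list.
``BandMatrix``
    lanes × matched band classes presence/absence (with intensities)
    after cross-lane matching — the object that similarity, uniqueness
    and clustering statistics operate on.

Migration positions are normalised to [0, 1] with 0 at the well and 1 at
the gel bottom.  The chemical denaturant concentration is assumed to be
linear in migration distance across the gel's stated gradient, so a
position maps to a denaturant percentage by linear interpolation.

All file formats are headered CSV/TSV; no gel-image formats are handled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GradientSpec",
    "SampleMeta",
    "Band",
    "Fingerprint",
    "LaneProfile",
    "Gel",
    "BandMatrix",
    "position_to_denaturant",
    "denaturant_to_position",
    "read_profiles",
    "write_profiles",
    "read_band_table",
    "write_band_table",
    "read_matrix",
    "write_matrix",
]

#: fixed-point precision for serialised migration positions
_POSITION_DECIMALS = 6


class FormatError(ValueError):
    """Raised when an input file violates the documented format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GradientSpec:
    """Denaturant gradient of a gel: ``low`` % at the well side, ``high`` %
    at the bottom (e.g. 35–75 for a V3–V5 16S rDNA gel)."""

    low: float
    high: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.low < self.high <= 100.0):
            raise ValueError(
                f"gradient must satisfy 0 <= low < high <= 100, got "
                f"{self.low}-{self.high}"
            )

    @property
    def span(self) -> float:
        return self.high - self.low


@dataclass(frozen=True)
class SampleMeta:
    """Provenance of one lane: process stage label, sampling time, reactor."""

    stage: str = ""
    time_h: float | None = None
    reactor: str = ""


@dataclass
class Band:
    """One detected band.

    ``position`` is the migration coordinate in [0, 1]; ``denaturant`` is
    the % denaturant at that position, set after marker normalisation;
    ``height`` is the background-subtracted peak intensity (arbitrary
    units); ``rel_intensity`` is the height divided by the sum of heights
    in its lane.
    """

    position: float
    height: float
    denaturant: float | None = None
    rel_intensity: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.position <= 1.0):
            raise ValueError(f"band position {self.position} outside [0, 1]")
        if self.height < 0:
            raise ValueError(f"band height {self.height} < 0")


@dataclass
class Fingerprint:
    """Ordered band list of one lane; the unit of all downstream statistics."""

    lane_id: str
    bands: list[Band] = field(default_factory=list)
    sample_meta: SampleMeta | None = None
    is_marker: bool = False

    def __post_init__(self) -> None:
        pos = [b.position for b in self.bands]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(
                f"lane {self.lane_id!r}: bands must be strictly ordered by position"
            )

    @property
    def richness(self) -> int:
        """Band count S of the lane."""
        return len(self.bands)

    def positions(self) -> np.ndarray:
        return np.array([b.position for b in self.bands], dtype=float)

    def denaturants(self) -> np.ndarray:
        if any(b.denaturant is None for b in self.bands):
            raise ValueError(f"lane {self.lane_id!r}: denaturant not set on all bands")
        return np.array([b.denaturant for b in self.bands], dtype=float)

    def with_rel_intensity(self) -> "Fingerprint":
        """Return a copy whose bands carry rel_intensity (heights / total)."""
        total = sum(b.height for b in self.bands)
        if total <= 0:
            bands = [replace(b, rel_intensity=None) for b in self.bands]
        else:
            bands = [replace(b, rel_intensity=b.height / total) for b in self.bands]
        return replace(self, bands=bands)


@dataclass
class LaneProfile:
    """Densitometric trace of one lane on an ascending [0, 1] position grid."""

    lane_id: str
    positions: np.ndarray
    intensities: np.ndarray
    sample_meta: SampleMeta | None = None
    is_marker: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.shape != self.intensities.shape:
            raise ValueError("positions and intensities must have equal length")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise FormatError(
                f"lane {self.lane_id!r}: position grid must be strictly ascending"
            )
        if np.any(self.intensities < 0):
            raise FormatError(f"lane {self.lane_id!r}: negative intensity")


@dataclass
class Gel:
    """An ordered set of lanes plus gradient metadata.

    ``marker_reference`` holds the known denaturant positions of the
    reference marker bands (ascending) when a species marker is used.
    """

    lanes: list
    gradient: GradientSpec | None = None
    marker_reference: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.lanes:
            raise ValueError("a gel needs at least one lane")
        if self.marker_reference is not None:
            ref = list(self.marker_reference)
            if any(b <= a for a, b in zip(ref, ref[1:])):
                raise ValueError("marker_reference must be strictly ascending")

    @property
    def lane_ids(self) -> list[str]:
        return [lane.lane_id for lane in self.lanes]


@dataclass
class BandMatrix:
    """Lanes × matched band classes, after cross-lane matching.

    ``presence`` is binary; ``intensity`` carries each lane's relative
    band intensity in the class (0 where absent).  ``class_positions``
    are the consensus denaturant positions of the classes, ascending.
    """

    lane_ids: list[str]
    class_positions: np.ndarray
    presence: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.class_positions = np.asarray(self.class_positions, dtype=float)
        self.presence = np.asarray(self.presence, dtype=int)
        self.intensity = np.asarray(self.intensity, dtype=float)
        n_lanes, n_classes = len(self.lane_ids), self.class_positions.size
        if self.presence.shape != (n_lanes, n_classes):
            raise ValueError("presence must be lanes x classes")
        if self.intensity.shape != (n_lanes, n_classes):
            raise ValueError("intensity must be lanes x classes")
        if not np.isin(self.presence, (0, 1)).all():
            raise ValueError("presence entries must be 0 or 1")
        if np.any((self.intensity > 0) != (self.presence == 1)):
            raise ValueError("intensity > 0 exactly where presence = 1")
        if n_classes > 1 and np.any(np.diff(self.class_positions) <= 0):
            raise ValueError("class_positions must be strictly ascending")

    def row(self, lane_id: str) -> np.ndarray:
        try:
            i = self.lane_ids.index(lane_id)
        except ValueError:
            raise KeyError(f"unknown lane id {lane_id!r}") from None
        return self.presence[i]


# ---------------------------------------------------------------------------
# coordinate mapping
# ---------------------------------------------------------------------------


def position_to_denaturant(position: float, gradient: GradientSpec) -> float:
    """Map a migration position in [0, 1] to % denaturant.

    Denaturant concentration is taken to be linear in migration distance:
    ``low + position * (high - low)``.
    """
    position = float(position)
    if not (0.0 <= position <= 1.0) or math.isnan(position):
        raise ValueError(f"position {position} outside [0, 1]")
    return gradient.low + position * gradient.span


def denaturant_to_position(denaturant: float, gradient: GradientSpec) -> float:
    """Inverse of :func:`position_to_denaturant`."""
    denaturant = float(denaturant)
    if not (gradient.low <= denaturant <= gradient.high):
        raise ValueError(
            f"denaturant {denaturant} outside gradient {gradient.low}-{gradient.high}"
        )
    return (denaturant - gradient.low) / gradient.span


# ---------------------------------------------------------------------------
# profiles TSV
# ---------------------------------------------------------------------------


def read_profiles(path, gradient: GradientSpec | None = None) -> Gel:
    """Read a lane-profile TSV (column 1 ``position``, one column per lane).

    Positions given in other units (e.g. pixels or mm) are linearly
    rescaled to [0, 1].  Raises :class:`FormatError` on a non-monotone
    position column or negative intensities.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError("profiles TSV needs a position column and >= 1 lane")
    pos = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(np.diff(pos) <= 0):
        raise FormatError("position column must be strictly ascending")
    if pos.min() < 0 or pos.max() > 1:
        pos = (pos - pos.min()) / (pos.max() - pos.min())
    lanes = []
    for col in df.columns[1:]:
        inten = df[col].to_numpy(dtype=float)
        if np.any(inten < 0):
            raise FormatError(f"lane {col!r}: negative intensity")
        lanes.append(LaneProfile(lane_id=str(col), positions=pos, intensities=inten))
    return Gel(lanes=lanes, gradient=gradient)


def write_profiles(gel: Gel, path) -> None:
    """Write a gel of :class:`LaneProfile` lanes as a TSV (round-trips with
    :func:`read_profiles` to 1e-9)."""
    lanes = gel.lanes
    base = lanes[0].positions
    for lane in lanes[1:]:
        if lane.positions.shape != base.shape or not np.allclose(
            lane.positions, base, atol=0, rtol=0
        ):
            raise ValueError("all lanes must share one position grid to serialise")
    data = {"position": base}
    data.update({lane.lane_id: lane.intensities for lane in lanes})
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# band table CSV
# ---------------------------------------------------------------------------

_BAND_COLUMNS = ["lane_id", "position", "denaturant", "height", "rel_intensity"]


def read_band_table(path) -> list[Fingerprint]:
    """Read a band-table CSV into one :class:`Fingerprint` per lane.

    Bands are sorted by position and ``rel_intensity`` recomputed per
    lane.  Duplicate (lane, position) pairs and negative heights are
    format errors.  Lane metadata (stage, marker flag) is not serialised
    in band tables and must be reattached by the caller.
    """
    df = pd.read_csv(path)
    missing = {"lane_id", "position", "height"} - set(df.columns)
    if missing:
        raise FormatError(f"band table missing columns: {sorted(missing)}")
    if (df["height"] < 0).any():
        raise FormatError("band table contains a negative height")
    if df.duplicated(subset=["lane_id", "position"]).any():
        raise FormatError("duplicate (lane_id, position) pair in band table")
    fps = []
    for lane_id, group in df.groupby("lane_id", sort=False):
        group = group.sort_values("position")
        bands = []
        for _, r in group.iterrows():
            den = r.get("denaturant")
            bands.append(
                Band(
                    position=float(r["position"]),
                    height=float(r["height"]),
                    denaturant=None if pd.isna(den) else float(den),
                )
            )
        fps.append(Fingerprint(lane_id=str(lane_id), bands=bands).with_rel_intensity())
    return fps


def write_band_table(fps: list[Fingerprint], path) -> None:
    """Write fingerprints as a band-table CSV.

    Positions use 6-decimal fixed point so detector output is canonical;
    lanes with no bands contribute no rows (an empty list yields a
    header-only file).
    """
    rows = []
    for fp in fps:
        for b in fp.bands:
            rows.append(
                {
                    "lane_id": fp.lane_id,
                    "position": round(b.position, _POSITION_DECIMALS),
                    "denaturant": b.denaturant,
                    "height": b.height,
                    "rel_intensity": b.rel_intensity,
                }
            )
    pd.DataFrame(rows, columns=_BAND_COLUMNS).to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# band matrix TSV
# ---------------------------------------------------------------------------


def write_matrix(bm: BandMatrix, path) -> None:
    """Write a band matrix as TSV: rows = lanes, columns = class consensus
    denaturant positions, cells = relative intensity (0 = absent)."""
    cols = [f"{p:.4f}" for p in bm.class_positions]
    df = pd.DataFrame(bm.intensity, index=bm.lane_ids, columns=cols)
    df.index.name = "lane_id"
    df.to_csv(path, sep="\t", float_format="%.9g")


def read_matrix(path) -> BandMatrix:
    """Read a band-matrix TSV written by :func:`write_matrix`; presence is
    reconstructed as intensity > 0."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    intensity = df.to_numpy(dtype=float)
    return BandMatrix(
        lane_ids=[str(i) for i in df.index],
        class_positions=np.array([float(c) for c in df.columns]),
        presence=(intensity > 0).astype(int),
        intensity=intensity,
    )
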