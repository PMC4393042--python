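"""Ground-truthed synthetic DGGE gels emulating an ATAD treatment series.

Autothermal thermophilic aerobic digestion (ATAD) takes sludge from a
mesophilic inlet (~10 °C) through an autoheating reactor (1A) into a
thermophilic reactor (2A, ~55–65 °C) and out as stabilised biosolids.
The bacterial community turns over at the mesophilic→thermophilic
transition: many mesophilic species disappear, new thermophilic species
appear, and — because thermophile amplicons tend to be GC-richer and so
melt at higher denaturant — the new bands sit further down the gel.  A
few generalists persist through every stage.

This module plants such a succession as ground truth and renders it into
densitometric lane profiles: Gaussian bands on a smooth baseline with
additive noise, each lane distorted by a small monotone warp that varies
smoothly across the gel (the distortion marker-based normalization must
undo).  Two flanking reference-marker lanes (a six-species standard) are
included, as on a real comparative gel.

Every output is a deterministic function of the :class:`SimulationConfig`
(including its seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .model_io import (
    Band,
    Fingerprint,
    Gel,
    GradientSpec,
    LaneProfile,
    SampleMeta,
    denaturant_to_position,
)
from .normalization import PiecewiseMap

__all__ = [
    "SpeciesAmplicon",
    "Community",
    "SimulationConfig",
    "STAGES",
    "STAGE_META",
    "make_marker",
    "generate_succession",
    "sample_warp",
    "render_lane",
    "simulate_gel",
]

#: sample-lane order of the ATAD series (gel lane order)
STAGES = ["inlet", "R1A_4h", "R1A_8h", "R1A_16h", "R2A_4h", "R2A_23h", "product"]

STAGE_META = {
    "inlet": SampleMeta(stage="inlet"),
    "R1A_4h": SampleMeta(stage="R1A_4h", time_h=4, reactor="1A"),
    "R1A_8h": SampleMeta(stage="R1A_8h", time_h=8, reactor="1A"),
    "R1A_16h": SampleMeta(stage="R1A_16h", time_h=16, reactor="1A"),
    "R2A_4h": SampleMeta(stage="R2A_4h", time_h=4, reactor="2A"),
    "R2A_23h": SampleMeta(stage="R2A_23h", time_h=23, reactor="2A"),
    "product": SampleMeta(stage="product"),
    "marker": SampleMeta(stage="marker"),
}


@dataclass(frozen=True)
class SpeciesAmplicon:
    """One species' amplicon: where its band sits and how abundant it is."""

    species_id: str
    true_denaturant: float
    abundance: float

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError("abundance must be > 0")


@dataclass(frozen=True)
class Community:
    """The species mixture loaded in one lane."""

    stage_label: str
    members: tuple[SpeciesAmplicon, ...]

    def __post_init__(self) -> None:
        ids = [m.species_id for m in self.members]
        if len(ids) != len(set(ids)):
            raise ValueError("member species ids must be unique")

    @property
    def species_ids(self) -> set[str]:
        return {m.species_id for m in self.members}


@dataclass(frozen=True)
class SimulationConfig:
    """Forward-model parameters for one synthetic gel.

    Units: migration coordinates are on [0, 1]; ``band_sigma`` and
    ``warp_amp`` are in migration units; denaturant quantities
    (``thermo_shift``, ``thermo_jitter_sd``, ``min_spacing``) are in
    denaturant-%.  ``turnover`` is the fraction of the late-mesophilic
    community replaced by new thermophilic species at the 1A→2A
    transition.
    """

    gradient: GradientSpec = field(
        default_factory=lambda: GradientSpec(35.0, 75.0, "V3-V5 16S rDNA")
    )
    band_sigma: float = 0.004
    baseline_amp: float = 6.0
    noise_sd: float = 0.5
    warp_amp: float = 0.01
    grid_n: int = 2000
    seed: int = 0
    turnover: float = 0.75
    thermo_shift: float = 15.0
    thermo_jitter_sd: float = 4.0
    min_spacing: float = 1.0
    abundance_median: float = 40.0
    abundance_sigma: float = 0.5
    abundance_min: float = 10.0
    n_marker_lanes: int = 2

    def __post_init__(self) -> None:
        if self.band_sigma <= 0:
            raise ValueError("band_sigma must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.turnover <= 1.0:
            raise ValueError("turnover must be in [0, 1]")
        if not 0.0 <= self.warp_amp < 0.1:
            raise ValueError("warp_amp must be in [0, 0.1) to keep warps monotone")
        if self.n_marker_lanes not in (1, 2):
            raise ValueError("n_marker_lanes must be 1 or 2")

    @property
    def n_lanes(self) -> int:
        return len(STAGES) + self.n_marker_lanes


def _rng(config: SimulationConfig, *stream) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), *stream])


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------


def make_marker(gradient: GradientSpec) -> Community:
    """The six-species reference standard, as a community.

    Six strains with distinct, well-separated melting positions spanning
    90% of the gradient, loaded in equal amounts.  Deterministic in the
    gradient alone.
    """
    offsets = np.linspace(0.05, 0.95, 6)
    members = tuple(
        SpeciesAmplicon(
            species_id=f"marker_{k + 1}",
            true_denaturant=gradient.low + off * gradient.span,
            abundance=100.0,
        )
        for k, off in enumerate(offsets)
    )
    return Community(stage_label="marker", members=members)


def _jittered_grid(rng, lo: float, hi: float, n: int) -> np.ndarray:
    """n well-separated positions in [lo, hi]: an even grid with ±15%-of-gap
    jitter, randomly shuffled so subsets are spread over the whole range."""
    centers = np.linspace(lo, hi, n)
    gap = (hi - lo) / max(n - 1, 1)
    pts = centers + rng.uniform(-0.15, 0.15, n) * gap
    rng.shuffle(pts)
    return pts


def _draw_thermophiles(
    rng, config: SimulationConfig, base_mean: float, occupied: list[float], n: int
) -> list[float]:
    """Rejection-sample n new melting positions around base_mean +
    thermo_shift, within the gel and >= min_spacing from occupied bands."""
    g = config.gradient
    lo, hi = g.low + 0.02 * g.span, g.high - 0.02 * g.span
    out: list[float] = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > 20_000:
            raise RuntimeError(
                "cannot place thermophilic species: gradient too crowded "
                "(reduce min_spacing or community sizes)"
            )
        d = base_mean + config.thermo_shift + rng.normal(0.0, config.thermo_jitter_sd)
        if not (lo <= d <= hi):
            continue
        if any(abs(d - o) < config.min_spacing for o in occupied + out):
            continue
        out.append(d)
    return out


def generate_succession(config: SimulationConfig) -> list[Community]:
    """Plant the seven-stage ATAD community succession.

    A pool of 12 mesophilic species (6 of them a persistent core)
    populates the inlet and Reactor-1A stages, with richness declining by
    16 h.  At the 1A→2A transition a ``turnover`` fraction of the 16-h
    community is replaced by new thermophilic species whose melting
    positions centre ``thermo_shift`` denaturant-% above the 16-h
    community mean.  Reactor 2A at 23 h keeps one of the 4-h thermophiles
    and gains a fresh set; the product returns to a mesophilic profile
    plus that one adapted thermophile.  Abundances are log-normal per
    stage.  Deterministic given the config.
    """
    g = config.gradient
    rng = _rng(config, 11)
    meso = _jittered_grid(rng, g.low + 0.05 * g.span, g.low + 0.45 * g.span, 12)
    m = [(f"m{k + 1:02d}", d) for k, d in enumerate(meso)]

    membership: dict[str, list[tuple[str, float]]] = {
        "inlet": m[0:10],
        "R1A_4h": m[0:8] + [m[10]],
        "R1A_8h": m[0:8] + [m[11]],
        "R1A_16h": m[0:8],
    }
    r1a_late = membership["R1A_16h"]
    n_drop = round(config.turnover * len(r1a_late))
    kept = r1a_late[: len(r1a_late) - n_drop]
    base_mean = float(np.mean([d for _, d in r1a_late]))

    occupied = [d for _, d in m]
    rng_t = _rng(config, 13)
    new4 = _draw_thermophiles(rng_t, config, base_mean, occupied, n_drop)
    t4 = [(f"t{k + 1:02d}", d) for k, d in enumerate(new4)]
    n_shared = 1 if n_drop > 0 else 0
    new23 = _draw_thermophiles(
        rng_t, config, base_mean, occupied + new4, n_drop
    ) if n_drop > 0 else []
    t23 = [(f"t{k + 1 + n_drop:02d}", d) for k, d in enumerate(new23)]

    membership["R2A_4h"] = kept + t4
    membership["R2A_23h"] = kept + t4[:n_shared] + t23
    membership["product"] = m[0:6] + m[10:12] + t4[:n_shared]

    communities = []
    for i, stage in enumerate(STAGES):
        rng_a = _rng(config, 17, i)
        members = []
        for sp_id, d in membership[stage]:
            ab = np.exp(np.log(config.abundance_median)
                        + config.abundance_sigma * rng_a.standard_normal())
            members.append(
                SpeciesAmplicon(
                    species_id=sp_id,
                    true_denaturant=float(d),
                    abundance=float(max(ab, config.abundance_min)),
                )
            )
        communities.append(Community(stage_label=stage, members=tuple(members)))
    return communities


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def _warp_interior_knots(gradient: GradientSpec) -> np.ndarray:
    """Interior warp knots, placed on a subset of the marker band positions
    so the marker-anchored piecewise-linear normalization model can
    represent the true distortion exactly."""
    marker = make_marker(gradient)
    pos = np.array(
        [denaturant_to_position(mm.true_denaturant, gradient) for mm in marker.members]
    )
    return pos[[1, 2, 4]]


def sample_warp(
    config: SimulationConfig, lane_index: int, n_lanes: int | None = None
) -> PiecewiseMap:
    """Monotone lane warp with fixed endpoints 0→0, 1→1.

    Two end-of-gel warps are drawn from the seed (interior-knot offsets
    uniform in ±``warp_amp``) and each lane's warp interpolates between
    them by lane index, modelling distortion that varies smoothly across
    the gel.  Deterministic per (config, lane_index).
    """
    if n_lanes is None:
        n_lanes = config.n_lanes
    interior = _warp_interior_knots(config.gradient)
    off_left = _rng(config, 101).uniform(-config.warp_amp, config.warp_amp, interior.size)
    off_right = _rng(config, 102).uniform(-config.warp_amp, config.warp_amp, interior.size)
    alpha = 0.0 if n_lanes <= 1 else lane_index / (n_lanes - 1)
    offsets = (1.0 - alpha) * off_left + alpha * off_right
    knots_in = np.concatenate(([0.0], interior, [1.0]))
    knots_out = np.concatenate(([0.0], interior + offsets, [1.0]))
    return PiecewiseMap(knots_in=knots_in, knots_out=knots_out)


def render_lane(
    community: Community,
    config: SimulationConfig,
    warp: PiecewiseMap | None = None,
    lane_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> LaneProfile:
    """Render a community into a densitometric lane profile.

    Each member contributes an abundance-scaled Gaussian of width
    ``band_sigma`` at the warped image of its melting position; a smooth
    half-cosine baseline (strongest at the well, as smearing is in
    practice) and additive Gaussian noise are superimposed and the trace
    clipped at zero.
    """
    g = config.gradient
    grid = np.linspace(0.0, 1.0, config.grid_n)
    signal = np.zeros_like(grid)
    for member in community.members:
        p = denaturant_to_position(member.true_denaturant, g)  # raises if outside
        center = warp(p) if warp is not None else p
        signal += member.abundance * np.exp(
            -0.5 * ((grid - center) / config.band_sigma) ** 2
        )
    baseline = config.baseline_amp * 0.5 * (1.0 + np.cos(np.pi * grid))
    if config.noise_sd > 0:
        if rng is None:
            salt = zlib.crc32((lane_id or community.stage_label).encode()) % (2**31)
            rng = _rng(config, 23, salt)
        signal = signal + rng.normal(0.0, config.noise_sd, grid.size)
    intensities = np.clip(signal + baseline, 0.0, None)
    return LaneProfile(
        lane_id=lane_id or community.stage_label,
        positions=grid,
        intensities=intensities,
        sample_meta=STAGE_META.get(community.stage_label),
        is_marker=community.stage_label == "marker",
    )


def simulate_gel(config: SimulationConfig) -> tuple[Gel, list[Fingerprint]]:
    """Render the full comparative gel and return it with its ground truth.

    Lane layout: marker, the seven ATAD stages in process order, and
    (by default) a second flanking marker.  Each lane gets its own warp
    from :func:`sample_warp`.  The ground-truth fingerprints record each
    planted band's *observed* (warped) position, its true denaturant and
    its abundance as height.
    """
    g = config.gradient
    marker = make_marker(g)
    communities = generate_succession(config)

    lane_plan: list[tuple[str, Community]] = [("M1", marker)]
    lane_plan += [(c.stage_label, c) for c in communities]
    if config.n_marker_lanes == 2:
        lane_plan.append(("M2", marker))

    lanes, truth = [], []
    for i, (lane_id, community) in enumerate(lane_plan):
        warp = sample_warp(config, i, n_lanes=len(lane_plan))
        lanes.append(render_lane(community, config, warp=warp, lane_id=lane_id))
        bands = sorted(
            (
                Band(
                    position=float(
                        np.clip(warp(denaturant_to_position(mm.true_denaturant, g)), 0, 1)
                    ),
                    height=mm.abundance,
                    denaturant=mm.true_denaturant,
                )
                for mm in community.members
            ),
            key=lambda b: b.position,
        )
        truth.append(
            Fingerprint(
                lane_id=lane_id,
                bands=bands,
                sample_meta=STAGE_META.get(community.stage_label),
                is_marker=community.stage_label == "marker",
            ).with_rel_intensity()
        )
    reference = sorted(mm.true_denaturant for mm in marker.members)
    return Gel(lanes=lanes, gradient=g, marker_reference=reference), truth
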