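"""End-to-end orchestration: simulate/load → detect → normalize → match →
indices → cluster, with config snapshotting and a run log.

Every run writes its intermediate artifacts to the output directory:

    profiles.tsv          lane intensity profiles
    ground_truth.csv      planted band table (synthetic runs only)
    marker_reference.txt  marker band denaturants, one per line
    bands_raw.csv         detected bands, gel coordinates
    bands_normalized.csv  detected bands, reference coordinates
    band_matrix.tsv       lanes × band classes (sample lanes)
    report.json           diversity report (per-lane indices, similarity,
                          moving-window curve, Δt, unique-band counts)
    tree.nwk              UPGMA dendrogram
    merges.csv            UPGMA merge table
    config.yaml           snapshot of the effective configuration
    run.log               all parameters and stage progress

A failed stage aborts with a stage-named error; artifacts written before
the failure are retained.  Runs are deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import yaml

from . import band_detection, clustering, diversity, model_io, normalization
from .band_detection import DetectionConfig
from .model_io import Gel, GradientSpec
from .synthetic_data import STAGES, SimulationConfig, simulate_gel

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "summarize"]

logger = logging.getLogger(__name__)

#: files every completed run must contain
RUN_ARTIFACTS = [
    "profiles.tsv",
    "bands_raw.csv",
    "bands_normalized.csv",
    "band_matrix.tsv",
    "report.json",
    "tree.nwk",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``simulation`` is set (synthetic run) or ``profiles_path`` +
    ``marker_reference`` describe real input profiles; ``marker_lanes``
    names the reference lanes in that case.  ``lane_order`` is the time
    series for the moving-window analysis and ``focal_lanes`` the subset
    for unique-band counting (defaults: the seven ATAD stages, and the
    two thermophilic lanes).
    """

    outdir: str = "dggekit_run"
    seed: int = 0
    gradient: GradientSpec = dataclasses.field(
        default_factory=lambda: GradientSpec(35.0, 75.0, "V3-V5 16S rDNA")
    )
    simulation: SimulationConfig | None = None
    profiles_path: str | None = None
    marker_lanes: list[str] = dataclasses.field(default_factory=lambda: ["M1", "M2"])
    marker_reference: list[float] | None = None
    detection: DetectionConfig = dataclasses.field(default_factory=DetectionConfig)
    tolerance: float = normalization.DEFAULT_TOLERANCE
    lane_order: list[str] | None = None
    focal_lanes: list[str] | None = None
    similarity_method: str = "dice"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.simulation is None and self.profiles_path is None:
            self.simulation = SimulationConfig(seed=self.seed, gradient=self.gradient)

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "outdir": str(self.outdir),
            "seed": self.seed,
            "gradient": {
                "low": self.gradient.low,
                "high": self.gradient.high,
                "label": self.gradient.label,
            },
            "profiles_path": self.profiles_path,
            "marker_lanes": list(self.marker_lanes),
            "marker_reference": self.marker_reference,
            "detection": dataclasses.asdict(self.detection),
            "tolerance": self.tolerance,
            "lane_order": self.lane_order,
            "focal_lanes": self.focal_lanes,
            "similarity_method": self.similarity_method,
            "log_level": self.log_level,
        }
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            sim["gradient"] = {
                "low": self.simulation.gradient.low,
                "high": self.simulation.gradient.high,
                "label": self.simulation.gradient.label,
            }
            d["simulation"] = sim
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def grad(g):
            return GradientSpec(g["low"], g["high"], g.get("label", ""))

        kwargs = dict(d)
        if "gradient" in kwargs:
            kwargs["gradient"] = grad(kwargs["gradient"])
        if kwargs.get("simulation") is not None:
            sim = dict(kwargs["simulation"])
            sim["gradient"] = grad(sim["gradient"])
            kwargs["simulation"] = SimulationConfig(**sim)
        if kwargs.get("detection") is not None:
            kwargs["detection"] = DetectionConfig(**kwargs["detection"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage, writing all artifacts to ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("dggekit")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(cfg.log_level)
    try:
        cfg.to_yaml(outdir / "config.yaml")
        logger.info("effective configuration: %s", json.dumps(cfg.to_dict(), sort_keys=True))

        gel, truth = _stage("input")(_load_or_simulate)(cfg, outdir)
        fps_raw = _stage("detect")(_detect)(cfg, gel, outdir)
        fps_norm = _stage("normalize")(_normalize)(cfg, gel, fps_raw, outdir)
        bm = _stage("match")(_match)(cfg, fps_norm, outdir)
        report = _stage("indices")(_indices)(cfg, bm, fps_norm, outdir)
        _stage("cluster")(_cluster)(cfg, bm, outdir)
        logger.info("run complete: Dt = %.4f", report.Dt)
    finally:
        root.removeHandler(handler)
        handler.close()
        root.setLevel(old_level)
    return outdir


def _load_or_simulate(cfg: RunConfig, outdir: Path):
    if cfg.simulation is not None:
        gel, truth = simulate_gel(cfg.simulation)
        model_io.write_profiles(gel, outdir / "profiles.tsv")
        model_io.write_band_table(truth, outdir / "ground_truth.csv")
        with open(outdir / "marker_reference.txt", "w") as fh:
            fh.writelines(f"{d:.6f}\n" for d in gel.marker_reference)
        return gel, truth
    gel = model_io.read_profiles(cfg.profiles_path, gradient=cfg.gradient)
    if cfg.marker_reference is None:
        raise ValueError("marker reference required (file input)")
    for lane in gel.lanes:
        lane.is_marker = lane.lane_id in cfg.marker_lanes
    gel.marker_reference = sorted(cfg.marker_reference)
    model_io.write_profiles(gel, outdir / "profiles.tsv")
    return gel, None


def _detect(cfg: RunConfig, gel: Gel, outdir: Path):
    logger.info("detection parameters: %s", dataclasses.asdict(cfg.detection))
    fps = band_detection.detect_gel(gel, cfg.detection)
    model_io.write_band_table(fps, outdir / "bands_raw.csv")
    return fps


def _normalize(cfg: RunConfig, gel: Gel, fps, outdir: Path):
    if gel.marker_reference is None:
        raise ValueError("no marker reference available")
    fps_norm = normalization.normalize_gel(fps, gel.marker_reference, cfg.gradient)
    model_io.write_band_table(fps_norm, outdir / "bands_normalized.csv")
    return fps_norm


def _match(cfg: RunConfig, fps_norm, outdir: Path):
    samples = [fp for fp in fps_norm if not fp.is_marker]
    bm = normalization.match_bands(samples, tolerance=cfg.tolerance)
    model_io.write_matrix(bm, outdir / "band_matrix.tsv")
    return bm


def _indices(cfg: RunConfig, bm, fps_norm, outdir: Path):
    order = cfg.lane_order or [s for s in STAGES if s in bm.lane_ids]
    if len(order) < 2:
        order = list(bm.lane_ids)
    focal = cfg.focal_lanes or [s for s in ("R2A_4h", "R2A_23h") if s in bm.lane_ids]
    if not focal:
        focal = list(order)
    report = diversity.build_report(
        bm, fps_norm, cfg.gradient, order=order, focal=focal,
        method=cfg.similarity_method,
    )
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, sort_keys=True, indent=2)
        fh.write("\n")
    return report


def _cluster(cfg: RunConfig, bm, outdir: Path):
    d, labels = clustering.distance_matrix(bm, method=cfg.similarity_method)
    tree = clustering.upgma(d, labels)
    (outdir / "tree.nwk").write_text(clustering.to_newick(tree) + "\n")
    with open(outdir / "merges.csv", "w") as fh:
        fh.write("cluster_a,cluster_b,height\n")
        for a, b, h in tree.merges:
            fh.write(f"{a},{b},{h:.9g}\n")
    return tree


def summarize(rundir) -> str:
    """Render a completed run as an aligned text table (per-lane S, H',
    Rr, Dg, unique bands; then the rate of change Δt)."""
    rundir = Path(rundir)
    missing = [a for a in RUN_ARTIFACTS if not (rundir / a).exists()]
    if missing:
        raise FileNotFoundError(
            f"incomplete run in {rundir}: missing {', '.join(missing)}"
        )
    with open(rundir / "report.json") as fh:
        report = json.load(fh)
    unique = report["unique_counts"]["per_lane"]
    header = f"{'lane':<10}{'S':>4}{'H_prime':>10}{'Rr':>10}{'Dg':>8}{'unique':>8}"
    lines = [header, "-" * len(header)]
    for lane in report["lane_ids"]:
        row = report["per_lane"][lane]
        uniq = str(unique[lane]) if lane in unique else "-"
        h = "-" if row["H_prime"] is None else f"{row['H_prime']:.4f}"
        lines.append(
            f"{lane:<10}{row['S']:>4}{h:>10}"
            f"{row['Rr']:>10.4f}{row['Dg']:>8.4f}{uniq:>8}"
        )
    lines.append(f"rate of change Dt = {report['Dt']:.4f}")
    return "\n".join(lines)
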