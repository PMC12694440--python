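"""End-to-end per-frame workflow: segment -> depth profile -> cutting pose.

`process_frame` is the in-memory core; `run_frame` / `run_batch` wrap it
with file I/O (PNG in, JSON/CSV out) for the command-line tool. All outputs
are pure functions of (inputs, configuration): no hidden state.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .depth import CanopyFrame, DepthFilterConfig, extract_l_values
from .errors import ConfigError, ParameterError
from .pose import DecisionTable, RigConfig, default_decision_table, pose_pipeline
from .regions import FAR_REGION, NEAR_REGION, RegionSpec
from .segmentation import Lighting, SegmentationConfig, segment_shoots

logger = logging.getLogger("teaprof")

#: Columns of the per-frame CSV log, version-stamped in the header comment.
CSV_SCHEMA = (
    "frame_id", "ag", "lighting", "l_near", "l_far",
    "d", "alpha", "delta_x", "vertical", "rotation",
    "fallback_near", "fallback_far",
)
CSV_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Bundle of every sub-configuration the pipeline needs."""

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    depth: DepthFilterConfig = field(default_factory=DepthFilterConfig)
    rig: RigConfig = field(default_factory=RigConfig)
    near_region: RegionSpec = NEAR_REGION
    far_region: RegionSpec = FAR_REGION
    decision_table: DecisionTable = field(default_factory=default_decision_table)
    force_class: Lighting | None = None

    def to_dict(self) -> dict:
        return {
            "segmentation": dataclasses.asdict(self.segmentation),
            "depth": dataclasses.asdict(self.depth),
            "rig": dataclasses.asdict(self.rig),
            "near_region": dataclasses.asdict(self.near_region),
            "far_region": dataclasses.asdict(self.far_region),
            "decision_table": self.decision_table.to_dict(),
            "force_class": self.force_class.value if self.force_class else None,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {
            "segmentation", "depth", "rig", "near_region",
            "far_region", "decision_table", "force_class",
        }
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown RunConfig keys: {sorted(unknown)}")
        kwargs: dict = {}
        try:
            if "segmentation" in data:
                kwargs["segmentation"] = SegmentationConfig(**data["segmentation"])
            if "depth" in data:
                kwargs["depth"] = DepthFilterConfig(**data["depth"])
            if "rig" in data:
                kwargs["rig"] = RigConfig(**data["rig"])
            if "near_region" in data:
                kwargs["near_region"] = RegionSpec(**data["near_region"])
            if "far_region" in data:
                kwargs["far_region"] = RegionSpec(**data["far_region"])
            if "decision_table" in data:
                kwargs["decision_table"] = DecisionTable.from_dict(data["decision_table"])
            if data.get("force_class"):
                kwargs["force_class"] = Lighting(data["force_class"])
        except TypeError as exc:
            raise ConfigError(f"malformed RunConfig: {exc}") from exc
        return cls(**kwargs)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class FrameReport:
    """Everything the pipeline derived from one frame."""

    frame_id: str
    ag: float
    lighting: str
    otsu_foreground_fraction: float
    l_near: float
    l_far: float
    d: float
    alpha: float
    delta_x: float
    vertical: str
    rotation: str
    fallback_near: bool
    fallback_far: bool

    def to_json_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_csv_row(self) -> str:
        vals = [
            self.frame_id, f"{self.ag:.4f}", self.lighting,
            f"{self.l_near:.4f}", f"{self.l_far:.4f}",
            f"{self.d:.4f}", f"{self.alpha:.4f}", f"{self.delta_x:.4f}",
            self.vertical, self.rotation,
            str(int(self.fallback_near)), str(int(self.fallback_far)),
        ]
        return ",".join(vals)


def process_frame(frame: CanopyFrame, config: RunConfig | None = None) -> tuple[FrameReport, np.ndarray]:
    """Run segmentation, depth profiling and pose computation on one frame.

    Returns the report and the shoot mask (boolean array).
    """
    config = config or RunConfig()
    mask = segment_shoots(frame.rgb, config.segmentation, force_class=config.force_class)
    l_near, l_far, info = extract_l_values(
        frame, mask, config.near_region, config.far_region, config.depth
    )
    pose, decision = pose_pipeline(config.rig, config.decision_table, l_near, l_far)
    report = FrameReport(
        frame_id=frame.frame_id,
        ag=mask.source_lighting.ag_value,
        lighting=mask.source_lighting.label.value,
        otsu_foreground_fraction=float(mask.pixels.mean()),
        l_near=l_near,
        l_far=l_far,
        d=pose.d,
        alpha=pose.alpha,
        delta_x=pose.delta_x,
        vertical=decision.vertical.value,
        rotation=decision.rotation.value,
        fallback_near=info["fallback"]["near"],
        fallback_far=info["fallback"]["far"],
    )
    logger.debug("frame %s: %s", frame.frame_id, report)
    return report, mask.pixels


def load_frame(rgb_path: str | Path, depth_path: str | Path) -> CanopyFrame:
    """Read a pixel-aligned RGB PNG + 16-bit depth PNG pair."""
    rgb = iio.imread(rgb_path)
    depth = iio.imread(depth_path)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ParameterError(f"{rgb_path}: expected an RGB image")
    rgb = rgb[..., :3]
    if depth.ndim != 2:
        raise ParameterError(f"{depth_path}: expected a single-channel depth raster")
    return CanopyFrame(rgb=rgb, depth=depth.astype(np.uint16), frame_id=Path(rgb_path).stem)


def _append_csv(path: Path, report: FrameReport) -> None:
    if not path.exists():
        header = f"# teaprof frame log v{CSV_VERSION}\n" + ",".join(CSV_SCHEMA) + "\n"
        path.write_text(header)
    with path.open("a") as fh:
        fh.write(report.to_csv_row() + "\n")


def run_frame(
    rgb_path: str | Path,
    depth_path: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> FrameReport:
    """File-level single-frame run: writes mask PNG, report JSON, CSV log row."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = load_frame(rgb_path, depth_path)
    report, mask = process_frame(frame, config)
    stem = frame.frame_id
    iio.imwrite(out_dir / f"{stem}.mask.png", mask.astype(np.uint8) * 255)
    (out_dir / f"{stem}.report.json").write_text(json.dumps(report.to_json_dict(), indent=2))
    _append_csv(out_dir / "frames.csv", report)
    return report


def run_batch(
    pairs: list[tuple[str | Path, str | Path]],
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> dict:
    """Process many frame pairs, continuing past per-frame failures.

    Returns a summary dict with per-frame reports, recorded failures, the
    mean absolute height adjustment and a decision histogram.
    """
    if not pairs:
        raise ParameterError("empty batch manifest")
    reports: list[FrameReport] = []
    failures: list[dict] = []
    for rgb_path, depth_path in pairs:
        try:
            reports.append(run_frame(rgb_path, depth_path, out_dir, config))
        except Exception as exc:  # recorded, not raised: the batch must finish
            failures.append({"rgb": str(rgb_path), "error": f"{type(exc).__name__}: {exc}"})
            logger.warning("frame %s failed: %s", rgb_path, exc)
    histogram: dict[str, int] = {}
    for rep in reports:
        key = f"{rep.vertical}/{rep.rotation}"
        histogram[key] = histogram.get(key, 0) + 1
    summary = {
        "n_frames": len(pairs),
        "n_ok": len(reports),
        "failures": failures,
        "mean_abs_d": float(np.mean([abs(r.d) for r in reports])) if reports else None,
        "decision_histogram": histogram,
        "reports": [r.to_json_dict() for r in reports],
    }
    out = Path(out_dir) / "batch_summary.json"
    out.write_text(json.dumps(summary, indent=2))
    return summary
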