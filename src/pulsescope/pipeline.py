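"""End-to-end orchestration: simulate → project → trace → NPQ → features → PCA.

A run starts either from a simulated scene (with ground truth) or from a
user-supplied stack plus ROI labels, and writes every stage's output under
one directory together with a machine-readable JSON manifest (paths,
SHA-256 checksums, parameter echo, package version).  Rerunning the same
config and seed reproduces the checksums of all deterministic artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .features_pca import drop_incomplete, principal_components, standardize
from .photoparams import FEATURE_COLUMNS, compute_npq_series, extract_features
from .protocol_io import (
    AcquisitionStack,
    ProtocolTimeline,
    build_timeline,
    read_stack,
    sum_project,
    write_stack,
)
from .segmentation3d import (
    area_fraction,
    integrate_fluorescence,
    median_filter3d,
    segment_objects,
)
from .synthetic import GroundTruth, Kinetics, NoiseParams, BackgroundParams, SceneParams, render_scene
from .traces import Roi, mean_gray, rois_from_labels, subtract_background, traces_to_frame

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "scene_from_dict", "load_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class TimelineSpec:
    n_dark: int = 3
    n_light: int = 6
    n_relax: int = 6
    interval_s: float = 60.0
    actinic_umol: float = 500.0

    def build(self) -> ProtocolTimeline:
        return build_timeline(
            self.n_dark, self.n_light, self.n_relax, self.interval_s, self.actinic_umol
        )


@dataclass
class StackInput:
    """User-supplied acquisition: stack path, optional metadata sidecar,
    ROI label image and role map; exactly one background ROI is required."""

    stack: str
    sidecar: str | None = None
    roi_labels: str | None = None
    roi_roles: str | None = None


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    timeline: TimelineSpec = field(default_factory=TimelineSpec)
    scene: SceneParams | None = None
    input: StackInput | None = None
    run_pca: bool = True

    def __post_init__(self) -> None:
        if (self.scene is None) == (self.input is None):
            raise ValueError(
                "config must declare exactly one input source: 'scene' or 'input'"
            )


def scene_from_dict(d: dict) -> SceneParams:
    """Build SceneParams (nested kinetics/noise/background) from plain dicts."""
    d = dict(d)
    kw: dict = {}
    if "kinetics" in d:
        kw["kinetics"] = Kinetics(**d.pop("kinetics"))
    if "noise" in d:
        kw["noise"] = NoiseParams(**d.pop("noise"))
    if "background" in d:
        kw["background"] = BackgroundParams(**d.pop("background"))
    for tup in ("shape", "voxel_size"):
        if tup in d:
            d[tup] = tuple(d[tup])
    return SceneParams(**d, **kw)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML/JSON run config."""
    import yaml

    d = yaml.safe_load(Path(path).read_text())
    kw: dict = {"out_dir": d["out_dir"], "seed": int(d.get("seed", 0))}
    if "timeline" in d:
        kw["timeline"] = TimelineSpec(**d["timeline"])
    if "scene" in d:
        kw["scene"] = scene_from_dict(d["scene"] or {})
    if "input" in d:
        kw["input"] = StackInput(**d["input"])
    if "run_pca" in d:
        kw["run_pca"] = bool(d["run_pca"])
    return RunConfig(**kw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _estimate_area_frac(
    stack: AcquisitionStack, cell_masks: dict[str, np.ndarray]
) -> dict[str, float]:
    """AreaFrac per cell from a segmentation of the first (dark) frame."""
    vol = median_filter3d(stack.data[0].astype(float), radius=1)
    labeled = segment_objects(vol, threshold=None, min_voxels=8)
    plastid_fp = (labeled.labels > 0).any(axis=0)
    out = {}
    for name, mask in cell_masks.items():
        out[name] = area_fraction(mask, plastid_fp & mask)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def record(name: str, path: Path) -> None:
        files[name] = str(path.relative_to(out))

    timeline = config.timeline.build()
    timeline.to_json(out / "timeline.json")
    record("timeline", out / "timeline.json")

    truth: GroundTruth | None = None
    if config.scene is not None:
        scene = replace(config.scene, seed=config.seed)

        @_stage("simulate")
        def _simulate():
            return render_scene(scene, timeline)

        stack, truth = _simulate()
        write_stack(out / "stack.ome.tif", stack)
        truth.to_json(out / "ground_truth.json")
        record("stack", out / "stack.ome.tif")
        record("ground_truth", out / "ground_truth.json")
        cell_masks = {
            f"cell{ci + 1}": truth.cell_footprints[ci]
            for ci in range(truth.cell_footprints.shape[0])
        }
        background_mask = truth.background_mask
    else:

        @_stage("read")
        def _read():
            return read_stack(config.input.stack, config.input.sidecar)

        stack = _read()
        if config.input.roi_labels is None:
            raise PipelineError("stage 'read' failed: stack input requires roi_labels")
        rois = rois_from_labels(config.input.roi_labels, config.input.roi_roles)
        cell_masks = {r.label: r.mask for r in rois if r.role == "object"}
        bg = [r for r in rois if r.role == "background"]
        if len(bg) != 1:
            raise PipelineError(
                "stage 'read' failed: exactly one background ROI is required"
            )
        background_mask = bg[0].mask

    @_stage("project")
    def _project():
        return sum_project(stack)

    series = _project()
    series.write_tiff(out / "projected.tif")
    record("projected", out / "projected.tif")

    @_stage("trace")
    def _trace():
        bg_roi = Roi("background", background_mask, role="background")
        bg_trace = mean_gray(series, bg_roi)
        raw, corrected = [], {}
        for name, mask in cell_masks.items():
            tr = mean_gray(series, Roi(name, mask))
            raw.append(tr)
            corrected[name] = subtract_background(tr, bg_trace)
        return raw, bg_trace, corrected

    raw_traces, bg_trace, corrected = _trace()
    traces_df = traces_to_frame(raw_traces, bg_trace)
    traces_df.to_csv(out / "traces.csv", index=False)
    record("traces", out / "traces.csv")

    @_stage("npq")
    def _npq():
        return {name: compute_npq_series(tr, timeline) for name, tr in corrected.items()}

    npq_results = _npq()
    npq_rows = []
    for name, res in npq_results.items():
        for i, t in enumerate(res.timestamps):
            npq_rows.append(
                {"roi_label": name, "timestamp_s": t, "NPQ": res.npq[i], "Fm_dark": res.Fm_dark}
            )
    pd.DataFrame(npq_rows).to_csv(out / "npq.csv", index=False)
    record("npq", out / "npq.csv")

    @_stage("features")
    def _features():
        area = _estimate_area_frac(stack, cell_masks)
        feats = {
            name: extract_features(res, timeline, area_frac=area.get(name, float("nan")))
            for name, res in npq_results.items()
        }
        return pd.DataFrame({n: f.as_series() for n, f in feats.items()}).T

    features_df = _features()
    features_df.index.name = "cell"
    features_df.to_csv(out / "features.csv")
    record("features", out / "features.csv")

    if config.run_pca and len(features_df) >= 3:

        @_stage("pca")
        def _pca():
            complete = drop_incomplete(features_df)
            return principal_components(standardize(complete))

        try:
            pca = _pca()
        except PipelineError as exc:
            logger.warning("PCA skipped: %s", exc)
        else:
            pca.loadings.to_csv(out / "pca_loadings.csv")
            pca.scores.to_csv(out / "pca_scores.csv")
            pd.DataFrame(
                {
                    "component": pca.loadings.columns,
                    "explained_variance_pct": pca.explained_variance_pct,
                }
            ).to_csv(out / "pca_explained.csv", index=False)
            for name in ("pca_loadings", "pca_scores", "pca_explained"):
                record(name, out / f"{name}.csv")

    manifest = {
        "package": "pulsescope",
        "version": __version__,
        "seed": config.seed,
        "config": _config_echo(config),
        "files": {name: {"path": rel, "sha256": _sha256(out / rel)} for name, rel in files.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _config_echo(config: RunConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        return obj

    return clean(config)
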