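"""End-to-end orchestration of the segmentation pipelines.

``run_single_atlas`` pre-processes both subjects (fat homogenisation),
registers the reference to the target, and propagates the reference's manual
labels through the field; ``run_multi_atlas`` repeats this for several
references and fuses the candidates.  Every run emits a
:class:`RunManifest` capturing the configuration snapshot, the seeds, input
digests and per-stage timings, so deterministic stages are reproducible from
the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import time
import tomllib
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .errors import MuscleRegError
from .multiatlas import fuse
from .preprocess_fat import PreprocessConfig, homogenise_fat
from .registration import (
    NodeDisplacementField,
    RegistrationConfig,
    register,
    warp_image,
    warp_labels,
)
from .seg_metrics import SegmentationReport, evaluate
from .volumes_io import GreyVolume, LabelVolume

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "SingleAtlasResult",
    "MultiAtlasResult",
    "run_single_atlas",
    "run_multi_atlas",
]


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    fusion_window_voxels: int = 25
    fusion_agreement_threshold: float = 1.0

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        pre = PreprocessConfig(**raw.get("preprocess", {}))
        reg_raw = dict(raw.get("registration", {}))
        if "smoothing_sweep" in reg_raw:
            reg_raw["smoothing_sweep"] = tuple(reg_raw["smoothing_sweep"])
        reg = RegistrationConfig(**reg_raw)
        fus = raw.get("fusion", {})
        return cls(
            preprocess=pre,
            registration=reg,
            fusion_window_voxels=int(fus.get("window_voxels", 25)),
            fusion_agreement_threshold=float(fus.get("agreement_threshold", 1.0)),
        )

    def snapshot(self) -> dict:
        return asdict(self)


def _digest(vol: GreyVolume | LabelVolume) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(vol.data).tobytes())
    h.update(np.asarray(vol.spacing, dtype=float).tobytes())
    h.update(np.asarray(vol.origin, dtype=float).tobytes())
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    tool_version: str
    config: dict
    inputs: dict[str, str]
    seeds: dict[str, int]
    timings_s: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    stages: list[str] = field(default_factory=list)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


class StageError(MuscleRegError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


@dataclass
class SingleAtlasResult:
    labels: LabelVolume
    registered: GreyVolume
    field: NodeDisplacementField
    report: SegmentationReport | None
    manifest: RunManifest


@dataclass
class MultiAtlasResult:
    labels: LabelVolume
    report: SegmentationReport | None
    manifest: RunManifest
    per_reference: list[SingleAtlasResult]


def _stage(manifest: RunManifest, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            manifest.timings_s[name] = round(time.perf_counter() - self.t0, 4)
            manifest.stages.append(name)
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            return False

    return _Timer()


def run_single_atlas(
    target: GreyVolume,
    reference: GreyVolume,
    reference_labels: LabelVolume,
    config: PipelineConfig | None = None,
    target_manual: LabelVolume | None = None,
    preprocess: bool = True,
) -> SingleAtlasResult:
    """Segment ``target`` by propagating ``reference_labels`` through a
    reference-to-target registration.

    Both volumes are fat-homogenised first (set ``preprocess=False`` for
    augmentation-style runs).  If ``target_manual`` is supplied the result
    includes an evaluation report.
    """
    config = config or PipelineConfig()
    manifest = RunManifest(
        tool_version=__version__,
        config=config.snapshot(),
        inputs={
            "target": _digest(target),
            "reference": _digest(reference),
            "reference_labels": _digest(reference_labels),
        },
        seeds={"preprocess": config.preprocess.seed},
    )
    if preprocess:
        with _stage(manifest, "preprocess"):
            target_p, _ = homogenise_fat(target, config.preprocess)
            reference_p, _ = homogenise_fat(reference, config.preprocess)
    else:
        target_p, reference_p = target, reference
    with _stage(manifest, "register"):
        field_ = register(target_p, reference_p, config.registration)
    with _stage(manifest, "warp"):
        labels = warp_labels(reference_labels, field_)
        registered = warp_image(reference_p, field_)
    report = None
    if target_manual is not None:
        with _stage(manifest, "evaluate"):
            report = evaluate(labels, target_manual)
    return SingleAtlasResult(
        labels=labels, registered=registered, field=field_, report=report, manifest=manifest
    )


def run_multi_atlas(
    target: GreyVolume,
    references: list[tuple[GreyVolume, LabelVolume]],
    config: PipelineConfig | None = None,
    target_manual: LabelVolume | None = None,
) -> MultiAtlasResult:
    """Segment ``target`` from several references and fuse the candidates."""
    if len(references) < 2:
        raise ValueError("multi-atlas runs need at least two references")
    config = config or PipelineConfig()
    manifest = RunManifest(
        tool_version=__version__,
        config=config.snapshot(),
        inputs={"target": _digest(target)},
        seeds={"preprocess": config.preprocess.seed},
    )
    with _stage(manifest, "preprocess_target"):
        target_p, _ = homogenise_fat(target, config.preprocess)
    results = []
    for i, (ref_img, ref_lab) in enumerate(references):
        manifest.inputs[f"reference_{i}"] = _digest(ref_img)
        with _stage(manifest, f"register_{i}"):
            ref_p, _ = homogenise_fat(ref_img, config.preprocess)
            field_ = register(target_p, ref_p, config.registration)
            labels = warp_labels(ref_lab, field_)
            registered = warp_image(ref_p, field_)
        results.append(
            SingleAtlasResult(
                labels=labels,
                registered=registered,
                field=field_,
                report=None,
                manifest=manifest,
            )
        )
    with _stage(manifest, "fuse"):
        fused = fuse(
            [r.labels for r in results],
            [r.registered for r in results],
            target_p,
            window_voxels=config.fusion_window_voxels,
            agreement_threshold=config.fusion_agreement_threshold,
        )
    report = None
    if target_manual is not None:
        with _stage(manifest, "evaluate"):
            report = evaluate(fused, target_manual)
    return MultiAtlasResult(labels=fused, report=report, manifest=manifest, per_reference=results)
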