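"""Pipeline orchestration, configuration and file I/O.

Ties the stages together: candidate detection -> feature extraction ->
ensemble classification -> vessel-map false-positive removal -> centerline
extraction and gap filling (segmentation workflow), and gantry
initialization -> tip stage -> full refinement (calibration workflow).
Artifacts use plain formats: PNG/TIFF frames, CSV centerlines and feature
tables, JSON geometry and models, YAML configuration.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from cathcalib import calibration as cal
from cathcalib import classifier as clf
from cathcalib import features as feat
from cathcalib import geometry as geo
from cathcalib import indicators as ind
from cathcalib import postprocess as post

__all__ = [
    "PipelineConfig",
    "SegmentationOutput",
    "segment_frame",
    "run_segmentation",
    "run_calibration",
    "read_frame",
    "write_frame",
    "write_mask",
    "read_mask",
    "write_centerline",
    "read_centerline",
    "write_geometry",
    "read_geometry",
    "write_model",
    "read_model",
    "write_events",
    "write_features",
]

DEFAULT_PIXEL_SPACING = 0.154  # mm/px, used when a file carries no spacing


@dataclass
class PipelineConfig:
    """All tunable defaults of the pipeline, schema-versioned."""

    schema_version: int = 1
    candidate_threshold: float = ind.DEFAULT_THRESHOLD
    indicator_weights: tuple[float, float, float] = ind.DEFAULT_WEIGHTS
    combine_window: int = 5
    curvature_window: int = 7
    patch_size: int = 11
    neighborhood_px: int = ind.NEIGHBORHOOD
    b_cutoff: float = post.B_CUTOFF
    vote_threshold: int = 1
    spur_length_px: int = 10
    max_gap_px: float = 50.0
    n_learners: int = clf.DEFAULT_N_LEARNERS
    learning_rate: float = clf.DEFAULT_LEARNING_RATE
    holdout_fraction: float = 0.25
    epipolar_limit_px: float = cal.EPIPOLAR_LIMIT
    jump_limit_px: float = cal.JUMP_LIMIT
    n_samples_view1: int = cal.N_SAMPLES_VIEW1
    n_samples_view2: int = cal.N_SAMPLES_VIEW2
    pixel_spacing: float = DEFAULT_PIXEL_SPACING
    seed: int = 0

    def validate(self) -> None:
        if self.schema_version != 1:
            raise ValueError(f"unsupported config schema {self.schema_version}")
        w = np.asarray(self.indicator_weights, float)
        if abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("indicator weights must sum to 1")
        for name in ("candidate_threshold", "b_cutoff", "learning_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["indicator_weights"] = list(self.indicator_weights)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class SegmentationOutput:
    """Per-frame artifacts of the segmentation workflow."""

    candidate_masks: list[ind.CandidateMask]
    predicted_masks: list[np.ndarray]
    final_masks: list[np.ndarray]
    centerlines: list[post.CatheterCenterline | None]
    event_counts: list[dict] = field(default_factory=list)


def _events_to_mask(
    events: list[ind.EventRegion],
    keep: np.ndarray,
    shape: tuple[int, int],
    neighborhood: int = 2,
) -> np.ndarray:
    """Rasterize kept events: core runs dilated by a +/-2 px margin in both
    axes.  Candidate detection uses the generous 5-px recall margin, but the
    segmentation raster should stay at catheter width (at most 5 px) so the
    skeleton does not merge across nearby structures."""
    from scipy.ndimage import grey_dilation

    mask = np.zeros(shape, dtype=bool)
    for ev, k in zip(events, keep):
        if not k:
            continue
        if ev.axis == "row":
            mask[ev.line, ev.start : ev.end + 1] = True
        else:
            mask[ev.start : ev.end + 1, ev.line] = True
    if not mask.any():
        return mask
    size = 2 * neighborhood + 1
    return grey_dilation(mask, size=(size, size)).astype(bool)


def segment_frame(
    frame: np.ndarray,
    model,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[ind.CandidateMask, np.ndarray]:
    """Candidate detection + classification of one frame.

    ``model`` is a :class:`~cathcalib.classifier.TrainedEnsemble`, a callable
    mapping the event list to boolean labels (e.g. an oracle in harness
    tests), or None (keep every candidate).
    """
    cand = ind.candidate_mask(
        frame, threshold=config.candidate_threshold, weights=config.indicator_weights
    )
    if not cand.events:
        return cand, np.zeros(np.asarray(frame).shape, dtype=bool)
    if model is None:
        keep = np.ones(len(cand.events), dtype=bool)
    elif callable(model) and not isinstance(model, clf.TrainedEnsemble):
        keep = np.asarray(model(cand.events), dtype=bool)
    else:
        x, _ = feat.extract_event_features(frame, cand.events)
        _, keep = clf.predict(model, x)
    return cand, _events_to_mask(cand.events, keep, np.asarray(frame).shape)


def run_segmentation(
    frames: list[np.ndarray],
    model,
    sequence: np.ndarray | None = None,
    landmarks: list[tuple[np.ndarray, np.ndarray]] | None = None,
    physical_length_mm: float | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> SegmentationOutput:
    """Full segmentation workflow over a list of frames.

    When a contrast ``sequence`` is given, a vessel map is built from it and
    detections outside the map are removed.  When per-frame ``landmarks``
    (two image points each) are given, centerlines are clipped to them and
    carry ``physical_length_mm``.
    """
    config.validate()
    vessel = None
    if sequence is not None:
        dsa = post.dsa_subtract(sequence)
        eligible = []
        for f in dsa:
            post.fit_histogram_gaussian(f)
            if not f.discarded:
                eligible.append(f)
        if eligible:
            binaries = [post.kmeans_vessel_segment(f) for f in eligible]
            vessel = post.build_vessel_map(
                binaries, vote_threshold=config.vote_threshold,
                frames_used=[f.frame_index for f in eligible],
            )
        else:
            warnings.warn("no eligible contrast frames; skipping vessel map", stacklevel=2)

    cands, pred_masks, final_masks, centerlines, counts = [], [], [], [], []
    for i, frame in enumerate(frames):
        cand, pred = segment_frame(frame, model, config)
        final = post.remove_false_positives(pred, vessel) if vessel is not None else pred
        centerline = None
        if final.any():
            comps = post.extract_centerline(final, spur_length=config.spur_length_px)
            if comps:
                try:
                    centerline = post.fill_gaps(
                        comps, max_gap=config.max_gap_px,
                        pixel_spacing=config.pixel_spacing,
                    )
                except ValueError:
                    centerline = None
        if centerline is not None and landmarks is not None:
            pa, pb = landmarks[i]
            try:
                centerline = post.clip_to_landmarks(
                    centerline, pa, pb, physical_length_mm or 0.0
                )
            except ValueError as exc:
                warnings.warn(f"frame {i}: landmark clipping failed: {exc}", stacklevel=2)
        cands.append(cand)
        pred_masks.append(pred)
        final_masks.append(final)
        centerlines.append(centerline)
        counts.append(
            {"frame": i, "events": len(cand.events), "kept_px": int(final.sum())}
        )
    return SegmentationOutput(cands, pred_masks, final_masks, centerlines, counts)


def segmentation_benchmark(
    n_train: int = 10,
    n_test: int = 5,
    seed: int = 0,
    config: PipelineConfig = PipelineConfig(),
    boost: clf.BoostConfig | None = None,
):
    """Event-classification benchmark on synthetic angiograms.

    Renders ``n_train`` + ``n_test`` frames (one view per scene, distinct
    scene seeds derived from ``seed``), extracts candidate events, features
    and ground-truth labels, trains the GentleBoost ensemble on the training
    events and evaluates on the held-out frames.

    Returns ``(metrics, model, n_test_events)``.
    """
    from cathcalib import synthetic as syn

    boost = boost or clf.BoostConfig(config.n_learners, config.learning_rate, seed)

    def frame_events(scene_seed):
        scene = syn.generate_scene(scene_seed)
        v1, _, _ = syn.render_views(scene)
        cand = ind.candidate_mask(
            v1.image, threshold=config.candidate_threshold,
            weights=config.indicator_weights,
        )
        x, _ = feat.extract_event_features(v1.image, cand.events)
        y = syn.label_events(cand.events, v1.truth.catheter_mask)
        return x, y

    xs, ys = [], []
    for i in range(n_train + n_test):
        x, y = frame_events(seed * 1000 + i)
        xs.append(x)
        ys.append(y)
    x_train = np.vstack(xs[:n_train])
    y_train = np.concatenate(ys[:n_train])
    x_test = np.vstack(xs[n_train:])
    y_test = np.concatenate(ys[n_train:])
    model = clf.train_ensemble(x_train, y_train, boost, feature_names=list(feat.FEATURE_NAMES))
    _, pred = clf.predict(model, x_test)
    metrics = clf.evaluate(pred, y_test)
    return metrics, model, len(y_test)


def run_calibration(
    centerline1: post.CatheterCenterline,
    centerline2: post.CatheterCenterline,
    intr: tuple[geo.CameraIntrinsics, geo.CameraIntrinsics],
    poses: tuple[geo.GantryPose, geo.GantryPose],
    image_shape: tuple[int, int] | None = None,
    config: PipelineConfig = PipelineConfig(),
    bounds: cal.ParameterBounds = cal.ParameterBounds(),
    use_jump_criterion: bool = True,
) -> cal.CalibrationResult:
    """Full calibration workflow: initialize -> tip stage -> full stage."""
    params0 = cal.initialize_from_gantry(intr[0], intr[1], poses[0], poses[1], image_shape)
    tips1 = cal._landmark_points(centerline1)
    tips2 = cal._landmark_points(centerline2)
    length = centerline1.physical_length_mm or centerline2.physical_length_mm
    params1 = cal.optimize_tips(params0, tips1, tips2, bounds, physical_length_mm=length)

    def refine(start):
        return cal.optimize_full(
            start, centerline1, centerline2, bounds,
            n_samples1=config.n_samples_view1, n_samples2=config.n_samples_view2,
            use_jump_criterion=use_jump_criterion, params_before=params0,
        )

    # multi-start: the tip stage is a heuristic initialization and can land
    # the refinement in a poorer basin than the gantry record itself; the
    # second start (the raw record) runs unless the first fit is already
    # excellent
    first = refine(params1)
    if first.status == "converged" and first.error_after_px < 0.05:
        return first
    candidates = [first, refine(params0)]
    candidates.sort(key=lambda r: (r.status != "converged", r.error_after_px))
    return candidates[0]


# ---------------------------------------------------------------------------
# file I/O

def read_frame(path: str | Path, pixel_spacing: float = DEFAULT_PIXEL_SPACING):
    """Read a grayscale frame (PNG/TIFF/DICOM), normalized to [0, 1].

    Returns (image, pixel_spacing_mm).  16-bit rasters are scaled by the
    dtype maximum; DICOM spacing/gantry tags are honoured when present, else
    the configured default spacing applies with a warning.
    """
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(str(path))
        img = ds.pixel_array.astype(float)
        img = (img - img.min()) / max(img.max() - img.min(), 1e-12)
        spacing = pixel_spacing
        if getattr(ds, "ImagerPixelSpacing", None):
            spacing = float(ds.ImagerPixelSpacing[0])
        elif getattr(ds, "PixelSpacing", None):
            spacing = float(ds.PixelSpacing[0])
        else:
            warnings.warn(
                f"DICOM without pixel spacing: using default {pixel_spacing} mm",
                stacklevel=2,
            )
        return img, spacing
    img = np.asarray(iio.imread(path)).astype(float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.max() > 1.0:
        maxval = float(np.iinfo(np.uint16).max if img.max() > 255 else np.iinfo(np.uint8).max)
        img = img / maxval
    return img, pixel_spacing


def write_frame(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 16-bit PNG/TIFF."""
    arr = np.clip(np.asarray(image, float), 0, 1)
    iio.imwrite(Path(path), (arr * np.iinfo(np.uint16).max).astype(np.uint16))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 127


def write_centerline(path: str | Path, c: post.CatheterCenterline) -> None:
    lm = set(c.landmark_indices or ())
    df = pd.DataFrame(
        {
            "index": np.arange(len(c)),
            "u": c.points[:, 0],
            "v": c.points[:, 1],
            "arclength_px": c.arclength_px,
            "arclength_mm": c.arclength_mm,
            "is_landmark": [i in lm for i in range(len(c))],
        }
    )
    df.attrs["pixel_spacing"] = c.pixel_spacing
    df.to_csv(path, index=False)


def read_centerline(
    path: str | Path,
    pixel_spacing: float = DEFAULT_PIXEL_SPACING,
    physical_length_mm: float | None = None,
) -> post.CatheterCenterline:
    df = pd.read_csv(path)
    for col in ("u", "v"):
        if col not in df:
            raise ValueError(f"centerline file {path} missing column '{col}'")
    lm = None
    if "is_landmark" in df and df["is_landmark"].any():
        idx = np.nonzero(df["is_landmark"].to_numpy())[0]
        if len(idx) >= 2:
            lm = (int(idx[0]), int(idx[-1]))
    return post.CatheterCenterline(
        points=df[["u", "v"]].to_numpy(float),
        pixel_spacing=pixel_spacing,
        landmark_indices=lm,
        physical_length_mm=physical_length_mm,
    )


def write_geometry(
    path: str | Path,
    geom: geo.BiplaneGeometry,
    pose1: geo.GantryPose | None = None,
    pose2: geo.GantryPose | None = None,
) -> None:
    with open(path, "w") as fh:
        json.dump(geo.geometry_to_dict(geom, pose1, pose2), fh, indent=1)


def read_geometry(path: str | Path):
    with open(path) as fh:
        return geo.geometry_from_dict(json.load(fh))


def write_model(path: str | Path, model: clf.TrainedEnsemble) -> None:
    Path(path).write_text(model.to_json())


def read_model(path: str | Path) -> clf.TrainedEnsemble:
    return clf.TrainedEnsemble.from_json(Path(path).read_text())


def write_events(path: str | Path, events: list[ind.EventRegion]) -> None:
    pd.DataFrame(
        [(e.axis, e.line, e.start, e.end) for e in events],
        columns=["axis", "line", "start", "end"],
    ).to_csv(path, index=False)


def write_features(
    path: str | Path, features: np.ndarray, frame_ids, event_ids
) -> None:
    df = pd.DataFrame(np.atleast_2d(features), columns=list(feat.FEATURE_NAMES))
    df.insert(0, "frame_id", frame_ids)
    df.insert(1, "event_id", event_ids)
    df.to_csv(path, index=False)


def write_manifest(path: str | Path, config: PipelineConfig, extra: dict | None = None) -> None:
    """Reproducibility manifest: config hash, seed, package version."""
    from cathcalib import __version__

    d = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "config": asdict(config),
    }
    if extra:
        d.update(extra)
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1, default=str)
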