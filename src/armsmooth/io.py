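"""File formats, configuration and end-to-end orchestration.

Recordings travel as one CSV per sensor (columns ``t, ax, ay, az,
r11 … r33``, row-major rotation entries, header required), a YAML session
manifest tying the four sensor files to subject/session/observer metadata,
and a JSON ground-truth sidecar for synthetic data (segment boundaries,
mid-elevation timesteps, injected saccade counts).  ``run_pipeline`` drives
the full chain: subject frame → kinematics → semi-supervised segmentation →
phase jerks → reliability and comparison statistics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import segmentation as seg
from . import stats as st
from .errors import FormatError, InvalidArgumentError, SampleRateMismatchError
from .jerk import phase_jerks
from .kinematics import SensorRecording, build_subject_frame, compute_kinematics, lowpass
from .synthetic import GroundTruth, MovementRecording, Session

log = logging.getLogger("armsmooth")

SENSOR_IDS = ("right", "left", "head", "back")
_CSV_COLUMNS = ["t", "ax", "ay", "az"] + [
    f"r{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)
]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with the protocol defaults."""

    filter_order: int = 4
    cutoff_hz: float = 10.0
    n_segments: int = 7
    min_dur_s: float = 1.0
    max_dur_s: float = 20.0
    smooth_s: float = 0.2
    midpoint_w: int = 100
    sym_combine: str = "rss"
    jerk_fusion: str = "rss"
    jerk_physical: bool = False
    label_fraction: float = 0.2
    alpha_levels: tuple = (0.05, 0.01)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["alpha_levels"] = list(d["alpha_levels"])
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class SessionManifest:
    """Metadata tying one session's sensor files together."""

    subject_id: str
    session_index: int
    observer_id: str
    fs: float
    movements: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be positive")


# ---------------------------------------------------------------------------
# recording CSV dialect


def write_recording(path, recording: SensorRecording) -> None:
    """Write one sensor recording in the pipeline CSV dialect."""
    T = len(recording)
    t = np.arange(T) / recording.fs
    flat = recording.orient.reshape(T, 9)
    df = pd.DataFrame(
        np.column_stack([t, recording.accel, flat]), columns=_CSV_COLUMNS
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_recording(
    path, sensor_id: str, expected_fs: float | None = None
) -> SensorRecording:
    """Read and validate one sensor CSV.

    Raises :class:`FormatError` (with the offending row) for non-uniform
    timestamps or non-rotation matrices, and
    :class:`SampleRateMismatchError` when the file's sample rate disagrees
    with the manifest.
    """
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    med = float(np.median(dt))
    bad = np.flatnonzero(np.abs(dt - med) > 1e-6)
    if len(bad):
        raise FormatError(
            f"{path}: non-uniform timestamps (gap after row {int(bad[0]) + 1})"
        )
    fs = 1.0 / med
    if expected_fs is not None and abs(fs - expected_fs) > 1e-3 * expected_fs:
        raise SampleRateMismatchError(
            f"{path}: file sampled at {fs:.6g} Hz, manifest says {expected_fs:g} Hz"
        )
    accel = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    orient = df[_CSV_COLUMNS[4:]].to_numpy(dtype=float).reshape(-1, 3, 3)
    dets = np.linalg.det(orient)
    ortho_err = np.abs(
        np.einsum("tij,tik->tjk", orient, orient) - np.eye(3)
    ).max(axis=(1, 2))
    bad = np.flatnonzero((np.abs(dets - 1.0) > 1e-5) | (ortho_err > 1e-5))
    if len(bad):
        i = int(bad[0])
        raise FormatError(
            f"{path}: row {i} is not a rotation "
            f"(determinant {dets[i]:.6f}, orthonormality error {ortho_err[i]:.2e})"
        )
    return SensorRecording(sensor_id, fs, accel, orient)


def write_ground_truth(path, gt: GroundTruth) -> None:
    data = {
        "n_samples": gt.n_samples,
        "fs": gt.fs,
        "boundaries": [int(b) for b in gt.boundaries],
        "midpoints": [None if m is None else int(m) for m in gt.midpoints],
        "injected_saccades": {
            f"{arm}:{phase}": int(c) for (arm, phase), c in gt.injected_saccades.items()
        },
    }
    Path(path).write_text(json.dumps(data, indent=1))


def read_ground_truth(path) -> GroundTruth:
    data = json.loads(Path(path).read_text())
    return GroundTruth(
        n_samples=data["n_samples"],
        fs=data["fs"],
        boundaries=data["boundaries"],
        midpoints=data["midpoints"],
        injected_saccades={
            tuple(k.split(":")): v for k, v in data["injected_saccades"].items()
        },
    )


# ---------------------------------------------------------------------------
# session directory layout


def write_session(
    outdir,
    session: Session,
    subject_id: str = "sub01",
    session_index: int = 1,
    observer_id: str = "A",
) -> Path:
    """Write a simulated session (CSVs + sidecars + manifest); returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for mov in session.movements:
        files = {}
        for sensor_id, rec in mov.sensors.items():
            fname = f"{mov.movement_id}_{sensor_id}.csv"
            write_recording(outdir / fname, rec)
            files[sensor_id] = fname
        gt_name = f"{mov.movement_id}_truth.json"
        write_ground_truth(outdir / gt_name, mov.ground_truth)
        entries.append(
            {
                "movement_id": mov.movement_id,
                "laterality": mov.spec.laterality,
                "plane_deg": float(mov.spec.plane_deg),
                "functional": bool(mov.spec.functional),
                "sensors": files,
                "ground_truth": gt_name,
            }
        )
    manifest = {
        "subject_id": subject_id,
        "session_index": session_index,
        "observer_id": observer_id,
        "fs": float(session.fs),
        "movements": entries,
    }
    path = outdir / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path


def read_session(manifest_path):
    """Load a session directory; returns (SessionManifest, [MovementRecording])."""
    manifest_path = Path(manifest_path)
    data = yaml.safe_load(manifest_path.read_text())
    manifest = SessionManifest(
        subject_id=data["subject_id"],
        session_index=int(data["session_index"]),
        observer_id=data["observer_id"],
        fs=float(data["fs"]),
        movements=data["movements"],
    )
    base = manifest_path.parent
    movements = []
    for entry in data["movements"]:
        if set(entry["sensors"]) != set(SENSOR_IDS):
            raise FormatError(
                f"{manifest_path}: movement {entry['movement_id']} must list "
                f"the 4 sensors {SENSOR_IDS}"
            )
        sensors = {
            sid: read_recording(base / fname, sid, expected_fs=manifest.fs)
            for sid, fname in entry["sensors"].items()
        }
        gt = (
            read_ground_truth(base / entry["ground_truth"])
            if entry.get("ground_truth")
            else None
        )
        from .synthetic import MotionSpec

        spec = MotionSpec(
            movement_id=entry["movement_id"],
            laterality=entry["laterality"],
            plane_deg=entry.get("plane_deg", 90.0),
            functional=entry.get("functional", False),
        )
        movements.append(
            MovementRecording(entry["movement_id"], spec, sensors, gt)
        )
    return manifest, movements


# ---------------------------------------------------------------------------
# segmentation serialisation


def segmentation_to_dict(result: seg.SegmentationResult) -> dict:
    return {
        "fs": result.fs,
        "n_samples": result.n_samples,
        "boundaries": [int(b) for b in result.boundaries],
        "boundaries_s": [float(b / result.fs) for b in result.boundaries],
        "labels": list(result.labels),
        "midpoints": [
            None if m is None else int(m) for m in (result.midpoints or [])
        ],
    }


def segmentation_from_dict(data: dict) -> seg.SegmentationResult:
    return seg.SegmentationResult(
        fs=data["fs"],
        n_samples=data["n_samples"],
        boundaries=data["boundaries"],
        labels=data["labels"],
        midpoints=data.get("midpoints"),
    )


# ---------------------------------------------------------------------------
# orchestration


def _process_movement(mov, manifest, clf, config: PipelineConfig):
    """Kinematics → segmentation → jerk rows for one movement recording."""
    fs = manifest.fs
    rest = slice(0, int(round(fs)))  # subject frame from the first resting second
    subject = build_subject_frame(
        mov.sensors["head"].orient[rest],
        mov.sensors["back"].orient[rest],
    )
    kin = {
        arm: compute_kinematics(
            mov.sensors[arm], subject, config.filter_order, config.cutoff_hz
        )
        for arm in ("left", "right")
    }
    features = seg.extract_features(kin["left"], kin["right"])
    p = seg.predict_motion_probability(clf, features, fs)
    result = seg.segment_movement(
        p,
        kin["left"],
        kin["right"],
        functional=mov.spec.functional,
        w=config.midpoint_w,
        combine=config.sym_combine,
        n_segments=config.n_segments,
        min_dur_s=config.min_dur_s,
        max_dur_s=config.max_dur_s,
        smooth_s=config.smooth_s,
    )
    accels = {
        arm: lowpass(
            mov.sensors[arm].accel, fs, config.filter_order, config.cutoff_hz
        )
        for arm in ("left", "right")
    }
    table = phase_jerks(
        accels,
        result,
        fs,
        functional=mov.spec.functional,
        fusion_rule=config.jerk_fusion,
        physical=config.jerk_physical,
    )
    table.insert(0, "movement", mov.movement_id)
    table.insert(0, "observer", manifest.observer_id)
    table.insert(0, "session", manifest.session_index)
    table.insert(0, "subject", manifest.subject_id)
    return result, table


def train_cohort_classifier(cohort, config: PipelineConfig):
    """Train the motion classifier on the hand-labelled (ground-truth) subset."""
    all_movs = [(manifest, mov) for manifest, movements in cohort for mov in movements]
    if len(all_movs) >= 5:
        chosen = seg.bootstrap_manual_labels(
            all_movs, fraction=config.label_fraction, rng_seed=config.seed
        )
    else:
        chosen = list(range(len(all_movs)))
    feats, labels = [], []
    for idx in chosen:
        manifest, mov = all_movs[idx]
        if mov.ground_truth is None:
            raise InvalidArgumentError(
                f"movement {mov.movement_id} has no labels for training"
            )
        rest = slice(0, int(round(manifest.fs)))
        subject = build_subject_frame(
            mov.sensors["head"].orient[rest], mov.sensors["back"].orient[rest]
        )
        kin_l = compute_kinematics(
            mov.sensors["left"], subject, config.filter_order, config.cutoff_hz
        )
        kin_r = compute_kinematics(
            mov.sensors["right"], subject, config.filter_order, config.cutoff_hz
        )
        feats.append(seg.extract_features(kin_l, kin_r))
        labels.append(mov.ground_truth.binary_labels())
    clf, acc = seg.train_motion_classifier(feats, labels, rng_seed=config.seed)
    log.info("motion classifier trained on %d recordings, accuracy %.3f", len(chosen), acc)
    return clf, acc


# the comparison battery of the analysis: (label, family) -> list of
# (comparison name, (movement, arm, phase) numerator, (movement, arm, phase)
# denominator); the jerk ratio reported is numerator/(numerator+denominator)
_LATERALITY = [
    ("sagittal_bilateral", ("sagittal_bilateral", "left", "full"), ("sagittal_bilateral", "right", "full")),
    ("scapular_bilateral", ("scapular_bilateral", "left", "full"), ("scapular_bilateral", "right", "full")),
    ("frontal_bilateral", ("frontal_bilateral", "left", "full"), ("frontal_bilateral", "right", "full")),
    ("sagittal_unilateral", ("sagittal_unilateral_left", "left", "full"), ("sagittal_unilateral_right", "right", "full")),
    ("scapular_unilateral", ("scapular_unilateral_left", "left", "full"), ("scapular_unilateral_right", "right", "full")),
    ("hair_combing", ("hair_combing_left", "left", "full"), ("hair_combing_right", "right", "full")),
    ("low_back_washing", ("low_back_washing_left", "left", "full"), ("low_back_washing_right", "right", "full")),
]
_PHASE = [
    ("sagittal_bilateral", ("sagittal_bilateral", "total", "ascending"), ("sagittal_bilateral", "total", "lowering")),
    ("scapular_bilateral", ("scapular_bilateral", "total", "ascending"), ("scapular_bilateral", "total", "lowering")),
    ("frontal_bilateral", ("frontal_bilateral", "total", "ascending"), ("frontal_bilateral", "total", "lowering")),
    ("sagittal_unilateral_right", ("sagittal_unilateral_right", "right", "ascending"), ("sagittal_unilateral_right", "right", "lowering")),
    ("sagittal_unilateral_left", ("sagittal_unilateral_left", "left", "ascending"), ("sagittal_unilateral_left", "left", "lowering")),
    ("scapular_unilateral_right", ("scapular_unilateral_right", "right", "ascending"), ("scapular_unilateral_right", "right", "lowering")),
    ("scapular_unilateral_left", ("scapular_unilateral_left", "left", "ascending"), ("scapular_unilateral_left", "left", "lowering")),
]
_PLANE = [
    ("frontal/sagittal_bilateral", ("frontal_bilateral", "total", "full"), ("sagittal_bilateral", "total", "full")),
    ("frontal/scapular_bilateral", ("frontal_bilateral", "total", "full"), ("scapular_bilateral", "total", "full")),
    ("sagittal/scapular_bilateral", ("sagittal_bilateral", "total", "full"), ("scapular_bilateral", "total", "full")),
    ("sagittal/scapular_unilateral_right", ("sagittal_unilateral_right", "right", "full"), ("scapular_unilateral_right", "right", "full")),
    ("sagittal/scapular_unilateral_left", ("sagittal_unilateral_left", "left", "full"), ("scapular_unilateral_left", "left", "full")),
]
COMPARISON_FAMILIES = {
    "laterality": _LATERALITY,
    "phase": _PHASE,
    "plane": _PLANE,
}


def comparison_battery(jerk_table: pd.DataFrame) -> pd.DataFrame:
    """Paired Wilcoxon comparisons with per-family Bonferroni correction.

    Families (matching the analysis design): laterality (left vs right, up
    to 7 comparisons), contraction phase (ascending vs lowering, up to 7),
    elevation plane (pairwise planes, up to 5).  Uses one value per subject
    (median over sessions × trials); comparisons whose movements are absent
    from the table are skipped and the family size shrinks accordingly.
    """
    med = jerk_table.groupby(["subject", "movement", "arm", "phase"])["jerk"].median()
    rows = []
    for family, comparisons in COMPARISON_FAMILIES.items():
        available = []
        for name, key1, key2 in comparisons:
            try:
                x = med.xs(key=key1[0], level="movement").xs(
                    key=(key1[1], key1[2]), level=("arm", "phase")
                )
                y = med.xs(key=key2[0], level="movement").xs(
                    key=(key2[1], key2[2]), level=("arm", "phase")
                )
            except KeyError:
                continue
            common = x.index.intersection(y.index)
            if len(common) >= 6:
                available.append((name, x.loc[common], y.loc[common]))
        family_size = len(available)
        for name, x, y in available:
            res = st.paired_comparison(
                x.to_numpy(), y.to_numpy(), family_size=family_size
            )
            rows.append(
                {
                    "family": family,
                    "comparison": name,
                    "mean_ratio": res.mean_ratio,
                    "p_raw": res.p_raw,
                    "p_adj": res.p_adj,
                    "family_size": family_size,
                    "acceptance_level": res.acceptance_level,
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(cohort, config: PipelineConfig | None = None, outdir=None) -> dict:
    """Run the full analysis over a cohort of sessions.

    ``cohort`` is a list of ``(SessionManifest, [MovementRecording])`` pairs
    (as returned by :func:`read_session`) or of manifest paths.  Returns a
    dict with the jerk table, reliability report, comparison results,
    per-movement segmentations and the classifier training accuracy; if
    ``outdir`` is given, every artifact is also written there.
    """
    config = config or PipelineConfig()
    loaded = []
    for item in cohort:
        if isinstance(item, (str, Path)):
            loaded.append(read_session(item))
        else:
            loaded.append(item)
    if not loaded:
        raise InvalidArgumentError("empty cohort")
    log.info("pipeline config %s on %d sessions", config.hash(), len(loaded))

    clf, train_acc = train_cohort_classifier(loaded, config)
    tables, segmentations = [], {}
    for manifest, movements in loaded:
        for mov in movements:
            result, table = _process_movement(mov, manifest, clf, config)
            tables.append(table)
            key = (manifest.subject_id, manifest.session_index, mov.movement_id)
            segmentations[key] = result
    jerk_table = pd.concat(tables, ignore_index=True)
    jerk_table["fusion_rule"] = config.jerk_fusion
    jerk_table["physical_scaling"] = config.jerk_physical

    n_sessions = jerk_table.groupby("subject")["session"].nunique()
    reliability = (
        st.reliability_suite(jerk_table) if n_sessions.max() >= 2 else pd.DataFrame()
    )
    n_subjects = jerk_table["subject"].nunique()
    comparisons = comparison_battery(jerk_table) if n_subjects >= 6 else pd.DataFrame()

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        jerk_table.to_csv(outdir / "jerk_table.csv", index=False)
        if not reliability.empty:
            reliability.to_csv(outdir / "reliability.csv", index=False)
        if not comparisons.empty:
            comparisons.to_csv(outdir / "comparisons.csv", index=False)
        seg_blob = {
            "|".join(map(str, key)): segmentation_to_dict(res)
            for key, res in segmentations.items()
        }
        (outdir / "segmentations.json").write_text(json.dumps(seg_blob, indent=1))
        (outdir / "config.json").write_text(
            json.dumps({"hash": config.hash(), **config.to_dict()}, indent=1)
        )
    return {
        "jerk_table": jerk_table,
        "reliability": reliability,
        "comparisons": comparisons,
        "segmentations": segmentations,
        "train_accuracy": train_acc,
        "config": config,
    }
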