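"""Readers and writers binding the pipeline stages together.

Images travel as single-channel TIFF (32-bit float; 8/16-bit integer reads
are promoted to float) with a sidecar JSON manifest describing each frame's
channel, stage and acquisition time:

    {
      "schema": "sevquant.manifest/1",
      "sample_id": "...",
      "frames": [{"path": "...tif", "channel": "panorama",
                  "stage": "pre_wash", "time_min": 15.0}, ...]
    }

Tables are UTF-8 comma-separated CSV with a mandatory header row; a leading
``#``-comment block carries the schema version and a machine-readable
provenance line (package version, seed, config hash).  JSON outputs embed
the same provenance as an object.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .errors import ValidationError
from .imaging import CHANNELS, Detection, DetectionSet, Frame, FrameStack
from .quantify import SampleSummary
from .simdata import GroundTruth, SimulatedImageSet

MANIFEST_SCHEMA = "sevquant.manifest/1"
DETECTIONS_SCHEMA = "sevquant.detections/1"
SUMMARY_SCHEMA = "sevquant.summaries/1"

DETECTION_COLUMNS = [
    "sample_id",
    "stage",
    "time_min",
    "channel",
    "x",
    "y",
    "contrast_pct",
    "fluor_intensity",
    "size_nm",
    "sev_like",
    "retained",
    "mir21_pos",
    "gfp_pos",
    "membrane_dye_pos",
]


def provenance(seed: int | None = None, config: Any = None) -> dict:
    """Machine-readable provenance block for output artifacts."""
    block = {"package": "sevquant", "version": __version__}
    if seed is not None:
        block["seed"] = int(seed)
    if config is not None:
        if dataclasses.is_dataclass(config) and not isinstance(config, type):
            payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
        else:
            payload = json.dumps(config, sort_keys=True, default=str)
        block["config_sha256"] = hashlib.sha256(payload.encode()).hexdigest()[:16]
    return block


def _comment_header(schema: str, prov: dict) -> str:
    return f"# schema: {schema}\n# provenance: {json.dumps(prov, sort_keys=True)}\n"


def write_frame(path: str | Path, frame: Frame) -> None:
    tifffile.imwrite(str(path), frame.pixels.astype(np.float32))


def read_frame(path: str | Path, channel: str, stage: str, time_min: float | None) -> Frame:
    pixels = tifffile.imread(str(path)).astype(float)
    return Frame(pixels=pixels, channel=channel, stage=stage, time_min=time_min)


def write_image_set(
    out_dir: str | Path,
    images: SimulatedImageSet,
    ground_truth: GroundTruth | None = None,
    sample_id: str = "sample",
    prov: dict | None = None,
) -> Path:
    """Write all frames as TIFF plus manifest.json (and ground_truth.csv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []

    def emit(frame: Frame, name: str) -> None:
        write_frame(out / name, frame)
        entries.append(
            {
                "path": name,
                "channel": frame.channel,
                "stage": frame.stage,
                "time_min": frame.time_min,
            }
        )

    emit(images.panorama.background, "panorama_background.tif")
    for i, f in enumerate(images.panorama.frames):
        emit(f, f"panorama_{f.stage}_{i:02d}.tif")
    for ch, stack in images.fluorescence.items():
        emit(stack.background, f"{ch}_background.tif")
        for i, f in enumerate(stack.frames):
            emit(f, f"{ch}_{f.stage}_{i:02d}.tif")

    manifest = {
        "schema": MANIFEST_SCHEMA,
        "sample_id": sample_id,
        "provenance": prov or provenance(),
        "frames": entries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    if ground_truth is not None:
        header = _comment_header("sevquant.ground_truth/1", prov or provenance())
        with open(out / "ground_truth.csv", "w") as fh:
            fh.write(header)
            ground_truth.particles.to_csv(fh, index=False)
    return out / "manifest.json"


def read_image_set(manifest_path: str | Path) -> tuple[dict[str, FrameStack], str]:
    """Load the per-channel frame stacks described by a manifest."""
    mpath = Path(manifest_path)
    manifest = json.loads(mpath.read_text())
    if manifest.get("schema") != MANIFEST_SCHEMA:
        raise ValidationError(
            f"manifest.schema: expected {MANIFEST_SCHEMA!r}, got {manifest.get('schema')!r}"
        )
    frames_meta = manifest.get("frames")
    if not isinstance(frames_meta, list) or not frames_meta:
        raise ValidationError("manifest.frames: must be a non-empty list")
    by_channel: dict[str, dict[str, list[Frame]]] = {}
    for i, entry in enumerate(frames_meta):
        for key in ("path", "channel", "stage"):
            if key not in entry:
                raise ValidationError(f"manifest.frames[{i}].{key}: missing")
        if entry["channel"] not in CHANNELS:
            raise ValidationError(f"manifest.frames[{i}].channel: unknown {entry['channel']!r}")
        frame = read_frame(
            mpath.parent / entry["path"], entry["channel"], entry["stage"], entry.get("time_min")
        )
        slot = by_channel.setdefault(entry["channel"], {"background": [], "frames": []})
        (slot["background"] if frame.stage == "background" else slot["frames"]).append(frame)
    stacks: dict[str, FrameStack] = {}
    for ch, slot in by_channel.items():
        if len(slot["background"]) != 1:
            raise ValidationError(f"channel {ch!r}: need exactly one background frame")
        stacks[ch] = FrameStack(background=slot["background"][0], frames=slot["frames"])
    return stacks, manifest.get("sample_id", "sample")


def detections_to_frame(sets: Iterable[DetectionSet], sample_id: str) -> pd.DataFrame:
    rows = []
    for ds in sets:
        for d in ds:
            rows.append(
                {
                    "sample_id": sample_id,
                    "stage": ds.stage,
                    "time_min": ds.time_min,
                    "channel": ds.channel,
                    "x": d.x,
                    "y": d.y,
                    "contrast_pct": d.contrast_pct,
                    "fluor_intensity": d.fluor_intensity,
                    "size_nm": d.size_nm,
                    "sev_like": d.sev_like,
                    "retained": d.retained,
                    "mir21_pos": d.mir21_pos,
                    "gfp_pos": d.gfp_pos,
                    "membrane_dye_pos": d.membrane_dye_pos,
                }
            )
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def write_detections(path: str | Path, df: pd.DataFrame, prov: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header(DETECTIONS_SCHEMA, prov or provenance()))
        df.to_csv(fh, index=False)


def read_detections(path: str | Path) -> pd.DataFrame:
    # round_trip float parsing so write -> read -> write is byte-identical
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = set(DETECTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"detection table missing columns: {sorted(missing)}")
    return df


def detection_sets_from_frame(df: pd.DataFrame, image_shape: tuple[int, int]) -> list[DetectionSet]:
    """Rebuild DetectionSet objects from a detection table."""
    sets = []
    for (stage, time_min, channel), grp in df.groupby(
        ["stage", "time_min", "channel"], dropna=False, sort=True
    ):
        dets = [
            Detection(
                y=int(r.y),
                x=int(r.x),
                contrast_pct=None if pd.isna(r.contrast_pct) else float(r.contrast_pct),
                fluor_intensity=None if pd.isna(r.fluor_intensity) else float(r.fluor_intensity),
                size_nm=None if pd.isna(r.size_nm) else float(r.size_nm),
                sev_like=bool(r.sev_like),
                retained=bool(r.retained),
                mir21_pos=bool(r.mir21_pos),
                gfp_pos=bool(r.gfp_pos),
                membrane_dye_pos=bool(r.membrane_dye_pos),
            )
            for r in grp.itertuples()
        ]
        sets.append(
            DetectionSet(
                dets,
                channel=channel,
                stage=stage,
                time_min=None if pd.isna(time_min) else float(time_min),
                image_shape=image_shape,
            )
        )
    return sets


def write_summaries(
    path: str | Path, summaries: Iterable[SampleSummary], prov: dict | None = None
) -> None:
    rows = []
    for s in summaries:
        row = {
            "sample_id": s.sample_id,
            "group_label": s.group_label,
            "subtype": s.subtype,
            "pre_wash_total": s.pre_wash_total,
            "pre_wash_sev_like": s.pre_wash_sev_like,
            "post_wash_count": s.post_wash_count,
            "retention_pct": s.retention_pct,
            "retention_denominator": s.retention_denominator,
            "asc_per_ul": s.asc_per_ul,
            "volume_ul": s.volume_ul,
            "mean_contrast_pct": s.mean_contrast_pct,
            "mean_size_nm": s.mean_size_nm,
        }
        for flag, pct in s.occurrence_pct.items():
            row[f"occurrence_{flag}"] = pct
        rows.append(row)
    with open(path, "w") as fh:
        fh.write(_comment_header(SUMMARY_SCHEMA, prov or provenance()))
        pd.DataFrame(rows).to_csv(fh, index=False)


def read_summaries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def read_cohort_counts(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Counts and binary labels from a summary or bare cohort CSV.

    Accepts either the SampleSummary table or any CSV with columns
    ``post_wash_count`` and ``group_label`` (cancer/control naming) or
    ``label`` (0/1).
    """
    df = pd.read_csv(path, comment="#")
    if "post_wash_count" not in df.columns:
        raise ValidationError("cohort CSV needs a 'post_wash_count' column")
    counts = df["post_wash_count"].to_numpy(float)
    if "label" in df.columns:
        labels = df["label"].to_numpy(int)
    elif "group_label" in df.columns:
        labels = (df["group_label"].astype(str).str.lower() == "cancer").to_numpy(int)
    else:
        raise ValidationError("cohort CSV needs 'group_label' or 'label'")
    return counts, labels


def write_json(path: str | Path, payload: dict, prov: dict | None = None) -> None:
    payload = dict(payload)
    payload.setdefault("provenance", prov or provenance())
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
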