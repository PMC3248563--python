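"""File formats: TIFF stacks with sidecar calibration, CSV tables, manifests.

Calibration is never guessed silently from TIFF tags: a stack is read with an
explicit ``pixel_size_um`` / ``frame_interval_s`` pair, either passed directly
or loaded from a small sidecar JSON next to the TIFF.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import CalibrationRequiredError, InputError
from .frap import FrapTrace
from .imaging import FrameStack
from .tracking import MotilitySummary, WormTrack
from .triage import GeneRecord, ScreenDataset, TriageResult, TsOutcome

__all__ = [
    "read_stack",
    "write_stack",
    "read_frap_trace_csv",
    "tracks_to_frame",
    "summary_to_frame",
    "read_counts_csv",
    "dataset_to_json",
    "dataset_from_json",
    "triage_result_to_json",
    "write_manifest",
]


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(tiff_path.suffix + ".json")


def read_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> FrameStack:
    """Read a multi-page grayscale TIFF as a calibrated :class:`FrameStack`.

    Calibration comes from the arguments or, failing that, from a sidecar
    JSON ``<path>.json`` with keys ``pixel_size_um`` / ``frame_interval_s``.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    pixel_size_um = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    frame_interval_s = (
        frame_interval_s if frame_interval_s is not None else meta.get("frame_interval_s")
    )
    if pixel_size_um is None or frame_interval_s is None:
        raise CalibrationRequiredError(
            f"no calibration for {path.name}: pass pixel_size_um/frame_interval_s "
            "or provide a sidecar JSON"
        )
    return FrameStack(
        frames=np.asarray(frames, dtype=np.float64),
        frame_interval_s=float(frame_interval_s),
        pixel_size_um=float(pixel_size_um),
        meta=meta,
    )


def write_stack(stack: FrameStack, path: str | Path, dtype=np.float32) -> None:
    """Write a stack as multi-page TIFF plus a sidecar calibration JSON."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(dtype))
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "pixel_size_um": stack.pixel_size_um,
                "frame_interval_s": stack.frame_interval_s,
                **{k: v for k, v in stack.meta.items() if isinstance(v, (int, float, str))},
            },
            indent=2,
        )
    )


def read_frap_trace_csv(path: str | Path) -> FrapTrace:
    """Read a FRAP trace CSV with columns time_s, roi, total, is_prebleach."""
    df = pd.read_csv(path)
    required = {"time_s", "roi", "total", "is_prebleach"}
    if not required <= set(df.columns):
        raise InputError(f"FRAP CSV needs columns {sorted(required)}")
    pre = df["is_prebleach"].astype(bool).to_numpy()
    if not pre[0] or pre.sum() == 0 or pre.sum() == len(df):
        raise InputError("is_prebleach must mark a leading nonempty segment")
    bleach_index = int(pre.sum())
    if pre[bleach_index:].any():
        raise InputError("pre-bleach samples must be contiguous at the start")
    return FrapTrace(
        times_s=df["time_s"].to_numpy(float),
        roi_intensity=df["roi"].to_numpy(float),
        total_intensity=df["total"].to_numpy(float),
        bleach_index=bleach_index,
    )


def tracks_to_frame(tracks: list[WormTrack]) -> pd.DataFrame:
    """One row per track: id, span, body length, path, duration, BLPS."""
    return pd.DataFrame(
        [
            {
                "track_id": t.track_id,
                "n_frames": t.n_frames,
                "first_frame": t.first_frame,
                "body_length_um": t.body_length_um,
                "path_length_um": t.path_length_um,
                "duration_s": t.duration_s,
                "blps": t.blps,
            }
            for t in tracks
        ]
    )


def summary_to_frame(summary: MotilitySummary) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_label": summary.group_label,
                "n_tracks": summary.n_tracks,
                "mean_blps": summary.mean_blps,
                "sem_blps": summary.sem_blps,
                "pct_of_control": summary.pct_of_control,
            }
        ]
    )


def read_counts_csv(path: str | Path) -> dict[str, np.ndarray]:
    """Read per-animal foci counts: columns ``condition_label, foci_count``.

    Returns condition label -> integer count array.
    """
    df = pd.read_csv(path)
    if not {"condition_label", "foci_count"} <= set(df.columns):
        raise InputError("counts CSV needs columns condition_label, foci_count")
    return {
        str(label): grp["foci_count"].to_numpy(int)
        for label, grp in df.groupby("condition_label")
    }


def _arr(value):
    return None if value is None else np.asarray(value)


def dataset_to_json(dataset: ScreenDataset) -> dict:
    """JSON-serializable form of a screen dataset (counts as plain lists)."""

    def lst(a):
        return None if a is None else np.asarray(a).tolist()

    return {
        "controls": {
            "q35_counts": lst(dataset.q35_control_counts),
            "q37_counts": lst(dataset.q37_control_counts),
            "sod1_counts": lst(dataset.sod1_control_counts),
            "wt_blps": lst(dataset.wt_control_blps),
            "q35_blps": lst(dataset.q35_control_blps),
        },
        "records": [
            {
                "gene_id": r.gene_id,
                "functional_class": r.functional_class,
                "q35_counts": lst(r.q35_counts),
                "q37_counts": lst(r.q37_counts),
                "sod1_counts": lst(r.sod1_counts),
                "q24_artifact": bool(r.q24_artifact),
                "wt_blps": lst(r.wt_blps),
                "q35_blps": lst(r.q35_blps),
                "ts_outcomes": {
                    s: {
                        "pct_phenotype_treated": o.pct_phenotype_treated,
                        "pct_phenotype_control": o.pct_phenotype_control,
                        "n_animals": o.n_animals,
                    }
                    for s, o in r.ts_outcomes.items()
                },
            }
            for r in dataset.records
        ],
    }


def dataset_from_json(payload: dict) -> ScreenDataset:
    """Inverse of :func:`dataset_to_json`."""
    ctl = payload["controls"]
    records = [
        GeneRecord(
            gene_id=r["gene_id"],
            functional_class=r.get("functional_class", "unknown"),
            q35_counts=_arr(r.get("q35_counts")),
            q37_counts=_arr(r.get("q37_counts")),
            sod1_counts=_arr(r.get("sod1_counts")),
            q24_artifact=bool(r.get("q24_artifact", False)),
            wt_blps=_arr(r.get("wt_blps")),
            q35_blps=_arr(r.get("q35_blps")),
            ts_outcomes={
                s: TsOutcome(
                    strain=s,
                    pct_phenotype_treated=o["pct_phenotype_treated"],
                    pct_phenotype_control=o["pct_phenotype_control"],
                    n_animals=o["n_animals"],
                )
                for s, o in r.get("ts_outcomes", {}).items()
            },
        )
        for r in payload["records"]
    ]
    return ScreenDataset(
        records=records,
        q35_control_counts=_arr(ctl.get("q35_counts")),
        q37_control_counts=_arr(ctl.get("q37_counts")),
        sod1_control_counts=_arr(ctl.get("sod1_counts")),
        wt_control_blps=_arr(ctl.get("wt_blps")),
        q35_control_blps=_arr(ctl.get("q35_blps")),
    )


def triage_result_to_json(result: TriageResult) -> dict:
    """JSON-serializable form of a triage result (sets as sorted lists)."""
    return {
        "stage_counts": result.stage_counts,
        "class_percentages": result.class_percentages,
        "q35_positives": sorted(result.q35_positives),
        "q35_strong": sorted(result.q35_strong),
        "excluded_by_q24": sorted(result.excluded_by_q24),
        "class_a": sorted(result.class_a),
        "class_b": sorted(result.class_b),
        "sod1_common": sorted(result.sod1_common),
        "wt_motility_excluded": sorted(result.wt_motility_excluded),
        "motility_classes": dict(sorted(result.motility_classes.items())),
        "toxicity_suppressors": sorted(result.toxicity_suppressors),
        "core_modifiers": sorted(result.core_modifiers),
        "ts_tallies": {
            g: {"rescued": r, "tested": t}
            for g, (r, t) in sorted(result.ts_tallies.items())
        },
    }


def write_manifest(
    out_path: str | Path, inputs: dict[str, str | Path], config: dict
) -> None:
    """Write ``<out>.manifest.json`` with input hashes, config, and version."""
    from . import __version__

    out_path = Path(out_path)
    hashes = {}
    for name, p in inputs.items():
        p = Path(p)
        if p.exists() and p.is_file():
            hashes[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "wormtriage_version": __version__,
        "inputs_sha256": hashes,
        "config": config,
    }
    Path(str(out_path) + ".manifest.json").write_text(json.dumps(manifest, indent=2))
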