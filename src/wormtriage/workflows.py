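"""End-to-end experiments composed from the simulator and the tracker.

These are the desk-scale analogues of the screen's motility assays: simulate
groups of crawling worms at known speeds, run the full video pipeline
(de-flicker, background subtraction, Otsu binarization, blob linking, BLPS),
and compare the recovered group statistics with the driving ground truth.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .simulate import WormSimParams, simulate_worm_video
from .tracking import WormTrack, summarize_plate, track_stack

__all__ = [
    "tracked_group_blps",
    "motility_deficit_experiment",
    "blps_recovery_sweep",
]


def tracked_group_blps(
    speed_blps: float,
    n_worms: int,
    seed: int,
    worms_per_video: int = 5,
    params: WormSimParams | None = None,
    body_length_stride: int = 3,
) -> list[WormTrack]:
    """Simulate ``n_worms`` at one speed (split across videos) and track them.

    Each video holds ``worms_per_video`` worms in separate arena cells; seeds
    are derived per video so groups are independent but reproducible.
    """
    base = params or WormSimParams()
    tracks: list[WormTrack] = []
    remaining = n_worms
    video_index = 0
    while remaining > 0:
        k = min(worms_per_video, remaining)
        p = replace(base, n_worms=k, speed_blps=speed_blps)
        stack, _ = simulate_worm_video(p, seed=(seed * 1000 + video_index) % 2**31)
        tracks.extend(
            track_stack(stack, body_length_stride=body_length_stride)
        )
        remaining -= k
        video_index += 1
    return tracks


def motility_deficit_experiment(
    seed: int,
    wt_speed_blps: float = 0.20,
    mutant_speed_blps: float = 0.12,
    n_worms_per_group: int = 20,
    worms_per_video: int = 5,
    params: WormSimParams | None = None,
) -> dict:
    """Measure a group motility deficit end-to-end through the tracker.

    Simulates a wild-type-like group and a slower mutant-like group at the
    stated speeds, tracks both, and reports the percent deficit
    ``100 * (1 - mean_mutant / mean_wt)`` together with the per-group
    summaries.
    """
    wt_tracks = tracked_group_blps(
        wt_speed_blps, n_worms_per_group, seed * 2 + 1, worms_per_video, params
    )
    mut_tracks = tracked_group_blps(
        mutant_speed_blps, n_worms_per_group, seed * 2 + 2, worms_per_video, params
    )
    wt = summarize_plate(wt_tracks, "wt")
    mut = summarize_plate(mut_tracks, "mutant", control=wt)
    return {
        "wt_summary": wt,
        "mutant_summary": mut,
        "true_deficit_pct": 100.0 * (1.0 - mutant_speed_blps / wt_speed_blps),
        "measured_deficit_pct": 100.0 * (1.0 - mut.mean_blps / wt.mean_blps),
    }


def blps_recovery_sweep(
    seed: int,
    speeds: np.ndarray | None = None,
    params: WormSimParams | None = None,
) -> pd.DataFrame:
    """Single-worm speed-recovery sweep across the crawling range.

    One video per speed; returns a DataFrame with the driving speed, the
    recovered BLPS of the (single) track, and the relative error.
    """
    if speeds is None:
        speeds = np.linspace(0.02, 0.30, 20)
    base = params or WormSimParams()
    rows = []
    for i, speed in enumerate(np.asarray(speeds, dtype=float)):
        p = replace(base, n_worms=1, speed_blps=float(speed))
        stack, truth = simulate_worm_video(p, seed=(seed * 1000 + i) % 2**31)
        tracks = track_stack(stack, body_length_stride=3)
        best = max(tracks, key=lambda t: t.n_frames) if tracks else None
        recovered = best.blps if best else np.nan
        rows.append(
            {
                "true_blps": float(speed),
                "recovered_blps": recovered,
                "rel_error": (recovered - speed) / speed if best else np.nan,
                "n_tracks": len(tracks),
                "body_length_um": best.body_length_um if best else np.nan,
                "true_body_length_um": truth["body_length_um"],
            }
        )
    return pd.DataFrame(rows)
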