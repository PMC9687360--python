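"""Disk formats: sequence directories of 1-bit PNG frames and signal CSVs.

A silhouette sequence lives in one directory: frames as ``frame_00000.png``
(1-bit, foreground white) in lexicographic order plus a ``sequence.json``
sidecar carrying participant id, treadmill speed, fps and the generator
seed. Extracted signals go to a per-sequence CSV with header
``frame,HW1,HW2,HW3,A1,A2`` at full float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .core import FEATURE_NAMES, FeatureSignalSet, SilhouetteSequence, SpeedClass

__all__ = [
    "write_sequence_dir",
    "read_sequence_dir",
    "write_signals_csv",
    "read_signals_csv",
]

SIDECAR_NAME = "sequence.json"


def write_sequence_dir(
    seq: SilhouetteSequence, out_dir: str | Path, seed: int | None = None
) -> Path:
    """Write a sequence as 1-bit PNG frames plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq.frames):
        img = Image.fromarray((np.asarray(frame, dtype=np.uint8) * 255)).convert("1")
        img.save(out_dir / f"frame_{i:05d}.png")
    sidecar = {
        "participant_id": seq.participant_id,
        "speed_kmh": seq.speed_kmh,
        "fps": seq.fps,
        "seed": seed,
        "n_frames": len(seq.frames),
    }
    (out_dir / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2))
    return out_dir


def read_sequence_dir(seq_dir: str | Path, threshold: float = 127) -> SilhouetteSequence:
    """Read a sequence directory (PNGs sorted lexicographically + sidecar)."""
    seq_dir = Path(seq_dir)
    sidecar_path = seq_dir / SIDECAR_NAME
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    frames = []
    for png in sorted(seq_dir.glob("*.png")):
        arr = np.asarray(Image.open(png).convert("L"))
        frames.append(arr > threshold)
    if not frames:
        raise FileNotFoundError(f"no PNG frames in {seq_dir}")
    return SilhouetteSequence(
        frames=frames,
        fps=meta["fps"],
        participant_id=meta["participant_id"],
        speed_kmh=meta["speed_kmh"],
    )


def write_signals_csv(signals: FeatureSignalSet, path: str | Path) -> Path:
    """Per-sequence CSV: frame index plus the five ratio columns."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(signals.signals.T, columns=list(FEATURE_NAMES))
    df.insert(0, "frame", np.arange(signals.n_frames))
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "participant_id": signals.participant_id,
        "speed_class": signals.speed_class.value,
        "speed_kmh": signals.speed_kmh,
        "fps": signals.fps,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def read_signals_csv(
    path: str | Path,
    participant_id: str | None = None,
    speed_class: SpeedClass | str | None = None,
    fps: float | None = None,
) -> FeatureSignalSet:
    """Reload a signal CSV; metadata comes from the sidecar unless overridden."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"CSV {path} lacks column(s) {missing}")
    meta_path = path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return FeatureSignalSet(
        signals=df[list(FEATURE_NAMES)].to_numpy().T,
        fps=fps if fps is not None else meta.get("fps", 60.0),
        participant_id=(
            participant_id if participant_id is not None else meta.get("participant_id", "P00")
        ),
        speed_class=SpeedClass(speed_class if speed_class is not None else meta["speed_class"]),
        speed_kmh=meta.get("speed_kmh"),
    )
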