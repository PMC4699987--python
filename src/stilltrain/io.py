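"""Plain-text/file interchange: PGM frame sequences and TSV event streams."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .controller import OperatorCommand
from .errors import InputError
from .motion import Frame, MotionSample

__all__ = [
    "read_frames_dir",
    "read_frames_manifest",
    "write_frames_dir",
    "read_samples_tsv",
    "write_samples_tsv",
    "read_commands_tsv",
]

SAMPLES_HEADER = "timestamp_s\tmoved\tmagnitude"


def _load_frame(path: Path, timestamp: float) -> Frame:
    with Image.open(path) as img:
        arr = np.asarray(img.convert("L"), dtype=np.uint8)
    return Frame(arr, timestamp=timestamp)


def read_frames_dir(directory: str | Path, fps: float = 30.0) -> list[Frame]:
    """Read a directory of PGM frames in lexicographic order; timestamps are
    assigned from the frame index at the given rate."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.pgm"))
    if not paths:
        raise InputError(f"no .pgm frames found in {directory}")
    return [_load_frame(p, i / fps) for i, p in enumerate(paths)]


def read_frames_manifest(manifest: str | Path) -> list[Frame]:
    """Read frames listed in a manifest text file of `path<TAB>timestamp_s`
    lines (paths relative to the manifest's directory)."""
    manifest = Path(manifest)
    frames = []
    for lineno, line in enumerate(manifest.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise InputError(f"{manifest}:{lineno}: expected path<TAB>timestamp")
        frames.append(_load_frame(manifest.parent / parts[0], float(parts[1])))
    if not frames:
        raise InputError(f"no frames listed in {manifest}")
    return frames


def write_frames_dir(frames: Sequence[Frame], directory: str | Path) -> list[Path]:
    """Write frames as zero-padded binary PGM files; returns written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for i, frame in enumerate(frames):
        path = directory / f"frame_{i:06d}.pgm"
        Image.fromarray(frame.pixels, mode="L").save(path)
        out.append(path)
    return out


def write_samples_tsv(samples: Sequence[MotionSample], path: str | Path) -> None:
    lines = [SAMPLES_HEADER]
    lines += [
        f"{s.timestamp:.3f}\t{int(s.moved)}\t{s.magnitude:.6f}" for s in samples
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_samples_tsv(path: str | Path) -> list[MotionSample]:
    """Read a (timestamp_s, moved[, magnitude]) TSV stream; header optional."""
    path = Path(path)
    samples = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "timestamp")):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise InputError(f"{path}:{lineno}: expected timestamp<TAB>moved")
        try:
            samples.append(
                MotionSample(
                    timestamp=float(parts[0]),
                    moved=bool(int(parts[1])),
                    magnitude=float(parts[2]) if len(parts) > 2 else 0.0,
                )
            )
        except ValueError as exc:
            raise InputError(f"{path}:{lineno}: {exc}") from None
    if not samples:
        raise InputError(f"no samples in {path}")
    return samples


def read_commands_tsv(path: str | Path) -> list[OperatorCommand]:
    """Read an operator command stream: `timestamp_s<TAB>command [args]` rows.

    Commands: pause, restart, manual_reward, continuous_reward_start,
    continuous_reward_stop, save_stop, save_quit, and
    `set <field> <value>` for mid-session parameter changes.
    """
    path = Path(path)
    commands = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "timestamp")):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise InputError(f"{path}:{lineno}: expected timestamp<TAB>command")
        at_s = float(parts[0])
        words = parts[1].split() + [p for p in parts[2:] if p]
        kind = words[0]
        if kind == "set":
            if len(words) != 3:
                raise InputError(f"{path}:{lineno}: set needs field and value")
            commands.append(
                OperatorCommand(
                    kind="set", at_s=at_s, field=words[1], value=float(words[2])
                )
            )
        else:
            commands.append(OperatorCommand(kind=kind, at_s=at_s))
    return commands
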