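"""Skeleton sequence container and I/O.

Sequences are T×V×3 joint trajectories in meters (camera coordinates)
with subject / class metadata.  Supported formats:

* the NTU RGB+D ``.skeleton`` text dialect (read-only),
* an HDF5 container (read/write, one group per sample),
* CSV export of a single sequence for debugging.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SkeletonSequence",
    "ParseError",
    "read_ntu_skeleton",
    "resample_sequence",
    "write_hdf5",
    "read_hdf5",
    "sequence_to_csv",
]

log = logging.getLogger(__name__)

# NTU filename convention: SsssCcccPpppRrrrAaaa
_NTU_NAME_RE = re.compile(
    r"S(\d{3})C(\d{3})P(\d{3})R(\d{3})A(\d{3})", re.IGNORECASE
)


class ParseError(ValueError):
    """Malformed skeleton file."""


@dataclass
class SkeletonSequence:
    """A single skeleton trial: ``positions`` is T×V×3, meters.

    ``class_label`` is -1 when unknown (e.g. unlabeled recordings).
    """

    positions: np.ndarray
    subject_id: str = ""
    class_label: int = -1
    sample_id: str = ""
    fps: float = 30.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError(
                f"positions must be T×V×3, got {self.positions.shape}"
            )
        if self.positions.shape[0] < 2:
            raise ValueError("a sequence needs at least 2 frames")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")

    @property
    def num_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def num_joints(self) -> int:
        return self.positions.shape[1]


def _parse_ntu_name(stem: str) -> dict:
    m = _NTU_NAME_RE.search(stem)
    if not m:
        return {}
    setup, camera, subject, rep, action = (int(g) for g in m.groups())
    return {
        "setup": setup,
        "camera": camera,
        "subject": subject,
        "replication": rep,
        "action": action,
    }


def read_ntu_skeleton(path: str | Path, fps: float = 30.0) -> SkeletonSequence:
    """Read the first tracked body of an NTU ``.skeleton`` text file.

    Per frame the format lists a body count, then for each body one
    body-info line, one joint-count line and 25 joint lines whose first
    three fields are x y z in meters.  Frames with several bodies keep
    the body with the highest summed tracking state (ties: first body);
    frames with no body repeat the last observed frame.
    """
    path = Path(path)
    lines = path.read_text().split("\n")
    pos = 0

    def next_line() -> tuple[str, int]:
        nonlocal pos
        while pos < len(lines):
            ln = lines[pos].strip()
            pos += 1
            if ln:
                return ln, pos
        raise ParseError(f"{path}: unexpected end of file at line {pos}")

    ln, at = next_line()
    try:
        n_frames = int(ln)
    except ValueError:
        raise ParseError(f"{path}: line {at}: expected frame count, got {ln!r}")
    if n_frames < 1:
        raise ParseError(f"{path}: nonpositive frame count {n_frames}")

    frames: list[np.ndarray | None] = []
    for f in range(n_frames):
        ln, at = next_line()
        try:
            n_bodies = int(ln)
        except ValueError:
            raise ParseError(
                f"{path}: line {at}: expected body count for frame {f}, "
                f"got {ln!r}"
            )
        best: np.ndarray | None = None
        best_conf = -np.inf
        for b in range(n_bodies):
            next_line()  # body-info line (tracking id, clipped flags, ...)
            ln, at = next_line()
            try:
                n_joints = int(ln)
            except ValueError:
                raise ParseError(
                    f"{path}: line {at}: expected joint count, got {ln!r}"
                )
            if n_joints != 25:
                raise ParseError(
                    f"{path}: frame {f}, body {b}: expected 25 joints, "
                    f"got {n_joints}"
                )
            joints = np.empty((25, 3))
            conf = 0.0
            for j in range(25):
                ln, at = next_line()
                fields = ln.split()
                if len(fields) < 3:
                    raise ParseError(
                        f"{path}: line {at}: joint line has "
                        f"{len(fields)} fields, expected >= 3"
                    )
                try:
                    joints[j] = [float(x) for x in fields[:3]]
                except ValueError:
                    raise ParseError(
                        f"{path}: line {at}: non-numeric joint coordinates"
                    )
                if len(fields) >= 12:
                    conf += float(fields[11])  # tracking state
            if conf > best_conf:
                best_conf, best = conf, joints
        frames.append(best)

    if all(fr is None for fr in frames):
        raise ParseError(f"{path}: no tracked body in any frame")

    # forward/backward-fill missing frames
    filled: list[np.ndarray] = []
    last = None
    n_missing = 0
    for fr in frames:
        if fr is None:
            n_missing += 1
            fr = last if last is not None else next(
                f for f in frames if f is not None
            )
        last = fr
        filled.append(fr)
    if n_missing:
        log.warning("%s: %d body-less frames filled by repetition",
                    path.name, n_missing)

    meta = _parse_ntu_name(path.stem)
    return SkeletonSequence(
        positions=np.stack(filled, axis=0),
        subject_id=f"P{meta['subject']:03d}" if meta else "",
        class_label=meta["action"] - 1 if meta else -1,
        sample_id=path.stem,
        fps=fps,
        extra=meta,
    )


def resample_sequence(seq: SkeletonSequence, t_target: int) -> SkeletonSequence:
    """Linearly resample to ``t_target`` frames spanning [0, T-1].

    Endpoints are preserved exactly; the fps metadata is rescaled so the
    clip keeps its wall-clock duration.
    """
    if t_target < 2:
        raise ValueError("t_target must be >= 2")
    T = seq.num_frames
    if t_target == T:
        return replace(seq, positions=seq.positions.copy())
    t_old = np.arange(T, dtype=np.float64)
    t_new = np.linspace(0.0, T - 1, t_target)
    flat = seq.positions.reshape(T, -1)
    out = np.empty((t_target, flat.shape[1]))
    for c in range(flat.shape[1]):
        out[:, c] = np.interp(t_new, t_old, flat[:, c])
    return replace(
        seq,
        positions=out.reshape(t_target, seq.num_joints, 3),
        fps=seq.fps * (t_target - 1) / (T - 1),
    )


def write_hdf5(
    sequences: list[SkeletonSequence],
    path: str | Path,
    features: dict[str, dict[str, np.ndarray]] | None = None,
) -> None:
    """Write sequences to an HDF5 container, one group per sample.

    ``features`` optionally maps sample_id → {branch name → 6×T×V array},
    stored under a ``features/`` subgroup for caching preprocessed
    branch streams alongside the raw positions.
    """
    path = Path(path)
    with h5py.File(path, "w") as h5:
        for i, seq in enumerate(sequences):
            name = seq.sample_id or f"sample{i:05d}"
            grp = h5.create_group(name)
            grp.create_dataset("positions", data=seq.positions)
            grp.attrs["subject_id"] = seq.subject_id
            grp.attrs["class_label"] = int(seq.class_label)
            grp.attrs["fps"] = float(seq.fps)
            if features and name in features:
                fg = grp.create_group("features")
                for branch, arr in features[name].items():
                    fg.create_dataset(branch, data=arr)


def read_hdf5(
    path: str | Path, with_features: bool = False
) -> list[SkeletonSequence] | tuple[list[SkeletonSequence], dict]:
    """Read every sample group of an HDF5 container (sorted by name)."""
    path = Path(path)
    seqs: list[SkeletonSequence] = []
    feats: dict[str, dict[str, np.ndarray]] = {}
    with h5py.File(path, "r") as h5:
        for name in sorted(h5.keys()):
            grp = h5[name]
            seq = SkeletonSequence(
                positions=grp["positions"][()],
                subject_id=str(grp.attrs.get("subject_id", "")),
                class_label=int(grp.attrs.get("class_label", -1)),
                sample_id=name,
                fps=float(grp.attrs.get("fps", 30.0)),
            )
            seqs.append(seq)
            if with_features and "features" in grp:
                feats[name] = {
                    k: grp["features"][k][()] for k in grp["features"]
                }
    if with_features:
        return seqs, feats
    return seqs


def sequence_to_csv(seq: SkeletonSequence, path: str | Path) -> None:
    """Dump one sequence as long-format CSV (frame, joint, x, y, z)."""
    T, V, _ = seq.positions.shape
    frame = np.repeat(np.arange(T), V)
    joint = np.tile(np.arange(V), T)
    flat = seq.positions.reshape(T * V, 3)
    pd.DataFrame(
        {"frame": frame, "joint": joint,
         "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2]}
    ).to_csv(path, index=False)
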