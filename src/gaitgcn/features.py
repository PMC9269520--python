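"""Multi-branch skeleton feature algebra.

From a raw T×V×3 trajectory three 6-channel input streams are derived:

* **joint**    — absolute coordinates x_i and coordinates relative to the
  center joint, r_i = x_i − x_c;
* **velocity** — one-frame and two-frame displacements,
  v1(t) = x(t+1) − x(t) and v2(t) = x(t+2) − x(t);
* **bone**     — per-joint vector to the parent joint, b_i = x_i − x_parent,
  and the componentwise direction angles a_i = arccos(b_i / ‖b_i‖).

All streams are stored channel-first (6×T×V) so they can feed the graph
network directly.  Velocity frames past the end of the clip are
zero-padded to keep the three streams at a common T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import SkeletonGraph
from .io import SkeletonSequence

__all__ = [
    "BranchFeatures",
    "BRANCH_NAMES",
    "relative_coordinates",
    "motion_velocity",
    "bone_features",
    "assemble_branches",
]

BRANCH_NAMES = ("joint", "velocity", "bone")


@dataclass
class BranchFeatures:
    """The three 6×T×V input streams of one sample."""

    joint: np.ndarray
    velocity: np.ndarray
    bone: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.joint, self.velocity, self.bone)}
        if len(shapes) != 1:
            raise ValueError(f"branch shapes differ: {shapes}")
        if self.joint.shape[0] != 6:
            raise ValueError("each branch must have 6 channels")

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in BRANCH_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n) for n in BRANCH_NAMES}


def relative_coordinates(
    seq: SkeletonSequence, center_joint: int
) -> np.ndarray:
    """r_i(t) = x_i(t) − x_center(t), per frame.  T×V×3."""
    x = seq.positions
    if not (0 <= center_joint < x.shape[1]):
        raise ValueError(f"center_joint {center_joint} out of range")
    return x - x[:, center_joint : center_joint + 1, :]


def motion_velocity(seq: SkeletonSequence) -> tuple[np.ndarray, np.ndarray]:
    """One- and two-frame displacements, each T×V×3.

    v1(t) = x(t+1) − x(t) for t < T−1, v2(t) = x(t+2) − x(t) for t < T−2;
    the trailing undefined frames are zero so all branches share T.
    """
    x = seq.positions
    T = x.shape[0]
    v1 = np.zeros_like(x)
    v2 = np.zeros_like(x)
    v1[: T - 1] = x[1:] - x[:-1]
    if T > 2:
        v2[: T - 2] = x[2:] - x[:-2]
    return v1, v2


def bone_features(
    seq: SkeletonSequence, graph: SkeletonGraph
) -> tuple[np.ndarray, np.ndarray]:
    """Bone vectors and componentwise direction angles, each T×V×3.

    b_i = x_i − x_parent(i) with the tree rooted at the center joint;
    the root itself gets the zero vector.  a_i = arccos(b_i / ‖b_i‖)
    componentwise, clamped to [−1, 1]; zero-length bones (including the
    root) get the neutral angle π/2 in all three components.
    """
    x = seq.positions
    T, V, _ = x.shape
    if V != graph.num_joints:
        raise ValueError(
            f"sequence has {V} joints but graph has {graph.num_joints}"
        )
    parent = graph.parent_of
    b = np.zeros_like(x)
    for child, par in parent.items():
        b[:, child] = x[:, child] - x[:, par]

    norm = np.linalg.norm(b, axis=2, keepdims=True)
    nonzero = norm[..., 0] > 0
    unit = np.divide(b, norm, out=np.zeros_like(b), where=norm > 0)
    a = np.full_like(b, np.pi / 2)
    a[nonzero] = np.arccos(np.clip(unit[nonzero], -1.0, 1.0))
    return b, a


def assemble_branches(
    seq: SkeletonSequence, graph: SkeletonGraph
) -> BranchFeatures:
    """Build the three 6×T×V input streams of one sequence.

    Channel layout: joint = (x, y, z, r_x, r_y, r_z); velocity =
    (v1_x, v1_y, v1_z, v2_x, v2_y, v2_z); bone = (b_x, b_y, b_z,
    a_x, a_y, a_z).
    """
    r = relative_coordinates(seq, graph.center_joint)
    v1, v2 = motion_velocity(seq)
    b, a = bone_features(seq, graph)

    def stack(first: np.ndarray, second: np.ndarray) -> np.ndarray:
        # T×V×3 pairs → 6×T×V
        return np.concatenate(
            [first.transpose(2, 0, 1), second.transpose(2, 0, 1)], axis=0
        )

    return BranchFeatures(
        joint=stack(seq.positions, r),
        velocity=stack(v1, v2),
        bone=stack(b, a),
    )
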