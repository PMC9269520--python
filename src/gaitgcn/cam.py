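"""Class-activation mapping on the skeleton graph.

After global average pooling, the classifier assigns one weight per
channel and class.  Projecting the target class's weight vector back
onto the final pre-pool feature map F (shape C×T'×V) gives a per-frame,
per-joint importance map

    M(t, v) = Σ_c w_c · F_c(t, v),

rectified at zero (negative evidence discarded) and normalized to sum
to one.  T' is the temporal length of the mainstream's last feature map
(T/4 after the two stride-2 blocks); for visualization the frame axis is
mapped back to input frames by nearest-neighbor upsampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import MIBNetwork
from .training import Sample

__all__ = ["ActivationMap", "skeleton_cam", "joint_importance",
           "cam_to_csv", "render_cam_overlay"]

log = logging.getLogger(__name__)


@dataclass
class ActivationMap:
    """Nonnegative per-frame, per-joint importance, normalized to sum 1."""

    values: np.ndarray  # T'×V
    class_queried: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("activation map must be T'×V")
        if np.any(self.values < 0):
            raise ValueError("activation map must be nonnegative")
        total = self.values.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError("activation map must sum to 1")

    def upsampled(self, t_frames: int) -> np.ndarray:
        """Nearest-neighbor map back to ``t_frames`` input frames."""
        t_prime = self.values.shape[0]
        idx = np.clip(
            np.round(np.arange(t_frames) * t_prime / t_frames).astype(int),
            0, t_prime - 1,
        )
        return self.values[idx]


def skeleton_cam(
    model: MIBNetwork, sample: Sample, target_class: int
) -> ActivationMap:
    """CAM of one sample for ``target_class``.

    Runs the sample through the trained network (eval mode), takes the
    final pre-pool feature map and the classifier's weight column for
    the queried class, and returns the rectified, normalized weighted
    sum over channels.  A map that is all zero after rectification
    degenerates to the uniform map (with a warning).
    """
    n_classes = model.config.num_classes
    if not 0 <= target_class < n_classes:
        raise ValueError(
            f"target_class {target_class} outside [0, {n_classes})"
        )
    batch = {
        name: sample.features[name][None].astype(np.float32)
        for name in model.branch_names
    }
    model.set_training(False)
    model.forward(batch)
    fmap = model.feature_map[0]          # T'×V×C
    W, _ = model.classifier_weights()    # C×num_classes
    raw = fmap.astype(np.float64) @ W[:, target_class].astype(np.float64)
    raw = np.maximum(raw, 0.0)
    total = raw.sum()
    if total <= 0.0:
        log.warning(
            "sample %s: all-zero activation for class %d; "
            "returning the uniform map", sample.sample_id, target_class,
        )
        raw = np.ones_like(raw)
        total = raw.sum()
    return ActivationMap(
        values=raw / total,
        class_queried=target_class,
        sample_id=sample.sample_id,
    )


def joint_importance(amap: ActivationMap) -> np.ndarray:
    """Per-joint importance mass (sums over frames; total mass 1)."""
    return amap.values.sum(axis=0)


def cam_to_csv(amap: ActivationMap, path: str | Path) -> None:
    t_prime, V = amap.values.shape
    frame = np.repeat(np.arange(t_prime), V)
    joint = np.tile(np.arange(V), t_prime)
    pd.DataFrame(
        {"frame": frame, "joint": joint, "weight": amap.values.ravel()}
    ).to_csv(path, index=False)


def render_cam_overlay(
    amap: ActivationMap,
    positions: np.ndarray,
    edges: list[tuple[int, int]],
    path: str | Path,
    frame: int | None = None,
) -> None:
    """Render one frame's skeleton with joints sized/colored by CAM mass."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    T = positions.shape[0]
    if frame is None:
        frame = T // 2
    weights = amap.upsampled(T)[frame]
    pts = positions[frame]
    fig, ax = plt.subplots(figsize=(4, 6))
    for i, j in edges:
        ax.plot([pts[i, 0], pts[j, 0]], [pts[i, 1], pts[j, 1]],
                color="0.6", lw=1, zorder=1)
    w = weights / weights.max() if weights.max() > 0 else weights
    ax.scatter(pts[:, 0], pts[:, 1], s=30 + 400 * w, c=w, cmap="hot",
               zorder=2, edgecolors="k", linewidths=0.3)
    ax.set_aspect("equal")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_title(f"CAM, class {amap.class_queried}, frame {frame}")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
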