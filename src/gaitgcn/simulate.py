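"""Kinematic simulator of normal and pathological walking.

Generates 25-joint Kinect-V2-topology skeleton sequences for six gait
classes — normal, antalgic, lurch, steppage, stiff-legged and
Trendelenburg — so the full recognition pipeline can be exercised
without any external dataset.

The body is a tree of rigid segments; per-frame joint positions are
composed hierarchically from seeded sinusoidal joint-angle trajectories
(hip flexion, knee flexion, ankle pitch, arm swing, trunk pitch/roll)
on top of a forward-progressing pelvis.  Stance and swing are
parameterized through an explicit duty-factor phase map, so stance time
can be shortened per leg.  Each pathological class perturbs the normal
cycle where clinicians describe its signature, scaled linearly by a
``severity`` in [0, 1]:

* **antalgic** — stance duty factor of the affected leg reduced, hip
  amplitude slightly damped (short, guarded steps);
* **lurch** — trunk pitched backward during affected-side stance;
* **steppage** — affected knee lift amplified with foot drop (high
  stepping to clear a dangling foot);
* **stiff_legged** — affected knee flexion suppressed and the leg
  circumducted laterally in a semicircular swing arc;
* **trendelenburg** — trunk and pelvis roll toward the affected side
  during its stance phase.

At severity 0 every class degenerates to the identical normal gait for
the same seed and anthropometry, giving a negative-control condition.
Isotropic Gaussian position noise (Kinect-like jitter) is added last.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import SkeletonSequence

__all__ = ["GAIT_CLASSES", "GaitParams", "simulate_sequence",
           "simulate_dataset"]

GAIT_CLASSES = (
    "normal", "antalgic", "lurch", "steppage", "stiff_legged",
    "trendelenburg",
)

# joint indices in the Kinect V2 SDK ordering
SPINE_BASE, SPINE_MID, NECK, HEAD = 0, 1, 2, 3
SHOULDER_L, ELBOW_L, WRIST_L, HAND_L = 4, 5, 6, 7
SHOULDER_R, ELBOW_R, WRIST_R, HAND_R = 8, 9, 10, 11
HIP_L, KNEE_L, ANKLE_L, FOOT_L = 12, 13, 14, 15
HIP_R, KNEE_R, ANKLE_R, FOOT_R = 16, 17, 18, 19
SPINE_SHOULDER = 20
HANDTIP_L, THUMB_L, HANDTIP_R, THUMB_R = 21, 22, 23, 24


@dataclass(frozen=True)
class GaitParams:
    """Conditions of one simulated walking trial.

    ``severity`` scales every class-specific deviation (0 = normal);
    ``noise_sd`` is the per-coordinate Gaussian jitter in meters;
    ``limb_scale`` multiplies all segment lengths (anthropometry).
    """

    gait_class: str = "normal"
    affected_side: str = "left"
    severity: float = 0.7
    cadence_hz: float = 0.9
    n_frames: int = 64
    noise_sd: float = 0.005
    limb_scale: float = 1.0
    fps: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gait_class not in GAIT_CLASSES:
            raise ValueError(
                f"unknown gait class {self.gait_class!r}; "
                f"expected one of {GAIT_CLASSES}"
            )
        if self.affected_side not in ("left", "right"):
            raise ValueError("affected_side must be 'left' or 'right'")
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _rot_x(theta: np.ndarray) -> np.ndarray:
    """(T,3,3) rotation about the lateral x axis (sagittal pitch)."""
    c, s = np.cos(theta), np.sin(theta)
    R = np.zeros(theta.shape + (3, 3))
    R[..., 0, 0] = 1.0
    R[..., 1, 1] = c
    R[..., 1, 2] = -s
    R[..., 2, 1] = s
    R[..., 2, 2] = c
    return R


def _rot_z(theta: np.ndarray) -> np.ndarray:
    """(T,3,3) rotation about the forward z axis (frontal roll)."""
    c, s = np.cos(theta), np.sin(theta)
    R = np.zeros(theta.shape + (3, 3))
    R[..., 2, 2] = 1.0
    R[..., 0, 0] = c
    R[..., 0, 1] = -s
    R[..., 1, 0] = s
    R[..., 1, 1] = c
    return R


def _apply(R: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate a fixed 3-vector by per-frame matrices: (T,3,3)·(3,) → (T,3)."""
    return np.einsum("tij,j->ti", R, v)


def _duty_phase(u: np.ndarray, stance_fraction: float) -> np.ndarray:
    """Map cycle fraction u ∈ [0,1) to gait phase ψ with a given duty factor.

    Stance occupies u ∈ [0, c) and maps to ψ ∈ [π, 2π); swing occupies
    the rest and maps to ψ ∈ [0, π).  At c = 0.5 this is the uniform
    phase ψ = 2πu + π (mod 2π).
    """
    c = stance_fraction
    psi = np.where(
        u < c,
        np.pi + np.pi * u / c,
        np.pi * (u - c) / (1.0 - c),
    )
    return psi


def simulate_sequence(params: GaitParams) -> SkeletonSequence:
    """Generate one T×25×3 walking sequence for the given parameters."""
    p = params
    rng = np.random.default_rng(p.seed)
    s = p.severity
    left_affected = p.affected_side == "left"
    side_sign = 1.0 if left_affected else -1.0  # +x is the left direction

    # segment lengths (m), scaled by anthropometry
    L = p.limb_scale
    thigh, shank = 0.40 * L, 0.40 * L
    foot_v = np.array([0.0, -0.05, 0.13]) * L
    hip_off = np.array([0.09, -0.05, 0.0]) * L
    sb_sm = 0.22 * L          # SpineBase → SpineMid
    sm_ss = 0.22 * L          # SpineMid → SpineShoulder
    ss_neck, neck_head = 0.07 * L, 0.15 * L
    sh_off = np.array([0.18, -0.02, 0.0]) * L
    upper_arm, forearm = 0.26 * L, 0.24 * L
    hand = 0.08 * L

    T = p.n_frames
    t = np.arange(T) / p.fps
    phase0 = rng.uniform(0.0, 1.0)       # cycle-fraction offset of the trial
    u_left = (p.cadence_hz * t + phase0) % 1.0
    u_right = (u_left + 0.5) % 1.0

    cls = p.gait_class
    # per-leg stance duty factor (antalgic shortens the affected side)
    duty_l = duty_r = 0.5
    if cls == "antalgic":
        shortened = 0.5 * (1.0 - 0.55 * s)
        if left_affected:
            duty_l = shortened
        else:
            duty_r = shortened
    psi_l = _duty_phase(u_left, duty_l)
    psi_r = _duty_phase(u_right, duty_r)
    psi_aff = psi_l if left_affected else psi_r
    # smooth positive weight during affected-side stance (ψ ∈ [π, 2π))
    w_stance = np.maximum(0.0, -np.sin(psi_aff))
    w_swing = np.maximum(0.0, np.sin(psi_aff))

    # hip / knee / ankle angle trajectories
    a_hip = 0.40
    hip_amp_l = hip_amp_r = a_hip
    knee_amp_l = knee_amp_r = 1.0
    foot_drop = np.zeros(T)
    circumduction = np.zeros(T)
    if cls == "antalgic":
        damp = 1.0 - 0.35 * s
        if left_affected:
            hip_amp_l *= damp
        else:
            hip_amp_r *= damp
    elif cls == "steppage":
        boost = 1.0 + 1.4 * s
        if left_affected:
            knee_amp_l *= boost
        else:
            knee_amp_r *= boost
        foot_drop = 0.55 * s * w_swing
    elif cls == "stiff_legged":
        damp = 1.0 - 0.85 * s
        if left_affected:
            knee_amp_l *= damp
        else:
            knee_amp_r *= damp
        circumduction = 0.40 * s * w_swing

    hip_l = hip_amp_l * np.sin(psi_l)
    hip_r = hip_amp_r * np.sin(psi_r)
    a_knee = 0.75
    knee_l = a_knee * knee_amp_l * np.maximum(0.0, np.sin(psi_l)) ** 2
    knee_r = a_knee * knee_amp_r * np.maximum(0.0, np.sin(psi_r)) ** 2
    ankle_l = 0.15 * np.sin(psi_l)
    ankle_r = 0.15 * np.sin(psi_r)
    if cls == "steppage":
        if left_affected:
            ankle_l = ankle_l - foot_drop
        else:
            ankle_r = ankle_r - foot_drop
    abd_l = np.zeros(T)
    abd_r = np.zeros(T)
    if cls == "stiff_legged":
        # lateral semicircular swing arc of the affected leg
        if left_affected:
            abd_l = circumduction
        else:
            abd_r = -circumduction

    # trunk pitch (about x; negative = backward lean) and roll (about z)
    pitch = 0.03 * np.sin(2.0 * np.pi * (2.0 * p.cadence_hz) * t)
    roll = 0.04 * np.sin(psi_l)
    pelvis_roll = 0.5 * roll
    if cls == "lurch":
        pitch = pitch - 0.40 * s * w_stance
    elif cls == "trendelenburg":
        # primary sign: pelvic obliquity (swing-side drop) during
        # affected stance, with compensatory trunk lean toward the
        # affected side (negative z-rotation tilts the +y trunk axis
        # toward +x/left)
        roll = roll - side_sign * 0.35 * s * w_stance
        pelvis_roll = pelvis_roll - side_sign * 0.35 * s * w_stance

    # pelvis trajectory
    speed = 1.15 * L * (p.cadence_hz / 0.9)
    base_h = (thigh + shank + 0.10 * L)
    bob = 0.02 * L * np.sin(2.0 * np.pi * (2.0 * p.cadence_hz) * t)
    sway = 0.025 * L * np.sin(psi_l)
    root = np.stack([sway, base_h + bob, speed * t], axis=1)

    X = np.zeros((T, 25, 3))
    X[:, SPINE_BASE] = root

    R_pelvis = _rot_z(pelvis_roll)
    R_trunk = np.matmul(_rot_x(pitch), _rot_z(roll))
    # head righting and pendulum arms: the head-neck chain and the
    # hanging arms compensate most of the trunk inclination (vestibular
    # head stabilization; arms hang under gravity), so trunk pitch/roll
    # reads out at the shoulder girdle and pelvis rather than being
    # amplified down the longest levers
    RIGHTING = 0.75
    R_head = np.matmul(_rot_x((1 - RIGHTING) * pitch),
                       _rot_z((1 - RIGHTING) * roll))

    # torso and head
    X[:, SPINE_MID] = root + _apply(R_trunk, np.array([0.0, sb_sm, 0.0]))
    X[:, SPINE_SHOULDER] = X[:, SPINE_MID] + _apply(
        R_trunk, np.array([0.0, sm_ss, 0.0]))
    X[:, NECK] = X[:, SPINE_SHOULDER] + _apply(
        R_head, np.array([0.0, ss_neck, 0.0]))
    X[:, HEAD] = X[:, NECK] + _apply(
        R_head, np.array([0.0, neck_head, 0.0]))

    # arms: swing opposite to the same-side leg, fixed elbow flexion
    elbow_flex = 0.35
    for sign, psi, (sh, el, wr, ha, tip, th) in (
        (+1.0, psi_l, (SHOULDER_L, ELBOW_L, WRIST_L, HAND_L,
                       HANDTIP_L, THUMB_L)),
        (-1.0, psi_r, (SHOULDER_R, ELBOW_R, WRIST_R, HAND_R,
                       HANDTIP_R, THUMB_R)),
    ):
        arm_swing = -0.35 * a_hip * np.sin(psi)
        X[:, sh] = X[:, SPINE_SHOULDER] + _apply(
            R_trunk, sh_off * np.array([sign, 1.0, 1.0]))
        R_arm = np.matmul(R_head, _rot_x(arm_swing))
        X[:, el] = X[:, sh] + _apply(R_arm, np.array([0.0, -upper_arm, 0.0]))
        R_fore = np.matmul(R_arm, _rot_x(np.full(T, elbow_flex)))
        X[:, wr] = X[:, el] + _apply(R_fore, np.array([0.0, -forearm, 0.0]))
        X[:, ha] = X[:, wr] + _apply(R_fore, np.array([0.0, -hand, 0.0]))
        X[:, tip] = X[:, ha] + _apply(
            R_fore, np.array([0.0, -0.04 * L, 0.0]))
        X[:, th] = X[:, wr] + _apply(
            R_fore, np.array([sign * 0.05 * L, -0.02 * L, 0.0]))

    # legs: hip flexion (sagittal) + abduction (frontal), knee, ankle
    for sign, psi, hip_flex, knee_flex, ankle_pitch, abd, (hp, kn, an, ft) in (
        (+1.0, psi_l, hip_l, knee_l, ankle_l, abd_l,
         (HIP_L, KNEE_L, ANKLE_L, FOOT_L)),
        (-1.0, psi_r, hip_r, knee_r, ankle_r, abd_r,
         (HIP_R, KNEE_R, ANKLE_R, FOOT_R)),
    ):
        X[:, hp] = root + _apply(
            R_pelvis, hip_off * np.array([sign, 1.0, 1.0]))
        R_thigh = np.matmul(R_pelvis,
                            np.matmul(_rot_z(abd), _rot_x(hip_flex)))
        X[:, kn] = X[:, hp] + _apply(R_thigh, np.array([0.0, -thigh, 0.0]))
        R_shank = np.matmul(R_thigh, _rot_x(knee_flex))
        X[:, an] = X[:, kn] + _apply(R_shank, np.array([0.0, -shank, 0.0]))
        R_foot = np.matmul(R_shank, _rot_x(ankle_pitch))
        X[:, ft] = X[:, an] + _apply(R_foot, foot_v)

    if p.noise_sd > 0:
        X = X + rng.normal(0.0, p.noise_sd, size=X.shape)

    return SkeletonSequence(
        positions=X,
        class_label=GAIT_CLASSES.index(cls),
        sample_id=f"{cls}_s{p.seed}",
        fps=p.fps,
        extra={"severity": s, "affected_side": p.affected_side,
               "limb_scale": p.limb_scale, "cadence_hz": p.cadence_hz},
    )


def simulate_dataset(
    n_subjects: int,
    trials_per_class: int,
    shared: GaitParams | None = None,
    seed: int = 0,
) -> list[SkeletonSequence]:
    """Simulate a balanced multi-subject dataset.

    Every subject receives randomized anthropometry (limb scale, cadence)
    and a randomized affected side, then contributes ``trials_per_class``
    trials of each of the six classes.  Trial-level randomness (cycle
    phase, sensor noise) comes from per-trial seeds derived from ``seed``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for subject-wise splits")
    if shared is None:
        shared = GaitParams()
    sequences: list[SkeletonSequence] = []
    for si in range(n_subjects):
        subj_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(si,))
        )
        limb = float(np.clip(subj_rng.normal(1.0, 0.06), 0.8, 1.2))
        cadence = float(np.clip(subj_rng.normal(
            shared.cadence_hz, 0.08), 0.6, 1.3))
        side = "left" if subj_rng.random() < 0.5 else "right"
        subject_id = f"S{si:02d}"
        for ci, cls in enumerate(GAIT_CLASSES):
            for trial in range(trials_per_class):
                # trial-level seed: deterministic in (seed, subject,
                # class, trial), independent of iteration order
                trial_seed = int(
                    np.random.default_rng(
                        np.random.SeedSequence(
                            entropy=seed, spawn_key=(si, ci, trial))
                    ).integers(0, 2**31 - 1)
                )
                params = replace(
                    shared,
                    gait_class=cls,
                    affected_side=side,
                    limb_scale=limb,
                    cadence_hz=cadence,
                    seed=trial_seed,
                )
                seq = simulate_sequence(params)
                seq.subject_id = subject_id
                seq.sample_id = f"{subject_id}_{cls}_{trial:02d}"
                sequences.append(seq)
    return sequences
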