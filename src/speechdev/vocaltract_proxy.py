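"""Parametric articulatory-acoustic stand-in that executes gesture scores.

This module turns fully specified gesture scores into

* articulatory trajectories (4 channels x 64 frames of 10 ms: lips aperture,
  tongue-tip and tongue-body distance-to-wall, jaw elevation), which double
  as the somatosensory state;
* bark-scaled formant-pattern auditory states (24 channels x 64 frames);
* agonist/antagonist neuromuscular patterns (2 x 64 frames x 10 muscle
  groups), the motor-program state.

Articulator channels follow critically damped second-order target tracking:
while a gesture is active the channel is driven toward the gesture's
quantitative target, otherwise it relaxes toward a neutral posture.  With a
constant target T, stiffness omega and initial state (y0, v0) the closed
form is ``y(t) = T + (a + b t) e^(-omega t)`` with ``a = y0 - T`` and
``b = v0 + omega (y0 - T)``; integration composes this form exactly over the
10 ms frame grid.

All acoustic numbers (vowel formant targets, consonant loci, murmur
resonances) are synthetic stand-ins chosen for plausibility and pairwise
distinctness of the produced patterns, not measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .gestures import (
    FULL_CLOSING,
    GLOTTAL_CLOSING,
    GLOTTAL_OPENING,
    GLOTTAL_TIGHT_CLOSING,
    LABIAL_SHAPING,
    LATERAL_CONSTRICTION,
    NEAR_CLOSING,
    TRACT_SHAPING,
    VELO_CLOSING,
    VELO_OPENING,
    VELO_TIGHT_CLOSING,
    FullGesture,
    FullGestureScore,
)

__all__ = [
    "ProxyConfig",
    "ArticulatoryTrajectory",
    "AuditoryPattern",
    "MotorProgramPattern",
    "bark",
    "execute",
    "auditory_render",
    "neuromuscular",
    "motor_plan_vector",
    "MOTOR_PLAN_DIM",
    "syllable_patterns",
    "save_patterns",
    "load_patterns",
    "pattern_to_csv",
]

ArticulatoryTrajectory = np.ndarray  # (4, 64)
AuditoryPattern = np.ndarray  # (24, 64)
MotorProgramPattern = np.ndarray  # (2, 64, 10)

N_AUD_CHANNELS = 24
N_SOMA_CHANNELS = 4
N_MUSCLE_GROUPS = 10

# somatosensory channel indices
LIPS, TIP, BODY, JAW = 0, 1, 2, 3

_CONSTRICTION_CHANNEL = {"labial": LIPS, "apical": TIP, "dorsal": BODY}


@dataclass(frozen=True)
class ProxyConfig:
    """Synthetic articulatory/acoustic parameters (stand-ins, not measured)."""

    neutral: tuple[float, float, float, float] = (0.6, 0.7, 0.7, 0.4)
    #: per-vowel (F1, F2, F3) targets in Hz
    vowel_formants: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "a": (730.0, 1090.0, 2440.0),
            "i": (270.0, 2290.0, 3010.0),
            "u": (300.0, 870.0, 2240.0),
            "e": (530.0, 1840.0, 2480.0),
            "o": (570.0, 840.0, 2410.0),
        }
    )
    #: per-place (F1, F2, F3) consonant loci in Hz; the labial locus lowers
    #: F2, the apical locus raises it, the dorsal locus converges F2/F3
    loci: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "labial": (250.0, 800.0, 2000.0),
            "apical": (350.0, 1800.0, 2700.0),
            "dorsal": (300.0, 1700.0, 2050.0),
            "lateral": (400.0, 1500.0, 2900.0),
        }
    )
    aspiration_amplitude: float = 0.6
    #: nasal-murmur resonances during a voiced closure with open velic port
    murmur: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "labial": (250.0, 900.0),
            "apical": (250.0, 1300.0),
            "dorsal": (250.0, 1700.0),
        }
    )
    voice_bar_hz: float = 120.0
    closure_threshold: float = 0.08
    #: channel value at which a constriction no longer colours the formants
    open_reference: float = 0.5
    #: per-vowel jaw elevation targets
    jaw_by_vowel: dict[str, float] = field(
        default_factory=lambda: {"a": 0.15, "i": 0.5, "u": 0.5, "e": 0.35, "o": 0.35}
    )
    jaw_consonant: float = 0.65
    noise_sigma: float = 0.02


DEFAULT_PROXY = ProxyConfig()


def bark(f_hz: float) -> float:
    """Critical-band rate (bark) of a frequency in Hz."""
    return 13.0 * math.atan(0.00076 * f_hz) + 3.5 * math.atan((f_hz / 7500.0) ** 2)


def _bark_channel(f_hz: float) -> int:
    return int(min(max(bark(f_hz), 0.0), N_AUD_CHANNELS - 1))


def _paint_ridge(pattern: np.ndarray, frame: int, f_hz: float, amp: float = 1.0) -> None:
    """Paint one formant ridge, splitting energy across the two bark
    channels straddling the exact critical-band position (keeps sub-channel
    frequency differences visible in the 24-channel pattern)."""
    z = min(max(bark(f_hz), 0.0), N_AUD_CHANNELS - 1.0)
    lo = int(z)
    frac = z - lo
    pattern[lo, frame] = max(pattern[lo, frame], amp * (1.0 - frac))
    if frac > 0 and lo + 1 < N_AUD_CHANNELS:
        pattern[lo + 1, frame] = max(pattern[lo + 1, frame], amp * frac)


def _active(fg: FullGesture, t_ms: float) -> bool:
    return fg.activation_onset <= t_ms < fg.activation_offset


# ---------------------------------------------------------------------------
# Articulatory execution
# ---------------------------------------------------------------------------


def _frame_targets(
    score: FullGestureScore, config: ProxyConfig
) -> np.ndarray:
    """Per-frame target value for each somatosensory channel.

    Vocalic shaping gestures set channel targets at low priority; consonantal
    constriction gestures override them on their channel (and raise the jaw)
    while active.  Channels without an active gesture relax to neutral.
    """
    n = score.n_frames
    targets = np.tile(np.asarray(config.neutral, float)[:, None], (1, n))
    # low priority: vocalic shaping
    for fg in score.gestures:
        for i in range(n):
            t = (i + 0.5) * score.frame_ms
            if not _active(fg, t):
                continue
            if fg.gesture.gtype == TRACT_SHAPING:
                targets[BODY, i] = fg.target_value
                targets[JAW, i] = config.jaw_by_vowel.get(fg.gesture.target, 0.35)
            elif fg.gesture.gtype == LABIAL_SHAPING:
                targets[LIPS, i] = fg.target_value
    # high priority: consonantal constrictions
    for fg in score.gestures:
        if fg.gesture.gtype not in (FULL_CLOSING, NEAR_CLOSING, LATERAL_CONSTRICTION):
            continue
        ch = _CONSTRICTION_CHANNEL[fg.gesture.articulator]
        for i in range(n):
            t = (i + 0.5) * score.frame_ms
            if _active(fg, t):
                targets[ch, i] = fg.target_value
                targets[JAW, i] = config.jaw_consonant
    return targets


def _track(targets: np.ndarray, omega: float, dt_s: float, y0: np.ndarray) -> np.ndarray:
    """Exact piecewise integration of the critically damped tracker."""
    n_ch, n = targets.shape
    y = y0.astype(float).copy()
    v = np.zeros(n_ch)
    out = np.empty((n_ch, n))
    decay = math.exp(-omega * dt_s)
    for i in range(n):
        T = targets[:, i]
        a = y - T
        b = v + omega * a
        y = T + (a + b * dt_s) * decay
        v = (b - omega * (a + b * dt_s)) * decay
        out[:, i] = y
    return out


def execute(
    score: FullGestureScore, config: ProxyConfig = DEFAULT_PROXY
) -> ArticulatoryTrajectory:
    """Articulatory trajectory (4 x 64) for a motor program, clipped to [0, 1]."""
    targets = _frame_targets(score, config)
    omega = score.gestures[0].velocity if score.gestures else 100.0
    traj = _track(targets, omega, score.frame_ms / 1000.0, np.asarray(config.neutral))
    return np.clip(traj, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Auditory rendering
# ---------------------------------------------------------------------------


def _voiced(score: FullGestureScore, t: float) -> bool:
    """Phonation at time t: a glottal closing gesture active and no
    devoicing gesture still within its target-plus-release phase."""
    closing = any(
        fg.gesture.gtype == GLOTTAL_CLOSING and _active(fg, t) for fg in score.gestures
    )
    devoiced = any(
        fg.gesture.gtype in (GLOTTAL_OPENING, GLOTTAL_TIGHT_CLOSING)
        and fg.target_start <= t < fg.activation_offset
        for fg in score.gestures
    )
    return closing and not devoiced


def _nasal_open(score: FullGestureScore, t: float) -> bool:
    return any(
        fg.gesture.gtype == VELO_OPENING and _active(fg, t) for fg in score.gestures
    )


def auditory_render(
    traj: ArticulatoryTrajectory,
    score: FullGestureScore,
    config: ProxyConfig = DEFAULT_PROXY,
    rng: np.random.Generator | None = None,
    noise_sigma: float | None = None,
) -> AuditoryPattern:
    """Bark-scaled formant pattern (24 x 64) for an executed score.

    Voiced open-tract frames paint unit ridges at F1-F3, interpolated
    between the consonant locus and the vowel target proportionally to the
    constriction state; voiced closures paint a voice bar (plus murmur
    resonances when the velic port is open); voiceless or closed-glottis
    frames are silent (all-zero columns).
    """
    n = score.n_frames
    pattern = np.zeros((N_AUD_CHANNELS, n))
    constrictions = [
        fg
        for fg in score.gestures
        if fg.gesture.gtype in (FULL_CLOSING, NEAR_CLOSING, LATERAL_CONSTRICTION)
    ]
    tract_gestures = [
        fg for fg in score.gestures if fg.gesture.gtype == TRACT_SHAPING
    ]
    for i in range(n):
        t = (i + 0.5) * score.frame_ms
        voiced = _voiced(score, t)
        aspirated = not voiced and any(
            fg.gesture.gtype == GLOTTAL_OPENING and _active(fg, t)
            for fg in score.gestures
        )
        if not voiced and not aspirated:
            continue
        # oral closure state from the trajectory
        closed = bool(np.min(traj[(LIPS, TIP, BODY), i]) < config.closure_threshold)
        if closed:
            if voiced:
                _paint_ridge(pattern, i, config.voice_bar_hz)
                if _nasal_open(score, t):
                    active_c = [fg for fg in constrictions if _active(fg, t)]
                    place = active_c[0].gesture.articulator if active_c else "apical"
                    for f in config.murmur[place]:
                        _paint_ridge(pattern, i, f)
            continue  # voiceless closure: silence (no burst model)
        # open tract: formant frame (aspiration noise excites the formants
        # at reduced amplitude during voiceless open frames)
        active_v = [fg for fg in tract_gestures if _active(fg, t)]
        if not active_v:
            continue  # no vocalic shape specified: silence
        vowel = active_v[0].gesture.target
        formants = np.asarray(config.vowel_formants[vowel])
        active_c = [fg for fg in constrictions if _active(fg, t)]
        if active_c:
            fg = active_c[0]
            ch = _CONSTRICTION_CHANNEL[fg.gesture.articulator]
            alpha = float(np.clip(traj[ch, i] / config.open_reference, 0.0, 1.0))
            locus_key = (
                "lateral"
                if fg.gesture.gtype == LATERAL_CONSTRICTION
                else fg.gesture.articulator
            )
            loci = np.asarray(config.loci[locus_key])
            formants = loci + alpha * (formants - loci)
        amp = 1.0 if voiced else config.aspiration_amplitude
        for f in formants:
            _paint_ridge(pattern, i, float(f), amp)
    sigma = config.noise_sigma if noise_sigma is None else noise_sigma
    if rng is not None and sigma > 0:
        pattern = np.clip(pattern + rng.normal(0.0, sigma, pattern.shape), 0.0, None)
    return pattern


# ---------------------------------------------------------------------------
# Neuromuscular (motor program) patterns
# ---------------------------------------------------------------------------

#: muscle-group layout: three articulator pairs, then velum/glottis/jaw and
#: one reserve group
_MUSCLE_GROUP = {
    (FULL_CLOSING, "labial"): 0,
    (NEAR_CLOSING, "labial"): 0,
    (LABIAL_SHAPING, None): 1,
    (FULL_CLOSING, "apical"): 2,
    (NEAR_CLOSING, "apical"): 2,
    (LATERAL_CONSTRICTION, "apical"): 3,
    (FULL_CLOSING, "dorsal"): 4,
    (NEAR_CLOSING, "dorsal"): 4,
    (TRACT_SHAPING, None): 5,
    (VELO_CLOSING, None): 6,
    (VELO_TIGHT_CLOSING, None): 6,
    (VELO_OPENING, None): 6,
    (GLOTTAL_CLOSING, None): 7,
    (GLOTTAL_OPENING, None): 7,
    (GLOTTAL_TIGHT_CLOSING, None): 7,
}
JAW_GROUP = 8
ANTAGONIST_DRIVE = 0.5


def _muscle_group(fg: FullGesture) -> int:
    key = (fg.gesture.gtype, fg.gesture.articulator)
    if key in _MUSCLE_GROUP:
        return _MUSCLE_GROUP[key]
    return _MUSCLE_GROUP[(fg.gesture.gtype, None)]


def _agonist_drive(fg: FullGesture) -> float:
    # drive is monotone in the target value, so opposite targets on one
    # muscle group (e.g. velic opening vs tight closing) stay distinct
    return float(np.clip(0.25 + 0.7 * fg.target_value, 0.0, 1.0))


def neuromuscular(
    score: FullGestureScore, config: ProxyConfig = DEFAULT_PROXY
) -> MotorProgramPattern:
    """Agonist/antagonist activation (2 x 64 x 10 muscle groups).

    The agonist channel carries the drive toward the target over the
    frame-quantized [activation onset, target end) interval; the antagonist
    carries the braking drive over the release interval.
    """
    n = score.n_frames
    pattern = np.zeros((2, n, N_MUSCLE_GROUPS))
    for fg in score.gestures:
        group = _muscle_group(fg)
        drive = _agonist_drive(fg)
        for i in range(n):
            t = (i + 0.5) * score.frame_ms
            if fg.activation_onset <= t < fg.target_end:
                pattern[0, i, group] += drive
                if fg.gesture.gtype in (
                    FULL_CLOSING,
                    NEAR_CLOSING,
                    LATERAL_CONSTRICTION,
                ):
                    pattern[0, i, JAW_GROUP] += 0.4
            elif fg.target_end <= t < fg.activation_offset:
                pattern[1, i, group] += ANTAGONIST_DRIVE
    return np.clip(pattern, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Motor plan encoding and pattern bundles
# ---------------------------------------------------------------------------

#: fixed gesture-slot layout (tier, slot count) for plan encoding
_PLAN_SLOTS = (("tract", 2), ("constr", 2), ("velo", 3), ("glottal", 3))
MOTOR_PLAN_DIM = sum(n for _, n in _PLAN_SLOTS) * 10

_ARTICULATOR_ID = {
    None: 0.0,
    "lips": 0.1,
    "labial": 0.2,
    "apical": 0.3,
    "dorsal": 0.4,
    "tongue_body": 0.5,
}


def motor_plan_vector(score: FullGestureScore) -> np.ndarray:
    """Flattened 10-parameter-per-gesture motor plan encoding.

    Per gesture slot: four time points (normalized to score duration), two
    target values and one articulator code; the remaining three slots are
    reserved zero padding.
    """
    vec = np.zeros(MOTOR_PLAN_DIM)
    by_tier: dict[str, list[FullGesture]] = {t: [] for t, _ in _PLAN_SLOTS}
    for fg in score.gestures:
        by_tier[fg.tier].append(fg)
    offset = 0
    for tier, n_slots in _PLAN_SLOTS:
        gest = sorted(by_tier[tier], key=lambda fg: (fg.span, fg.gesture.label))
        for j, fg in enumerate(gest[:n_slots]):
            base = offset + j * 10
            d = score.duration_ms
            vec[base : base + 7] = [
                fg.activation_onset / d,
                fg.target_start / d,
                fg.target_end / d,
                fg.activation_offset / d,
                fg.target_value,
                fg.target_value2,
                _ARTICULATOR_ID.get(fg.gesture.articulator, 0.6),
            ]
        offset += n_slots * 10
    return vec


def syllable_patterns(
    score: FullGestureScore,
    config: ProxyConfig = DEFAULT_PROXY,
    rng: np.random.Generator | None = None,
    noise_sigma: float | None = None,
) -> dict[str, np.ndarray]:
    """All state-map patterns for one motor program.

    With an ``rng``, Gaussian noise of the configured sigma is added to the
    auditory and somatosensory patterns (one rendition); without, the
    noiseless prototype is returned.
    """
    traj = execute(score, config)
    aud = auditory_render(traj, score, config, rng=rng, noise_sigma=noise_sigma)
    soma = traj
    if rng is not None:
        sigma = config.noise_sigma if noise_sigma is None else noise_sigma
        if sigma > 0:
            soma = np.clip(traj + rng.normal(0.0, sigma, traj.shape), 0.0, 1.0)
    return {
        "auditory": aud,
        "somatosensory": soma,
        "motor_program": neuromuscular(score, config),
        "motor_plan": motor_plan_vector(score),
    }


def save_patterns(path: str, patterns: dict[str, np.ndarray]) -> None:
    np.savez_compressed(path, **patterns)


def load_patterns(path: str) -> dict[str, np.ndarray]:
    with np.load(path) as data:
        return {k: data[k] for k in data.files}


def pattern_to_csv(pattern: np.ndarray) -> str:
    """CSV export (one row per channel) for inspection."""
    mat = pattern.reshape(pattern.shape[0], -1)
    return "\n".join(",".join(f"{v:.4f}" for v in row) for row in mat) + "\n"
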