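"""Gesture algebra: from phonemes to raw and fully specified gesture scores.

A *gesture* is a target-directed articulatory movement unit (e.g. a labial
full-closing gesture, a velopharyngeal opening gesture).  A syllable's
gestures are arranged on four articulatory tiers:

========  ==========================================================
tract     global vocal-tract shaping + labial shaping (vocalic)
constr    local constriction forming (full/near closing, lateral)
velo      velopharyngeal closing / tight closing / opening
glottal   glottal closing (phonation) / opening / tight closing
========  ==========================================================

A *raw gesture score* (motor plan) is the discrete, tier-ordered arrangement
of gestures with segment spans; adjacent identical gestures on a tier
assimilate into one spanning gesture.  A *fully specified gesture score*
(motor program) adds, per gesture, four points in time (activation onset,
target-phase start/end, activation offset, in ms on a 640 ms / 10 ms-frame
grid), a quantitative target value and a velocity (stiffness) parameter.

Motor programming for an unlearned syllable proceeds by *adapting*: the time
points of a phonologically similar donor program are copied verbatim and only
the gesture identities/targets that differ from the target motor plan are
substituted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

from .phonology import (
    GLOTTAL_STOP,
    LATERAL,
    NASAL,
    PLOSIVE,
    VOWEL,
    Phoneme,
    Syllable,
)

__all__ = [
    "Gesture",
    "TimedGesture",
    "RawGestureScore",
    "FullGesture",
    "FullGestureScore",
    "TimingPolicy",
    "ExpansionError",
    "SpecificationError",
    "AdaptationError",
    "TIERS",
    "expand_phoneme",
    "gesture_features",
    "segment_features_from_gestures",
    "build_raw_score",
    "specify_full",
    "adapt_score",
    "substitution_count",
    "SubstitutionSummary",
    "score_to_textgrid",
    "full_score_to_json",
]


class ExpansionError(ValueError):
    """Phoneme class has no known gesture bundle."""


class SpecificationError(ValueError):
    """Timing policy produced inverted time points."""


class AdaptationError(ValueError):
    """Donor and target plan have incompatible gesture-count skeletons.

    This is the (unimplemented) case where a motor program would have to be
    assembled from sub-syllabic parts rather than adapted.
    """


TIERS = ("tract", "constr", "velo", "glottal")

# gesture types
TRACT_SHAPING = "vocal_tract_shaping"
LABIAL_SHAPING = "labial_shaping"
FULL_CLOSING = "full_closing"
NEAR_CLOSING = "near_closing"
LATERAL_CONSTRICTION = "lateral_constriction"
VELO_CLOSING = "velopharyngeal_closing"
VELO_TIGHT_CLOSING = "velopharyngeal_tight_closing"
VELO_OPENING = "velopharyngeal_opening"
GLOTTAL_CLOSING = "glottal_closing"  # closing for phonation
GLOTTAL_OPENING = "glottal_opening"
GLOTTAL_TIGHT_CLOSING = "glottal_tight_closing"

_CONSTRICTION_TYPES = {FULL_CLOSING, NEAR_CLOSING, LATERAL_CONSTRICTION}

_TIER_OF = {
    TRACT_SHAPING: "tract",
    LABIAL_SHAPING: "tract",
    FULL_CLOSING: "constr",
    NEAR_CLOSING: "constr",
    LATERAL_CONSTRICTION: "constr",
    VELO_CLOSING: "velo",
    VELO_TIGHT_CLOSING: "velo",
    VELO_OPENING: "velo",
    GLOTTAL_CLOSING: "glottal",
    GLOTTAL_OPENING: "glottal",
    GLOTTAL_TIGHT_CLOSING: "glottal",
}


@dataclass(frozen=True)
class Gesture:
    """One articulatory gesture: type, performing articulator, symbolic target.

    Constriction gestures carry a labial/apical/dorsal articulator; the
    velopharyngeal and glottal gestures act on a fixed articulator and carry
    none.
    """

    gtype: str
    articulator: str | None = None
    target: str | None = None

    def __post_init__(self) -> None:
        if self.gtype not in _TIER_OF:
            raise ExpansionError(f"unknown gesture type {self.gtype!r}")
        if self.gtype in _CONSTRICTION_TYPES:
            if self.articulator not in ("labial", "apical", "dorsal"):
                raise ExpansionError(
                    f"constriction gesture needs labial/apical/dorsal articulator, "
                    f"got {self.articulator!r}"
                )
        elif self.articulator is not None and self.gtype not in (
            TRACT_SHAPING,
            LABIAL_SHAPING,
        ):
            raise ExpansionError(f"{self.gtype} carries no articulator")

    @property
    def tier(self) -> str:
        return _TIER_OF[self.gtype]

    @property
    def label(self) -> str:
        parts = [self.gtype]
        if self.articulator:
            parts.append(self.articulator)
        if self.target:
            parts.append(self.target)
        return ":".join(parts)


def expand_phoneme(p: Phoneme) -> frozenset[Gesture]:
    """The gesture bundle realizing one phoneme.

    Vowels expand to four gestures (tract shaping, labial shaping,
    velopharyngeal closing, glottal closing/phonation); consonants to the
    constriction/velic/glottal triple determined by class and voicing; the
    glottal stop to a glottal tight closing plus velopharyngeal closing.
    """
    if p.sound_class == VOWEL:
        rounded = "rounded" if p.symbol in ("u", "o", "y") else "unrounded"
        return frozenset(
            {
                Gesture(TRACT_SHAPING, "tongue_body", p.symbol),
                Gesture(LABIAL_SHAPING, "lips", rounded),
                Gesture(VELO_CLOSING),
                Gesture(GLOTTAL_CLOSING),
            }
        )
    if p.sound_class == PLOSIVE:
        glottal = GLOTTAL_CLOSING if p.voicing == "voiced" else GLOTTAL_OPENING
        return frozenset(
            {
                Gesture(FULL_CLOSING, p.place, "closure"),
                Gesture(VELO_TIGHT_CLOSING),
                Gesture(glottal),
            }
        )
    if p.sound_class == NASAL:
        return frozenset(
            {
                Gesture(FULL_CLOSING, p.place, "closure"),
                Gesture(VELO_OPENING),
                Gesture(GLOTTAL_CLOSING),
            }
        )
    if p.sound_class == LATERAL:
        return frozenset(
            {
                Gesture(LATERAL_CONSTRICTION, p.place, "lateral"),
                Gesture(VELO_CLOSING),
                Gesture(GLOTTAL_CLOSING),
            }
        )
    if p.sound_class == GLOTTAL_STOP:
        return frozenset({Gesture(GLOTTAL_TIGHT_CLOSING), Gesture(VELO_CLOSING)})
    raise ExpansionError(f"no gesture bundle for class {p.sound_class!r}")


def gesture_features(g: Gesture) -> frozenset[str]:
    """Generic feature (dimension) values determined by one gesture."""
    if g.gtype == TRACT_SHAPING:
        return frozenset({"high-low", "front-back"})
    if g.gtype == LABIAL_SHAPING:
        return frozenset({"rounded-unrounded"})
    if g.gtype == FULL_CLOSING:
        return frozenset({"full_closure", g.articulator})
    if g.gtype == NEAR_CLOSING:
        return frozenset({"near_closure", g.articulator})
    if g.gtype == LATERAL_CONSTRICTION:
        return frozenset({"lateral", g.articulator})
    if g.gtype == VELO_OPENING:
        return frozenset({"nasal"})
    if g.gtype == VELO_CLOSING:
        return frozenset({"oral"})
    if g.gtype == VELO_TIGHT_CLOSING:
        return frozenset({"oral", "obstruent"})
    if g.gtype == GLOTTAL_CLOSING:
        return frozenset({"voiced"})
    if g.gtype == GLOTTAL_OPENING:
        return frozenset({"voiceless"})
    if g.gtype == GLOTTAL_TIGHT_CLOSING:
        return frozenset({"glottal_stop"})
    raise ExpansionError(f"no features for {g.gtype!r}")


_PLACE_FEAT = {"labial": "lab", "apical": "api", "dorsal": "dors", "glottal": "glott"}


def segment_features_from_gestures(
    gestures: frozenset[Gesture], role: str, vowel: Phoneme | None = None
) -> frozenset[str]:
    """Segment-feature layer values carried by one phoneme's gesture bundle.

    ``role`` positions the segment within the syllable ("C" for a CV onset,
    "C1"/"C2" within a cluster, "V" for the nucleus) and selects the feature
    vocabulary of that position, mirroring the four-layer structure
    description.  The union over a syllable's segments reproduces the
    segment-features layer of :func:`speechdev.phonology.profile`.
    """
    feats: set[str] = set()
    for g in gestures:
        if role == "V":
            if g.gtype == TRACT_SHAPING and vowel is not None:
                if vowel.vowel_height == "high":
                    feats.add("V_high")
                if vowel.vowel_height == "low":
                    feats.add("V_low")
                if vowel.vowel_backness == "front":
                    feats.add("V_front")
                if vowel.vowel_backness == "back":
                    feats.add("V_back")
        elif role == "C":
            if g.gtype == FULL_CLOSING:
                feats |= {"C_full", f"C_{_PLACE_FEAT[g.articulator]}"}
            elif g.gtype == LATERAL_CONSTRICTION:
                feats |= {"C_lat", f"C_{_PLACE_FEAT[g.articulator]}"}
            elif g.gtype == VELO_OPENING:
                feats.add("C_nas")
            elif g.gtype in (VELO_CLOSING, VELO_TIGHT_CLOSING):
                feats.add("C_nonas")
            elif g.gtype == GLOTTAL_CLOSING:
                feats.add("C_voice")
            elif g.gtype == GLOTTAL_OPENING:
                feats.add("C_vless")
            elif g.gtype == GLOTTAL_TIGHT_CLOSING:
                feats |= {"C_full", "C_glott"}
        elif role == "C1":
            if g.gtype in (FULL_CLOSING, NEAR_CLOSING, LATERAL_CONSTRICTION):
                feats.add(f"C1_{_PLACE_FEAT[g.articulator]}")
            elif g.gtype == GLOTTAL_CLOSING:
                feats.add("C1_voice")
            elif g.gtype == GLOTTAL_OPENING:
                feats.add("C1_vless")
        elif role == "C2":
            if g.gtype == LATERAL_CONSTRICTION:
                feats.add("C2_lat")
            elif g.gtype == VELO_OPENING:
                feats.add("C2_nas")
            elif g.gtype in (VELO_CLOSING, VELO_TIGHT_CLOSING):
                feats.add("CC_nonas")
        else:
            raise ValueError(f"unknown segment role {role!r}")
    return frozenset(feats)


# ---------------------------------------------------------------------------
# Raw gesture scores (motor plans)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimedGesture:
    """A gesture with the phoneme positions (span) it covers on its tier."""

    gesture: Gesture
    span: tuple[int, int]  # inclusive (first, last) phoneme position


@dataclass(frozen=True)
class RawGestureScore:
    """Motor plan: discrete gestures on the four tiers with segment spans."""

    tiers: dict[str, tuple[TimedGesture, ...]]
    n_positions: int
    sampa: str = ""

    def __post_init__(self) -> None:
        if set(self.tiers) != set(TIERS):
            raise ValueError(f"score must carry exactly the tiers {TIERS}")

    def skeleton(self) -> tuple[int, ...]:
        """Tier-wise gesture counts; adaptation requires identical skeletons."""
        return tuple(len(self.tiers[t]) for t in TIERS)

    def all_gestures(self) -> list[tuple[str, TimedGesture]]:
        return [(t, tg) for t in TIERS for tg in self.tiers[t]]


def _tier_sequence(phonemes: Sequence[Phoneme]) -> dict[str, list[TimedGesture]]:
    tiers: dict[str, list[TimedGesture]] = {t: [] for t in TIERS}
    for pos, p in enumerate(phonemes):
        bundle = sorted(expand_phoneme(p), key=lambda g: g.label)
        # stable within-position order: tract shaping before labial shaping
        bundle.sort(key=lambda g: (g.tier, g.gtype != TRACT_SHAPING))
        for g in bundle:
            tiers[g.tier].append(TimedGesture(g, (pos, pos)))
    return tiers


def _assimilate(tiers: dict[str, list[TimedGesture]]) -> dict[str, tuple[TimedGesture, ...]]:
    """Merge adjacent identical gestures (same type, articulator and target).

    Tight-closing and plain closing velopharyngeal gestures are distinct
    types and therefore never assimilate.
    """
    merged: dict[str, tuple[TimedGesture, ...]] = {}
    for tier, items in tiers.items():
        out: list[TimedGesture] = []
        for tg in items:
            if (
                out
                and out[-1].gesture == tg.gesture
                and tg.span[0] - out[-1].span[1] == 1
            ):
                out[-1] = TimedGesture(tg.gesture, (out[-1].span[0], tg.span[1]))
            else:
                out.append(tg)
        merged[tier] = tuple(out)
    return merged


def build_raw_score(s: Syllable | Sequence[Phoneme]) -> RawGestureScore:
    """Place per-phoneme gesture bundles on their tiers and assimilate."""
    phonemes = s.phonemes if isinstance(s, Syllable) else tuple(s)
    tiers = _assimilate(_tier_sequence(phonemes))
    sampa = "".join(p.symbol for p in phonemes)
    return RawGestureScore(tiers, n_positions=len(phonemes), sampa=sampa)


def unmerge(score: RawGestureScore) -> dict[str, tuple[TimedGesture, ...]]:
    """Split assimilated spans back into per-position gestures."""
    out: dict[str, tuple[TimedGesture, ...]] = {}
    for tier in TIERS:
        items: list[TimedGesture] = []
        for tg in score.tiers[tier]:
            for pos in range(tg.span[0], tg.span[1] + 1):
                items.append(TimedGesture(tg.gesture, (pos, pos)))
        out[tier] = tuple(items)
    return out


# ---------------------------------------------------------------------------
# Fully specified gesture scores (motor programs)
# ---------------------------------------------------------------------------

#: Quantitative articulatory targets (dimensionless channel values in [0, 1]).
DEFAULT_TARGETS: dict[tuple[str, str | None], float] = {
    (FULL_CLOSING, "closure"): 0.0,
    (NEAR_CLOSING, None): 0.15,
    (LATERAL_CONSTRICTION, "lateral"): 0.25,
    (VELO_CLOSING, None): 0.1,
    (VELO_TIGHT_CLOSING, None): 0.0,
    (VELO_OPENING, None): 0.9,
    (GLOTTAL_CLOSING, None): 0.2,
    (GLOTTAL_OPENING, None): 0.9,
    (GLOTTAL_TIGHT_CLOSING, None): 0.0,
    (LABIAL_SHAPING, "rounded"): 0.25,
    (LABIAL_SHAPING, "unrounded"): 0.65,
    (TRACT_SHAPING, "a"): 0.9,
    (TRACT_SHAPING, "e"): 0.6,
    (TRACT_SHAPING, "i"): 0.3,
    (TRACT_SHAPING, "o"): 0.55,
    (TRACT_SHAPING, "u"): 0.35,
}


def quantitative_target(g: Gesture) -> float:
    key = (g.gtype, g.target)
    if key in DEFAULT_TARGETS:
        return DEFAULT_TARGETS[key]
    key = (g.gtype, None)
    if key in DEFAULT_TARGETS:
        return DEFAULT_TARGETS[key]
    raise SpecificationError(f"no quantitative target for {g.label}")


@dataclass(frozen=True)
class TimingPolicy:
    """Deterministic timing of gesture scores on a 640 ms frame grid.

    All numbers are policy parameters (ms).  The layout is qualitative-order
    correct: onset-consonant closure target phase precedes the vowel target
    phase, a cluster's second consonant is inserted between first-consonant
    release and the vowel target, a coda sits late in the score, and the
    vocalic tract-shaping gesture is active over most of the score.
    """

    duration_ms: float = 640.0
    frame_ms: float = 10.0
    c1_target: tuple[float, float] = (80.0, 180.0)
    c2_target: tuple[float, float] = (200.0, 280.0)
    coda_target: tuple[float, float] = (440.0, 560.0)
    vowel_lag_ms: float = 40.0  # vowel target starts this long after C release
    vowel_target_end: float = 560.0
    attack_ms: float = 60.0  # movement phase before the target phase
    release_ms: float = 60.0  # release phase after the target phase
    stiffness: float = 100.0  # critically damped stiffness omega (1/s)
    vowel_onset_at_init: bool = True

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_ms / self.frame_ms))


@dataclass(frozen=True)
class FullGesture:
    """One quantitatively specified gesture of a motor program."""

    gesture: Gesture
    tier: str
    span: tuple[int, int]
    activation_onset: float
    target_start: float
    target_end: float
    activation_offset: float
    target_value: float
    target_value2: float = 0.0
    velocity: float = 100.0

    def __post_init__(self) -> None:
        if not (
            self.activation_onset
            <= self.target_start
            <= self.target_end
            <= self.activation_offset
        ):
            raise SpecificationError(
                f"inverted time points for {self.gesture.label}: "
                f"{self.activation_onset}, {self.target_start}, "
                f"{self.target_end}, {self.activation_offset}"
            )


@dataclass(frozen=True)
class FullGestureScore:
    """Motor program: all activation/target time points and targets specified."""

    gestures: tuple[FullGesture, ...]
    n_positions: int
    duration_ms: float = 640.0
    frame_ms: float = 10.0
    init_ms: float = 0.0
    sampa: str = ""

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_ms / self.frame_ms))

    def skeleton(self) -> tuple[int, ...]:
        counts = {t: 0 for t in TIERS}
        for fg in self.gestures:
            counts[fg.tier] += 1
        return tuple(counts[t] for t in TIERS)

    def raw(self) -> RawGestureScore:
        """Discard quantitative specification, recovering the motor plan."""
        tiers: dict[str, list[TimedGesture]] = {t: [] for t in TIERS}
        for fg in self.gestures:
            tiers[fg.tier].append(TimedGesture(fg.gesture, fg.span))
        return RawGestureScore(
            {t: tuple(v) for t, v in tiers.items()},
            n_positions=self.n_positions,
            sampa=self.sampa,
        )


def _segment_phases(
    raw: RawGestureScore, policy: TimingPolicy
) -> list[tuple[float, float]]:
    """Per phoneme position: (target_start, target_end) of its host phase."""
    # classify positions: onset consonants, nucleus, coda consonants
    n = raw.n_positions
    nucleus = None
    for tier in ("tract",):
        for tg in raw.tiers[tier]:
            if tg.gesture.gtype == TRACT_SHAPING:
                nucleus = tg.span[0]
    if nucleus is None:  # no vowel: treat last position as nucleus-like
        nucleus = n - 1
    phases: list[tuple[float, float]] = []
    n_onset = nucleus
    last_onset_end = 0.0
    for pos in range(n):
        if pos < nucleus:  # onset consonant
            phase = policy.c1_target if pos == 0 else policy.c2_target
            last_onset_end = max(last_onset_end, phase[1])
            phases.append(phase)
        elif pos == nucleus:
            start = (
                last_onset_end + policy.release_ms + policy.vowel_lag_ms
                if n_onset
                else policy.vowel_lag_ms
            )
            phases.append((start, policy.vowel_target_end))
        else:  # coda consonant
            phases.append(policy.coda_target)
    return phases


def specify_full(
    raw: RawGestureScore, policy: TimingPolicy = TimingPolicy()
) -> FullGestureScore:
    """Assign all four time points, targets and velocity under a timing policy.

    Each gesture's target phase is the union of its host segments' phases
    (assimilated gestures span several segments); the movement phase starts
    ``attack_ms`` before the target phase and the release phase ends
    ``release_ms`` after it, clipped to the score.
    """
    phases = _segment_phases(raw, policy)
    out: list[FullGesture] = []
    for tier in TIERS:
        for tg in raw.tiers[tier]:
            t_start = phases[tg.span[0]][0]
            t_end = phases[tg.span[1]][1]
            if tg.gesture.gtype in (TRACT_SHAPING, LABIAL_SHAPING) and (
                policy.vowel_onset_at_init
            ):
                onset = 0.0
            else:
                onset = max(t_start - policy.attack_ms, 0.0)
            offset = min(t_end + policy.release_ms, policy.duration_ms)
            out.append(
                FullGesture(
                    gesture=tg.gesture,
                    tier=tier,
                    span=tg.span,
                    activation_onset=onset,
                    target_start=t_start,
                    target_end=t_end,
                    activation_offset=offset,
                    target_value=quantitative_target(tg.gesture),
                    velocity=policy.stiffness,
                )
            )
    return FullGestureScore(
        tuple(out),
        n_positions=raw.n_positions,
        duration_ms=policy.duration_ms,
        frame_ms=policy.frame_ms,
        sampa=raw.sampa,
    )


# ---------------------------------------------------------------------------
# Adaptation (programming route)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubstitutionSummary:
    count: int
    vowel_substitutions: int
    consonantal_substitutions: int

    @property
    def stratum(self) -> str:
        if self.count == 0:
            return "identical"
        if self.consonantal_substitutions == 0:
            return "vowel_only"
        return f"consonantal_{self.consonantal_substitutions}"


def _aligned_positions(
    a: RawGestureScore, b: RawGestureScore
) -> tuple[dict[str, dict[int, Gesture]], dict[str, dict[int, Gesture]]]:
    """Per-tier position->gesture views; scores must cover the same
    positions on every tier (assimilation may group them differently, e.g.
    a voicing change splits a merged phonation gesture)."""
    if a.n_positions != b.n_positions:
        raise AdaptationError(
            f"incompatible syllable skeletons: {a.n_positions} vs "
            f"{b.n_positions} segment positions"
        )
    views = []
    for score in (a, b):
        split = unmerge(score)
        view: dict[str, dict[tuple[int, int], Gesture]] = {}
        for tier in TIERS:
            slots: dict[tuple[int, int], Gesture] = {}
            for tg in split[tier]:
                # two vocalic sub-gestures share a position on the tract
                # tier: tract shaping takes slot 0, labial shaping slot 1
                slot = 1 if tg.gesture.gtype == LABIAL_SHAPING else 0
                slots[(tg.span[0], slot)] = tg.gesture
            view[tier] = slots
        views.append(view)
    for tier in TIERS:
        if set(views[0][tier]) != set(views[1][tier]):
            raise AdaptationError(
                f"incompatible gesture skeletons on the {tier} tier"
            )
    return views[0], views[1]


def _mismatches(
    a: RawGestureScore, b: RawGestureScore
) -> list[tuple[str, int, Gesture, Gesture]]:
    va, vb = _aligned_positions(a, b)
    out = []
    for tier in TIERS:
        for pos in sorted(va[tier]):
            if va[tier][pos] != vb[tier][pos]:
                out.append((tier, pos, va[tier][pos], vb[tier][pos]))
    return out


def substitution_count(a: RawGestureScore, b: RawGestureScore) -> SubstitutionSummary:
    """Gesture-target mismatches between two compatible motor plans.

    Mismatches on the tract tier (vocalic tract-shaping and labial-shaping
    targets) form the vowel stratum and count as one substitution of the
    vocalic gesture complex; all other mismatches affect consonants and are
    counted per gesture.
    """
    mism = _mismatches(a, b)
    consonantal = sum(1 for tier, *_ in mism if tier != "tract")
    vowel = 1 if len(mism) > consonantal else 0
    return SubstitutionSummary(
        count=vowel + consonantal,
        vowel_substitutions=vowel,
        consonantal_substitutions=consonantal,
    )


def adapt_score(
    donor: FullGestureScore, target_plan: RawGestureScore
) -> FullGestureScore:
    """Copy the donor's time points verbatim; substitute differing gestures.

    The output has the donor's exact temporal specification (bitwise) with
    gesture identities and targets replaced wherever the target motor plan
    differs from the donor's plan.
    """
    donor_raw = donor.raw()
    _aligned_positions(donor_raw, target_plan)  # raises on incompatibility
    # donor gesture covering each (tier, position, slot), with time points
    covering: dict[tuple[str, int, int], FullGesture] = {}
    for fg in donor.gestures:
        slot = 1 if fg.gesture.gtype == LABIAL_SHAPING else 0
        for pos in range(fg.span[0], fg.span[1] + 1):
            covering[(fg.tier, pos, slot)] = fg
    out: list[FullGesture] = []
    for tier in TIERS:
        for tg in target_plan.tiers[tier]:
            slot = 1 if tg.gesture.gtype == LABIAL_SHAPING else 0
            fg = covering[(tier, tg.span[0], slot)]
            if fg.gesture == tg.gesture and fg.span == tg.span:
                out.append(fg)
            else:
                out.append(
                    replace(
                        fg,
                        gesture=tg.gesture,
                        span=tg.span,
                        target_value=quantitative_target(tg.gesture),
                    )
                )
    return FullGestureScore(
        tuple(out),
        n_positions=target_plan.n_positions,
        duration_ms=donor.duration_ms,
        frame_ms=donor.frame_ms,
        init_ms=donor.init_ms,
        sampa=target_plan.sampa,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def full_score_to_json(score: FullGestureScore) -> str:
    doc = {
        "sampa": score.sampa,
        "duration_ms": score.duration_ms,
        "frame_ms": score.frame_ms,
        "init_ms": score.init_ms,
        "n_positions": score.n_positions,
        "gestures": [
            {
                "tier": fg.tier,
                "type": fg.gesture.gtype,
                "articulator": fg.gesture.articulator,
                "target": fg.gesture.target,
                "span": list(fg.span),
                "activation_onset": fg.activation_onset,
                "target_start": fg.target_start,
                "target_end": fg.target_end,
                "activation_offset": fg.activation_offset,
                "target_value": fg.target_value,
                "target_value2": fg.target_value2,
                "velocity": fg.velocity,
            }
            for fg in score.gestures
        ],
    }
    return json.dumps(doc, indent=2)


def score_to_textgrid(score: FullGestureScore) -> str:
    """Praat TextGrid (long format): one interval tier per gesture tier.

    Interval labels are ``type:target`` over each gesture's activation
    interval; times in seconds.
    """
    xmax = score.duration_ms / 1000.0
    # the two vocalic sub-gestures overlap in time, so they get their own
    # interval tiers (Praat interval tiers must not overlap)
    tg_tiers: list[tuple[str, list[FullGesture]]] = [
        ("tract_shape", [f for f in score.gestures if f.gesture.gtype == TRACT_SHAPING]),
        ("tract_lips", [f for f in score.gestures if f.gesture.gtype == LABIAL_SHAPING]),
        ("constr", [f for f in score.gestures if f.tier == "constr"]),
        ("velo", [f for f in score.gestures if f.tier == "velo"]),
        ("glottal", [f for f in score.gestures if f.tier == "glottal"]),
    ]
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {xmax:g}",
        "tiers? <exists>",
        f"size = {len(tg_tiers)}",
        "item []:",
    ]
    for t_i, (tier, tier_gestures) in enumerate(tg_tiers, start=1):
        gest = sorted(tier_gestures, key=lambda fg: fg.activation_onset)
        # fill gaps with empty intervals
        intervals: list[tuple[float, float, str]] = []
        cursor = 0.0
        for fg in gest:
            # clamp overlapping activation intervals (coarticulatory overlap)
            a = max(fg.activation_onset / 1000.0, cursor)
            b = fg.activation_offset / 1000.0
            if a > cursor:
                intervals.append((cursor, a, ""))
            label = fg.gesture.gtype + (
                f":{fg.gesture.target}" if fg.gesture.target else ""
            )
            intervals.append((a, max(b, a), label))
            cursor = max(b, cursor)
        if cursor < xmax:
            intervals.append((cursor, xmax, ""))
        lines += [
            f"    item [{t_i}]:",
            '        class = "IntervalTier"',
            f'        name = "{tier}"',
            "        xmin = 0",
            f"        xmax = {xmax:g}",
            f"        intervals: size = {len(intervals)}",
        ]
        for i, (a, b, label) in enumerate(intervals, start=1):
            lines += [
                f"        intervals [{i}]:",
                f"            xmin = {a:g}",
                f"            xmax = {b:g}",
                f'            text = "{label}"',
            ]
    return "\n".join(lines) + "\n"
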