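"""Phoneme inventories, syllable vocabularies and layered phonological structure.

A syllable is described on four layers of phonological structure:

(i)   *syllable type* -- CV, CCV (or V);
(ii)  *gesture-score type* -- a coarse syllable subtype determined by the
      class and voicing of the onset (BV, PV, NV, LV for CV syllables and
      BLV, PLV, BNV, PNV for CCV syllables);
(iii) *segment types* -- which segments occur at which position, with the
      rest of the syllable schematised (e.g. /dV/, /Cu/, /pCV/, /CCa/);
(iv)  *segment features* -- distinctive features of the individual segments
      (e.g. C_full, C_api, C_voice, V_high, C1_lab, C2_lat).

A *knowledge level* selects which of these layers are available to the
similarity computation used during motor planning; five named levels are
supported (``all`` down to ``minus_scores_and_segments``).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import yaml

__all__ = [
    "Phoneme",
    "Syllable",
    "PhonProfile",
    "KnowledgeLevel",
    "KNOWLEDGE_LEVELS",
    "InventoryError",
    "PlanningError",
    "UnsupportedStructureError",
    "Inventory",
    "EXP1_INVENTORY",
    "EXP2_INVENTORY",
    "build_vocabulary",
    "profile",
    "restrict",
    "syllabify",
    "make_lexicon",
    "vocabulary_to_tsv",
    "inventory_to_yaml",
    "inventory_from_yaml",
]


class InventoryError(ValueError):
    """A phoneme symbol or cluster refers to nothing in the inventory."""


class PlanningError(ValueError):
    """A phoneme sequence cannot be chunked into known syllable structures."""


class UnsupportedStructureError(ValueError):
    """A syllable structure outside the supported {V, CV, CCV} set."""


# ---------------------------------------------------------------------------
# Phonemes
# ---------------------------------------------------------------------------

VOWEL = "vowel"
PLOSIVE = "plosive"
NASAL = "nasal"
LATERAL = "lateral"
GLOTTAL_STOP = "glottal_stop"

CONSONANT_CLASSES = {PLOSIVE, NASAL, LATERAL, GLOTTAL_STOP}


@dataclass(frozen=True)
class Phoneme:
    """A phoneme in SAMPA notation with its class attributes.

    Vowels carry height/backness only; consonants carry voicing/place only.
    The glottal stop is classed place=glottal with no plain voicing value --
    it acts as its own glottal-feature category.
    """

    symbol: str
    sound_class: str
    voicing: str | None = None  # "voiced" | "voiceless" (consonants)
    place: str | None = None  # "labial" | "apical" | "dorsal" | "glottal"
    vowel_height: str | None = None  # "high" | "low"
    vowel_backness: str | None = None  # "front" | "back"

    def __post_init__(self) -> None:
        if self.sound_class == VOWEL:
            if self.voicing is not None or self.place is not None:
                raise ValueError(f"vowel {self.symbol!r} must not carry voicing/place")
        elif self.sound_class in CONSONANT_CLASSES:
            if self.vowel_height is not None or self.vowel_backness is not None:
                raise ValueError(
                    f"consonant {self.symbol!r} must not carry height/backness"
                )
        else:
            raise ValueError(f"unknown sound class {self.sound_class!r}")

    @property
    def is_vowel(self) -> bool:
        return self.sound_class == VOWEL


def _v(symbol: str, height: str | None, backness: str | None) -> Phoneme:
    return Phoneme(symbol, VOWEL, vowel_height=height, vowel_backness=backness)


def _c(symbol: str, sound_class: str, voicing: str | None, place: str) -> Phoneme:
    return Phoneme(symbol, sound_class, voicing=voicing, place=place)


@dataclass(frozen=True)
class Inventory:
    """A phoneme inventory plus the licensed CC onset clusters.

    Ordering of ``consonants`` and ``vowels`` is meaningful: vocabulary
    enumeration is deterministic in (consonant order, vowel order).
    """

    consonants: tuple[Phoneme, ...]
    vowels: tuple[Phoneme, ...]
    clusters: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        symbols = [p.symbol for p in self.consonants + self.vowels]
        if len(symbols) != len(set(symbols)):
            raise InventoryError("duplicate phoneme symbols in inventory")
        cmap = {p.symbol for p in self.consonants}
        for c1, c2 in self.clusters:
            if c1 not in cmap or c2 not in cmap:
                raise InventoryError(f"cluster /{c1}{c2}/ uses unknown consonant")

    def lookup(self, symbol: str) -> Phoneme:
        for p in self.consonants + self.vowels:
            if p.symbol == symbol:
                return p
        raise InventoryError(f"unknown phoneme symbol {symbol!r}")


#: 45-syllable model language: 9 consonants x 3 vowels + 6 clusters.
EXP2_INVENTORY = Inventory(
    consonants=(
        _c("b", PLOSIVE, "voiced", "labial"),
        _c("d", PLOSIVE, "voiced", "apical"),
        _c("g", PLOSIVE, "voiced", "dorsal"),
        _c("p", PLOSIVE, "voiceless", "labial"),
        _c("t", PLOSIVE, "voiceless", "apical"),
        _c("k", PLOSIVE, "voiceless", "dorsal"),
        _c("m", NASAL, "voiced", "labial"),
        _c("n", NASAL, "voiced", "apical"),
        _c("l", LATERAL, "voiced", "apical"),
    ),
    vowels=(_v("i", "high", "front"), _v("a", "low", None), _v("u", "high", "back")),
    clusters=(("b", "l"), ("g", "l"), ("p", "l"), ("k", "l"), ("g", "n"), ("k", "n")),
)

#: 70-syllable babbling/imitation language: 10 consonants x 5 vowels + 4 clusters.
EXP1_INVENTORY = Inventory(
    consonants=(
        _c("b", PLOSIVE, "voiced", "labial"),
        _c("d", PLOSIVE, "voiced", "apical"),
        _c("g", PLOSIVE, "voiced", "dorsal"),
        _c("p", PLOSIVE, "voiceless", "labial"),
        _c("t", PLOSIVE, "voiceless", "apical"),
        _c("k", PLOSIVE, "voiceless", "dorsal"),
        _c("?", GLOTTAL_STOP, None, "glottal"),
        _c("m", NASAL, "voiced", "labial"),
        _c("n", NASAL, "voiced", "apical"),
        _c("l", LATERAL, "voiced", "apical"),
    ),
    vowels=(
        _v("i", "high", "front"),
        _v("e", None, "front"),
        _v("a", "low", None),
        _v("o", None, "back"),
        _v("u", "high", "back"),
    ),
    clusters=(("b", "l"), ("g", "l"), ("p", "l"), ("k", "l")),
)


# ---------------------------------------------------------------------------
# Syllables and vocabularies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Syllable:
    """An ordered phoneme sequence forming one syllable.

    Vocabularies contain only V/CV/CCV syllables; coda-bearing structures
    (CVC, CCVC) are supported for gesture-score construction.
    """

    phonemes: tuple[Phoneme, ...]

    def __post_init__(self) -> None:
        if self.structure not in ("V", "CV", "CCV", "CVC", "CCVC"):
            raise UnsupportedStructureError(
                f"unsupported phoneme pattern {self.pattern!r}"
            )

    @property
    def pattern(self) -> str:
        return "".join("V" if p.is_vowel else "C" for p in self.phonemes)

    @property
    def structure(self) -> str:
        return self.pattern

    @property
    def nucleus(self) -> Phoneme:
        for p in self.phonemes:
            if p.is_vowel:
                return p
        raise UnsupportedStructureError(f"{self.pattern!r} has no nucleus")

    @property
    def onset(self) -> tuple[Phoneme, ...]:
        out = []
        for p in self.phonemes:
            if p.is_vowel:
                break
            out.append(p)
        return tuple(out)

    @property
    def sampa(self) -> str:
        return "".join(p.symbol for p in self.phonemes)

    def __str__(self) -> str:  # /du/
        return f"/{self.sampa}/"


def build_vocabulary(
    consonants: Sequence[Phoneme],
    vowels: Sequence[Phoneme],
    clusters: Sequence[tuple[str, str]] = (),
) -> list[Syllable]:
    """All CxV CV-syllables followed by all clusterxV CCV-syllables.

    Enumeration order is consonant-major then vowel, matching the printed
    inventory order, so trial enumeration downstream is reproducible.
    """
    if not consonants or not vowels:
        raise InventoryError("consonant and vowel inventories must be non-empty")
    cmap = {p.symbol: p for p in consonants}
    vocab = [Syllable((c, v)) for c in consonants for v in vowels]
    for c1, c2 in clusters:
        if c1 not in cmap or c2 not in cmap:
            raise InventoryError(f"cluster /{c1}{c2}/ uses unknown consonant")
    vocab += [
        Syllable((cmap[c1], cmap[c2], v)) for (c1, c2) in clusters for v in vowels
    ]
    return vocab


def vocabulary(inventory: Inventory) -> list[Syllable]:
    return build_vocabulary(inventory.consonants, inventory.vowels, inventory.clusters)


# ---------------------------------------------------------------------------
# Four-layer profiles
# ---------------------------------------------------------------------------

_SCORE_ONSET_CLASS = {PLOSIVE: "BP", NASAL: "N", LATERAL: "L", GLOTTAL_STOP: "Q"}


def _onset_letter(c: Phoneme) -> str:
    """Score-type letter for a single onset consonant (B/P/N/L/Q)."""
    if c.sound_class == PLOSIVE:
        return "B" if c.voicing == "voiced" else "P"
    if c.sound_class == NASAL:
        return "N"
    if c.sound_class == LATERAL:
        return "L"
    if c.sound_class == GLOTTAL_STOP:
        return "Q"
    raise UnsupportedStructureError(f"no score letter for {c.symbol!r}")


@dataclass(frozen=True)
class PhonProfile:
    """Four-layer phonological structure description of one syllable."""

    syllable_type: str | None
    score_type: str | None
    segment_types: frozenset[str]
    segment_features: frozenset[str]

    def atoms(self) -> dict[str, frozenset[str]]:
        """Layer name -> set of symbolic values present."""
        return {
            "syllable": frozenset([self.syllable_type] if self.syllable_type else []),
            "score": frozenset([self.score_type] if self.score_type else []),
            "segments": self.segment_types,
            "features": self.segment_features,
        }


def _vowel_features(v: Phoneme, prefix: str = "V") -> set[str]:
    feats: set[str] = set()
    if v.vowel_height == "high":
        feats.add(f"{prefix}_high")
    if v.vowel_height == "low":
        feats.add(f"{prefix}_low")
    if v.vowel_backness == "front":
        feats.add(f"{prefix}_front")
    if v.vowel_backness == "back":
        feats.add(f"{prefix}_back")
    return feats


_PLACE_ABBREV = {"labial": "lab", "apical": "api", "dorsal": "dors", "glottal": "glott"}


def profile(syllable: Syllable) -> PhonProfile:
    """Populate all four structure layers for a CV or CCV syllable.

    Layer values follow the fixed value lists of the 45-/70-item model
    languages; e.g. /du/ yields score BV, segments {/dV/, /Cu/} and features
    {C_full, C_api, C_nonas, C_voice, V_high, V_back}.
    """
    structure = syllable.structure
    v = syllable.nucleus
    if structure == "CV":
        c = syllable.phonemes[0]
        letter = _onset_letter(c)
        score = f"{letter}V"
        segments = {f"{c.symbol}V", f"C{v.symbol}"}
        features: set[str] = set()
        if c.sound_class in (PLOSIVE, NASAL, GLOTTAL_STOP):
            features.add("C_full")
        if c.sound_class == LATERAL:
            features.add("C_lat")
        features.add(f"C_{_PLACE_ABBREV[c.place]}")
        features.add("C_nas" if c.sound_class == NASAL else "C_nonas")
        if c.voicing == "voiced":
            features.add("C_voice")
        elif c.voicing == "voiceless":
            features.add("C_vless")
        features |= _vowel_features(v)
        return PhonProfile("CV", score, frozenset(segments), frozenset(features))
    if structure == "CCV":
        c1, c2 = syllable.phonemes[0], syllable.phonemes[1]
        score = f"{_onset_letter(c1)}{_onset_letter(c2)}V"
        segments = {f"CC{v.symbol}", f"{c1.symbol}CV", f"C{c2.symbol}V"}
        features = {f"C1_{_PLACE_ABBREV[c1.place]}"}
        if c2.sound_class == LATERAL:
            features.add("C2_lat")
        if c2.sound_class == NASAL:
            features.add("C2_nas")
        else:
            features.add("CC_nonas")
        if c1.voicing == "voiced":
            features.add("C1_voice")
        elif c1.voicing == "voiceless":
            features.add("C1_vless")
        features |= _vowel_features(v)
        return PhonProfile("CCV", score, frozenset(segments), frozenset(features))
    raise UnsupportedStructureError(f"cannot profile structure {structure!r}")


# ---------------------------------------------------------------------------
# Knowledge levels
# ---------------------------------------------------------------------------

_ALL_LAYERS = frozenset({"syllable", "score", "segments", "features"})


@dataclass(frozen=True)
class KnowledgeLevel:
    """Which structure layers are available during similarity computation."""

    name: str
    layers_present: frozenset[str]

    def __post_init__(self) -> None:
        if not self.layers_present <= _ALL_LAYERS:
            raise ValueError(f"unknown layers {set(self.layers_present) - _ALL_LAYERS}")
        if "syllable" not in self.layers_present:
            raise ValueError("the syllable-type layer is always present")


def _level(name: str, *missing: str) -> KnowledgeLevel:
    return KnowledgeLevel(name, _ALL_LAYERS - frozenset(missing))


#: The five named levels of phonological knowledge.
KNOWLEDGE_LEVELS: dict[str, KnowledgeLevel] = {
    "all": _level("all"),
    "minus_scores": _level("minus_scores", "score"),
    "minus_segments": _level("minus_segments", "segments"),
    "minus_features": _level("minus_features", "features"),
    "minus_scores_and_segments": _level(
        "minus_scores_and_segments", "score", "segments"
    ),
}


def restrict(p: PhonProfile, level: KnowledgeLevel) -> PhonProfile:
    """Empty the layers absent at ``level``; present layers are unchanged.

    Idempotent and monotone: restricting never adds values.
    """
    present = level.layers_present
    return PhonProfile(
        syllable_type=p.syllable_type if "syllable" in present else None,
        score_type=p.score_type if "score" in present else None,
        segment_types=p.segment_types if "segments" in present else frozenset(),
        segment_features=p.segment_features if "features" in present else frozenset(),
    )


# ---------------------------------------------------------------------------
# Syllabification (motor planning: chunking the phoneme stream)
# ---------------------------------------------------------------------------


def syllabify(
    phoneme_sequence: Sequence[Phoneme],
    known_structures: Iterable[str] = ("V", "CV", "CCV"),
) -> list[Syllable]:
    """Greedy longest-match chunking of a phoneme sequence into syllables.

    Raises :class:`PlanningError` when a residue cannot be parsed into any
    known structure.
    """
    if not phoneme_sequence:
        raise PlanningError("empty phoneme sequence")
    known = sorted(set(known_structures), key=len, reverse=True)
    seq = list(phoneme_sequence)
    out: list[Syllable] = []
    i = 0
    while i < len(seq):
        for pattern in known:
            chunk = seq[i : i + len(pattern)]
            if len(chunk) == len(pattern) and (
                "".join("V" if p.is_vowel else "C" for p in chunk) == pattern
            ):
                out.append(Syllable(tuple(chunk)))
                i += len(pattern)
                break
        else:
            raise PlanningError(
                f"cannot chunk residue starting at position {i} "
                f"({''.join(p.symbol for p in seq[i:])!r}) into {known}"
            )
    return out


# ---------------------------------------------------------------------------
# Lexicon (synthetic word meanings) and serialization
# ---------------------------------------------------------------------------


def make_lexicon(vocab: Sequence[Syllable], seed: int = 0) -> dict[str, Syllable]:
    """Bind synthetic meanings word_00..word_NN 1:1 to syllables.

    The word<->syllable mapping is arbitrary; a seeded shuffle decides which
    label goes with which syllable so that different virtual speakers can
    carry different (but reproducible) lexica.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(vocab))
    width = max(2, len(str(len(vocab) - 1)))
    return {f"word_{order[i]:0{width}d}": s for i, s in enumerate(vocab)}


def vocabulary_to_tsv(vocab: Sequence[Syllable], lexicon: dict[str, Syllable]) -> str:
    """TSV export: word_id, syllable, structure, score_type."""
    by_syll = {s.sampa: w for w, s in lexicon.items()}
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(["word_id", "syllable", "structure", "score_type"])
    for s in vocab:
        writer.writerow([by_syll.get(s.sampa, ""), s.sampa, s.structure,
                         profile(s).score_type])
    return buf.getvalue()


def inventory_to_yaml(inv: Inventory) -> str:
    doc = {
        "consonants": [
            {"symbol": p.symbol, "class": p.sound_class, "voicing": p.voicing,
             "place": p.place}
            for p in inv.consonants
        ],
        "vowels": [
            {"symbol": p.symbol, "height": p.vowel_height,
             "backness": p.vowel_backness}
            for p in inv.vowels
        ],
        "clusters": ["".join(c) for c in inv.clusters],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def inventory_from_yaml(text: str) -> Inventory:
    doc = yaml.safe_load(text)
    consonants = tuple(
        _c(d["symbol"], d["class"], d.get("voicing"), d["place"])
        for d in doc["consonants"]
    )
    vowels = tuple(
        _v(d["symbol"], d.get("height"), d.get("backness")) for d in doc["vowels"]
    )
    clusters = tuple((c[0], c[1:]) for c in doc.get("clusters", []))
    return Inventory(consonants, vowels, clusters)
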