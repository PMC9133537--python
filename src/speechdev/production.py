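"""Dual-route adult production: buffers, control, similarity, adaptation.

The production pipeline mirrors a perception-production buffer architecture:
a word is perceived (A_perc -> P_perc -> L_perc -> C_perc), forwarded through
the cognitive input/output buffers without further processing, and sent down
the production pathway (C_prod -> L_prod -> P_prod -> M_plan).  A control
module then compares utility values: if a motor program for the planned
syllable exists (activity in M_prog), DIRECT_CALL_MOTOR executes it via the
syllable score events (M_score -> M_gest); otherwise ADAPT_MOTOR retrieves
the motor plan of a phonologically similar syllable (P_plan_sim), copies its
program's temporal specification and substitutes the differing gesture
targets (M_score_targ).

Phonological similarity is computed in a vector-symbolic layer: every layer
value of the four-layer structure description is a seeded random unit vector
(an atom); a syllable is encoded as the normalized weighted bundle (sum) of
its atoms; similarity is the cosine between bundles.  The *knowledge level*
restricts which layers enter the target's encoding, while stored syllabary
entries keep their full structure description.  Retrieval noise -- a random
perturbation of the query bundle whose magnitude grows with the square root
of the number of stored motor programs, emulating interference in an
associative memory -- makes repeated trials stochastic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import gestures as ge
from . import phonology as ph

__all__ = [
    "ProductionConfig",
    "SymbolVocab",
    "BufferState",
    "ControlAction",
    "CONTROL_ACTIONS",
    "Syllabary",
    "ProductionTrace",
    "encode_profile",
    "rank_similar",
    "control_step",
    "produce",
    "trace_to_json",
]


@dataclass(frozen=True)
class ProductionConfig:
    """Similarity-layer parameters.

    ``dimension``, the retrieval threshold (``theta_base`` plus a
    capacity term growing with the log of the number of stored programs,
    keeping the false-activation rate roughly constant as the syllabary
    grows), ``noise_base`` (retrieval interference, scaled by
    sqrt(#programs)) and the layer bundling weights were calibrated once
    against the knowledge-level production percentages and are frozen
    defaults.
    """

    dimension: int = 16384
    theta_base: float = 0.47
    theta_capacity: float = 0.048
    noise_base: float = 0.0153
    attempt_budget: int = 2
    max_consonantal_substitutions: int = 2
    layer_weights: dict[str, float] = field(
        default_factory=lambda: {
            "syllable": 1.0,
            "score": 1.0,
            "segments": 1.0,
            "features": 1.0,
        }
    )


DEFAULT_CONFIG = ProductionConfig()


def _atom_seed(seed: int, symbol: str) -> int:
    digest = hashlib.sha256(f"{seed}:{symbol}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


class SymbolVocab:
    """Seeded random unit vectors for atomic symbols, plus bundling weights.

    Atom vectors depend only on (seed, symbol), not on creation order, so a
    vocabulary is reproducible regardless of which syllables were encoded
    first.
    """

    def __init__(self, seed: int, config: ProductionConfig = DEFAULT_CONFIG):
        self.seed = int(seed)
        self.config = config
        self._atoms: dict[str, np.ndarray] = {}

    def atom(self, symbol: str) -> np.ndarray:
        vec = self._atoms.get(symbol)
        if vec is None:
            rng = np.random.default_rng(_atom_seed(self.seed, symbol))
            vec = rng.standard_normal(self.config.dimension)
            vec /= np.linalg.norm(vec)
            self._atoms[symbol] = vec
        return vec

    def bundle(self, weighted_symbols: Sequence[tuple[str, float]]) -> np.ndarray:
        if not weighted_symbols:
            raise ValueError("cannot bundle an empty symbol set")
        vec = np.zeros(self.config.dimension)
        for symbol, w in weighted_symbols:
            vec += w * self.atom(symbol)
        norm = np.linalg.norm(vec)
        if norm == 0:
            raise ValueError("bundle cancelled to zero")
        return vec / norm


def encode_profile(
    p: ph.PhonProfile,
    vocab: SymbolVocab,
    level: ph.KnowledgeLevel = ph.KNOWLEDGE_LEVELS["all"],
) -> np.ndarray:
    """Normalized weighted bundle of the layer-value atoms present at ``level``.

    Atoms are namespaced per layer so that identically spelled values in
    different layers stay distinct.  An empty restriction still encodes the
    syllable-type atom (that layer is always present).
    """
    restricted = ph.restrict(p, level)
    weights = vocab.config.layer_weights
    symbols: list[tuple[str, float]] = []
    for layer, values in restricted.atoms().items():
        for value in sorted(values):
            symbols.append((f"{layer}:{value}", weights.get(layer, 1.0)))
    if not symbols and p.syllable_type:
        symbols = [(f"syllable:{p.syllable_type}", weights.get("syllable", 1.0))]
    return vocab.bundle(symbols)


# ---------------------------------------------------------------------------
# Syllabary
# ---------------------------------------------------------------------------


@dataclass
class SyllabaryEntry:
    syllable: ph.Syllable
    plan: ge.RawGestureScore
    program: ge.FullGestureScore | None  # None: not yet learned
    encoding: np.ndarray  # full-knowledge structure encoding

    @property
    def has_program(self) -> bool:
        return self.program is not None


class Syllabary:
    """Mental syllabary: motor plans for all syllables, programs for learned ones."""

    def __init__(
        self,
        vocabulary: Sequence[ph.Syllable],
        learned: set[str],
        vocab: SymbolVocab,
        timing: ge.TimingPolicy = ge.TimingPolicy(),
    ):
        self.vocab = vocab
        self.timing = timing
        self.entries: dict[str, SyllabaryEntry] = {}
        for s in vocabulary:
            plan = ge.build_raw_score(s)
            program = ge.specify_full(plan, timing) if s.sampa in learned else None
            self.entries[s.sampa] = SyllabaryEntry(
                syllable=s,
                plan=plan,
                program=program,
                encoding=encode_profile(ph.profile(s), vocab),
            )

    @property
    def n_programs(self) -> int:
        return sum(e.has_program for e in self.entries.values())

    @property
    def theta(self) -> float:
        """Effective retrieval threshold at the current syllabary size."""
        cfg = self.vocab.config
        return cfg.theta_base + cfg.theta_capacity * np.log(max(self.n_programs, 1))

    def learned(self) -> list[SyllabaryEntry]:
        return [e for e in self.entries.values() if e.has_program]


@dataclass(frozen=True)
class RankedCandidate:
    sampa: str
    similarity: float


def rank_similar(
    target: np.ndarray,
    syllabary: Syllabary,
    rng: np.random.Generator | None = None,
) -> list[RankedCandidate]:
    """Stored-program candidates ranked by (noisy) cosine to the target encoding.

    The query bundle is perturbed by a Gaussian vector whose per-candidate
    similarity jitter is ``noise_base * sqrt(n_programs)`` -- interference
    grows with the number of stored programs competing in retrieval.  With
    ``rng=None`` the ranking is noiseless.
    """
    cfg = syllabary.vocab.config
    query = target
    if rng is not None and cfg.noise_base > 0:
        # additive interference on the retrieval activation: one shared
        # perturbation vector per trial, so similar candidates receive
        # correlated jitter of per-candidate std noise_base*sqrt(n_programs)
        sigma_sim = cfg.noise_base * np.sqrt(max(syllabary.n_programs, 1))
        query = target + rng.standard_normal(cfg.dimension) * sigma_sim
    out = [
        RankedCandidate(e.syllable.sampa, float(query @ e.encoding))
        for e in syllabary.learned()
    ]
    out.sort(key=lambda c: (-c.similarity, c.sampa))
    return out


# ---------------------------------------------------------------------------
# Control module
# ---------------------------------------------------------------------------

CONTROL_ACTIONS = (
    "LISTEN",
    "DIRECT_CALL_MOTOR",
    "ADAPT_MOTOR",
    "NEXT_SYLLABLE",
    "HALT",
)

ControlAction = str

_BUFFER_NAMES = (
    "A_perc", "V_perc", "P_perc", "L_perc", "C_perc",
    "C_cog_in", "C_cog_out",
    "C_prod", "L_prod", "P_prod",
    "M_plan", "P_plan_sim", "M_prog", "M_score", "M_score_targ", "M_gest",
    "in_con", "out_con", "utility_val",
)


@dataclass
class BufferState:
    """Named neural buffers; each holds a labeled content or is empty."""

    contents: dict[str, object] = field(
        default_factory=lambda: {name: None for name in _BUFFER_NAMES}
    )

    def __getitem__(self, name: str) -> object:
        if name not in self.contents:
            raise KeyError(f"unknown buffer {name!r}")
        return self.contents[name]

    def __setitem__(self, name: str, value: object) -> None:
        if name not in self.contents:
            raise KeyError(f"unknown buffer {name!r}")
        self.contents[name] = value

    def active(self, name: str) -> bool:
        return self.contents[name] is not None


def control_step(b: BufferState) -> ControlAction:
    """Select the control action by comparing buffer-occupancy utilities.

    Ties break deterministically by the fixed action order (LISTEN,
    DIRECT_CALL_MOTOR, ADAPT_MOTOR, NEXT_SYLLABLE, HALT).
    """
    utilities = {
        "LISTEN": 1.0 if b.active("A_perc") and not b.active("C_cog_in") else 0.0,
        "DIRECT_CALL_MOTOR": 1.0
        if b.active("M_plan") and b.active("M_prog")
        else 0.0,
        "ADAPT_MOTOR": 0.9 if b.active("M_plan") and not b.active("M_prog") else 0.0,
        "NEXT_SYLLABLE": 1.0
        if b.active("M_gest") and b["M_gest"] == "score_end"
        else 0.0,
        "HALT": 0.1,
    }
    b["utility_val"] = utilities
    return max(CONTROL_ACTIONS, key=lambda a: utilities[a])


# ---------------------------------------------------------------------------
# Single-word production
# ---------------------------------------------------------------------------


@dataclass
class ProductionTrace:
    """Record of one production trial."""

    word: str
    target: str
    level: str
    actions: list[str] = field(default_factory=list)
    route: str = "failed"  # direct | adapting | failed
    attempts: int = 0
    donor: str | None = None
    donor_similarity: float | None = None
    substitutions: int = 0
    stratum: str | None = None
    first_attempt_success: bool = False
    emitted_gestures: list[str] = field(default_factory=list)
    buffer_timeline: list[dict[str, str]] = field(default_factory=list)
    success: bool = False


class LexiconError(KeyError):
    pass


def _emit(trace: ProductionTrace, program: ge.FullGestureScore) -> None:
    events = sorted(program.gestures, key=lambda fg: (fg.activation_onset, fg.tier))
    trace.emitted_gestures = [fg.gesture.label for fg in events] + ["score_end"]


def _snapshot(b: BufferState) -> dict[str, str]:
    return {
        name: (str(v) if v is not None else "")
        for name, v in b.contents.items()
        if name != "utility_val"
    }


def produce(
    word: str,
    lexicon: dict[str, ph.Syllable],
    syllabary: Syllabary,
    level: ph.KnowledgeLevel = ph.KNOWLEDGE_LEVELS["all"],
    seed: int | None = None,
) -> ProductionTrace:
    """Run the full buffer pipeline for one word and return its trace.

    The direct route fires iff a motor program for the target syllable is
    stored.  Otherwise the adapting route searches the ranked similar
    syllables: a candidate is admissible when its similarity exceeds theta,
    its gesture-count skeleton matches and its adaptation needs at most the
    configured number of consonantal substitutions; the trial fails when no
    admissible candidate appears within the attempt budget.
    """
    if word not in lexicon:
        raise LexiconError(f"unknown word {word!r}")
    syllable = lexicon[word]
    entry = syllabary.entries[syllable.sampa]
    cfg = syllabary.vocab.config
    rng = np.random.default_rng(seed) if seed is not None else None

    trace = ProductionTrace(word=word, target=syllable.sampa, level=level.name)
    b = BufferState()
    b["A_perc"] = word

    # perception pathway and cognitive pass-through (forwarding only)
    action = control_step(b)
    trace.actions.append(action)
    assert action == "LISTEN"
    for buf in ("P_perc", "L_perc", "C_perc", "C_cog_in", "C_cog_out",
                "C_prod", "L_prod", "P_prod"):
        b[buf] = syllable.sampa if buf.startswith("P") else word
        trace.buffer_timeline.append(_snapshot(b))
    b["M_plan"] = syllable.sampa
    b["M_prog"] = syllable.sampa if entry.has_program else None

    action = control_step(b)
    trace.actions.append(action)

    if action == "DIRECT_CALL_MOTOR":
        trace.route = "direct"
        trace.attempts = 1
        trace.first_attempt_success = True
        trace.success = True
        b["M_score"] = syllable.sampa
        _emit(trace, entry.program)
        b["M_gest"] = "score_end"
        trace.actions.append(control_step(b))  # NEXT_SYLLABLE
        trace.buffer_timeline.append(_snapshot(b))
        return trace

    assert action == "ADAPT_MOTOR"
    target_vec = encode_profile(ph.profile(syllable), syllabary.vocab, level)
    ranked = rank_similar(target_vec, syllabary, rng=rng)
    b["M_score_targ"] = syllable.sampa
    for attempt, cand in enumerate(ranked[: cfg.attempt_budget], start=1):
        trace.attempts = attempt
        if cand.similarity < syllabary.theta:
            continue  # not activated: below the retrieval threshold
        donor_entry = syllabary.entries[cand.sampa]
        try:
            summary = ge.substitution_count(donor_entry.plan, entry.plan)
        except ge.AdaptationError:
            continue  # incompatible skeleton: would need assembling
        if summary.consonantal_substitutions > cfg.max_consonantal_substitutions:
            continue
        adapted = ge.adapt_score(donor_entry.program, entry.plan)
        check = ge.substitution_count(adapted.raw(), entry.plan)
        if check.count != 0:
            continue
        trace.route = "adapting"
        trace.donor = cand.sampa
        trace.donor_similarity = cand.similarity
        trace.substitutions = summary.count
        trace.stratum = summary.stratum
        trace.first_attempt_success = attempt == 1
        trace.success = True
        b["P_plan_sim"] = cand.sampa
        b["M_score"] = cand.sampa
        _emit(trace, adapted)
        b["M_gest"] = "score_end"
        trace.actions.append(control_step(b))
        trace.buffer_timeline.append(_snapshot(b))
        return trace

    trace.route = "failed"
    trace.success = False
    trace.actions.append("HALT")
    trace.buffer_timeline.append(_snapshot(b))
    return trace


def trace_to_json(trace: ProductionTrace) -> str:
    return json.dumps(dict(trace.__dict__), indent=2)


def timeline_to_tsv(trace: ProductionTrace) -> str:
    """Buffer-activity timeline (rows = control steps, columns = buffers)."""
    if not trace.buffer_timeline:
        return ""
    cols = list(trace.buffer_timeline[0])
    lines = ["\t".join(["step"] + cols)]
    for i, row in enumerate(trace.buffer_timeline):
        lines.append("\t".join([str(i)] + [row.get(c, "") for c in cols]))
    return "\n".join(lines) + "\n"
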