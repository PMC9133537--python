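"""Reproduction harnesses: babbling/imitation learners and knowledge-level grids.

Experiment 1 trains ten virtual learners (independently seeded G-SOM model
instances): each babbles the 70-item proto-syllable corpus, then imitates
210 items (70 syllables x 3 noisy renditions, 50 cycles x 1470 steps) while
a semantic map and word<->syllable links develop.  Reported per learner:
babbling auditory-to-motor association error, number of words with a
unique correct syllable association, word production error rate; across
learners: the feature-region count table with medians.

Experiment 2 runs the dual-route production model over a knowledge-level x
learning-stage grid: 2a at the CV stage (CV syllables with /a/ pre-learned;
5 levels x 3 trials x 27 CV syllables = 405 trials) and 2b at the CCV stage
(all CV plus CCV with /a/ pre-learned; 5 levels x 3 trials x 18 CCV
syllables = 270 trials).  Learned-syllable trials must complete via the
direct route; unlearned ones exercise the adapting route, and per-level
success percentages are split by adaptation stratum (vowel-only vs up to
two consonantal substitutions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gestures as ge
from . import gsom as gs
from . import phonology as ph
from . import production as pr
from . import topology as tp
from . import vocaltract_proxy as vp

__all__ = [
    "ExperimentConfig",
    "Exp1Results",
    "Exp2Results",
    "LEVEL_ORDER",
    "make_babbling_items",
    "make_imitation_items",
    "run_learner",
    "run_exp1",
    "run_exp2",
    "exp2_results_to_tsv",
    "plot_exp2",
    "plot_map",
]

LEVEL_ORDER = (
    "all",
    "minus_scores",
    "minus_segments",
    "minus_features",
    "minus_scores_and_segments",
)


def _trial_seed(master_seed: int, counter: int) -> int:
    """Deterministic per-trial seed derived from the master seed."""
    return (int(master_seed) * 1_000_003 + counter) % (2**31 - 1)


@dataclass(frozen=True)
class ExperimentConfig:
    experiment: str = "exp1"  # exp1 | exp2a | exp2b
    seed: int = 1
    # exp1
    n_learners: int = 10
    babbling_cycles: int = 10
    imitation_cycles: int = 50
    renditions: int = 3
    rendition_noise: float = 0.02
    gsom: gs.GsomConfig = field(default_factory=gs.GsomConfig)
    # exp2
    trials_per_syllable: int = 3
    levels: tuple[str, ...] = LEVEL_ORDER
    production: pr.ProductionConfig = field(default_factory=pr.ProductionConfig)

    @property
    def stage(self) -> str:
        return {"exp2a": "CV_stage", "exp2b": "CCV_stage"}.get(self.experiment, "")


# ---------------------------------------------------------------------------
# Experiment 1
# ---------------------------------------------------------------------------


def make_babbling_items(
    vocab: list[ph.Syllable] | None = None,
    proxy: vp.ProxyConfig = vp.DEFAULT_PROXY,
) -> list[gs.StateMaps]:
    """Noiseless proto-syllable patterns for the babbling corpus."""
    vocab = vocab if vocab is not None else ph.vocabulary(ph.EXP1_INVENTORY)
    items = []
    for s in vocab:
        score = ge.specify_full(ge.build_raw_score(s))
        pats = vp.syllable_patterns(score, proxy)
        items.append(
            gs.StateMaps(
                auditory=pats["auditory"],
                somatosensory=pats["somatosensory"],
                motor_program=pats["motor_program"],
                motor_plan=pats["motor_plan"],
                label=s.sampa,
            )
        )
    return items


def make_imitation_items(
    lexicon: dict[str, ph.Syllable],
    semantic: dict[str, np.ndarray],
    renditions: int = 3,
    noise_sigma: float = 0.02,
    seed: int = 0,
    proxy: vp.ProxyConfig = vp.DEFAULT_PROXY,
) -> list[gs.StateMaps]:
    """Noisy renditions of every word's syllable, paired with its meaning.

    Each syllable is rendered ``renditions`` times with independent seeded
    sensory noise, emulating the variability of repeated model imitations.
    """
    rng = np.random.default_rng(seed)
    items = []
    for word in sorted(lexicon):
        s = lexicon[word]
        score = ge.specify_full(ge.build_raw_score(s))
        for _ in range(renditions):
            pats = vp.syllable_patterns(score, proxy, rng=rng, noise_sigma=noise_sigma)
            items.append(
                gs.StateMaps(
                    auditory=pats["auditory"],
                    somatosensory=pats["somatosensory"],
                    motor_program=pats["motor_program"],
                    motor_plan=pats["motor_plan"],
                    semantic=semantic[word],
                    label=f"{word}={s.sampa}",
                )
            )
    return items


@dataclass
class LearnerResult:
    seed: int
    babbling_error: float
    learned_words: int
    word_error_rate: float
    n_nodes: int
    imitation: gs.ImitationResult
    labeling: tp.FeatureLabeling


def run_learner(
    seed: int, cfg: ExperimentConfig = ExperimentConfig()
) -> LearnerResult:
    """Train one virtual learner through babbling and imitation."""
    vocab = ph.vocabulary(ph.EXP1_INVENTORY)
    babble_items = make_babbling_items(vocab)
    g = gs.train_babbling(
        None, babble_items, cycles=cfg.babbling_cycles, config=cfg.gsom, seed=seed
    )
    babbling_error = gs.babbling_error_rate(g, babble_items)

    lexicon = ph.make_lexicon(vocab, seed=seed)
    semantic = gs.semantic_vectors(sorted(lexicon), seed=seed + 7)
    imit_items = make_imitation_items(
        lexicon,
        semantic,
        renditions=cfg.renditions,
        noise_sigma=cfg.rendition_noise,
        seed=seed + 13,
    )
    result = gs.train_imitation(
        g,
        imit_items,
        cycles=cfg.imitation_cycles,
        renditions=cfg.renditions,
        config=cfg.gsom,
        seed=seed,
    )
    report = gs.word_learning_report(result, semantic)
    return LearnerResult(
        seed=seed,
        babbling_error=babbling_error,
        learned_words=int(report["learned_words"]),
        word_error_rate=float(report["word_error_rate"]),
        n_nodes=g.n_nodes,
        imitation=result,
        labeling=tp.label_map(g),
    )


@dataclass
class Exp1Results:
    learners: pd.DataFrame  # per-learner metrics
    regions: tp.RegionReport

    @property
    def mean_babbling_error(self) -> float:
        return float(self.learners["babbling_error"].mean())

    @property
    def mean_learned_words(self) -> float:
        return float(self.learners["learned_words"].mean())

    @property
    def mean_word_error_rate(self) -> float:
        return float(self.learners["word_error_rate"].mean())


def run_exp1(cfg: ExperimentConfig = ExperimentConfig()) -> Exp1Results:
    """Train ``n_learners`` seeded instances and compile the region table."""
    rows = []
    labelings = []
    for k in range(cfg.n_learners):
        learner = run_learner(_trial_seed(cfg.seed, k), cfg)
        labelings.append(learner.labeling)
        rows.append(
            {
                "learner": f"tr{k + 1:02d}",
                "seed": learner.seed,
                "babbling_error": learner.babbling_error,
                "learned_words": learner.learned_words,
                "word_error_rate": learner.word_error_rate,
                "n_nodes": learner.n_nodes,
            }
        )
    learners = pd.DataFrame(rows).set_index("learner")
    regions = tp.region_count_table(
        labelings, instance_names=list(learners.index)
    )
    return Exp1Results(learners=learners, regions=regions)


# ---------------------------------------------------------------------------
# Experiment 2
# ---------------------------------------------------------------------------


def _stage_sets(experiment: str, vocab: list[ph.Syllable]):
    if experiment == "exp2a":
        learned = {
            s.sampa
            for s in vocab
            if s.structure == "CV" and s.nucleus.symbol == "a"
        }
        targets = [s for s in vocab if s.structure == "CV"]
    elif experiment == "exp2b":
        learned = {
            s.sampa
            for s in vocab
            if s.structure == "CV" or s.nucleus.symbol == "a"
        }
        targets = [s for s in vocab if s.structure == "CCV"]
    else:
        raise ValueError(f"unknown experiment {experiment!r}")
    return learned, targets


@dataclass
class Exp2Results:
    experiment: str
    stage: str
    table: pd.DataFrame  # per level x stratum results
    traces: list[pr.ProductionTrace]
    n_trials: int
    n_learned_trials: int
    n_learned_ok: int  # learned-syllable trials completed via the direct route

    def level_row(self, level: str) -> pd.Series:
        return self.table.loc[level]


def run_exp2(cfg: ExperimentConfig) -> Exp2Results:
    """Run one knowledge-level grid (exp2a or exp2b) and tabulate results."""
    vocab = ph.vocabulary(ph.EXP2_INVENTORY)
    learned, targets = _stage_sets(cfg.experiment, vocab)
    sv = pr.SymbolVocab(cfg.seed, cfg.production)
    syllabary = pr.Syllabary(vocab, learned, sv)
    lexicon = {s.sampa: s for s in vocab}  # word labels = syllable names here

    traces: list[pr.ProductionTrace] = []
    rows = []
    counter = 0
    n_learned_trials = 0
    n_learned_ok = 0
    for level_name in cfg.levels:
        level = ph.KNOWLEDGE_LEVELS[level_name]
        stats = {
            "n_unlearned": 0,
            "success": 0,
            "first": 0,
            "first_vowel_only": 0,
        }
        for s in targets:
            for _ in range(cfg.trials_per_syllable):
                seed = _trial_seed(cfg.seed, counter)
                counter += 1
                trace = pr.produce(s.sampa, lexicon, syllabary, level, seed=seed)
                traces.append(trace)
                if s.sampa in learned:
                    n_learned_trials += 1
                    if trace.route == "direct" and trace.success:
                        n_learned_ok += 1
                else:
                    stats["n_unlearned"] += 1
                    stats["success"] += trace.success
                    stats["first"] += trace.first_attempt_success
                    stats["first_vowel_only"] += (
                        trace.first_attempt_success
                        and trace.stratum in ("vowel_only", "identical")
                    )
        n = max(stats["n_unlearned"], 1)
        rows.append(
            {
                "level": level_name,
                "n_unlearned_trials": stats["n_unlearned"],
                "n_success": stats["success"],
                "n_first_attempt": stats["first"],
                "pct_success": 100.0 * stats["success"] / n,
                "pct_first_attempt": 100.0 * stats["first"] / n,
                "pct_first_vowel_only": 100.0 * stats["first_vowel_only"] / n,
            }
        )
    table = pd.DataFrame(rows).set_index("level")
    return Exp2Results(
        experiment=cfg.experiment,
        stage=cfg.stage,
        table=table,
        traces=traces,
        n_trials=counter,
        n_learned_trials=n_learned_trials,
        n_learned_ok=n_learned_ok,
    )


def exp2_results_to_tsv(results: Exp2Results) -> str:
    df = results.table.reset_index()
    return df.to_csv(sep="\t", index=False)


# ---------------------------------------------------------------------------
# Figure exports
# ---------------------------------------------------------------------------


def plot_exp2(results: Exp2Results, path: str) -> None:
    """Grouped bar chart of per-level percentages (vowel-only vs all successes)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = results.table
    x = np.arange(len(table))
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(x - 0.2, table["pct_first_vowel_only"], width=0.4,
           color="#1f3f8f", label="vowel target only")
    ax.bar(x + 0.2, table["pct_first_attempt"], width=0.4,
           color="#7fa8e0", label="up to 2 consonantal substitutions")
    ax.set_xticks(x, table.index, rotation=20, ha="right")
    ax.set_ylabel("% correct productions (unlearned syllables)")
    ax.set_ylim(0, 105)
    ax.set_title(f"{results.experiment}: {results.stage}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_map(labeling: tp.FeatureLabeling, group: str, path: str) -> None:
    """Map grid colored by the feature values of one group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = tp.FEATURE_GROUPS[group]
    cmap = plt.get_cmap("tab10")
    fig, ax = plt.subplots(figsize=(6, 6))
    for (r, c) in labeling.nodes:
        feats = labeling.features.get((r, c))
        color = "0.9"
        if feats:
            for i, f in enumerate(values):
                if f in feats:
                    color = cmap(i % 10)
                    break
        ax.add_patch(plt.Rectangle((c - 0.45, r - 0.45), 0.9, 0.9, color=color))
    coords = np.array(sorted(labeling.nodes))
    ax.set_xlim(coords[:, 1].min() - 1, coords[:, 1].max() + 1)
    ax.set_ylim(coords[:, 0].min() - 1, coords[:, 0].max() + 1)
    ax.set_aspect("equal")
    ax.set_title(f"feature group: {group}")
    handles = [plt.Rectangle((0, 0), 1, 1, color=cmap(i % 10)) for i in range(len(values))]
    ax.legend(handles, values, loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
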