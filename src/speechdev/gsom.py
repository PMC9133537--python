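"""Growing self-organizing maps for babbling and imitation learning.

The phonetic map is a growing SOM (G-SOM) on an integer grid, starting from
a 2x2 seed.  Each node carries one weight vector per attached state map
(auditory 24x64, somatosensory 4x64, motor program 2x64x10, motor plan).
Training presents state-map patterns of speech items; the best-matching unit
(BMU) is found by Euclidean distance on the flattened *auditory* pattern and
the weights of the BMU neighborhood are moved toward the item's patterns on
*all* attached maps simultaneously, so that sensory and motor states become
associated on the map.  Each node accumulates quantization error; when a
node's error exceeds the growth threshold, free grid positions next to it
are recruited as new nodes (weight-interpolated from their neighbors), so
the map grows to fit the item set.

Babbling training associates auditory and motor states of proto-syllables.
Imitation training continues phonetic-map training on noisy renditions of
language-specific syllables while a second G-SOM organizes the word meanings
(semantic feature vectors); Hebbian co-activation updates build
bidirectional word<->syllable links between the two maps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GsomConfig",
    "Gsom",
    "StateMaps",
    "ImitationResult",
    "STATE_MAP_SHAPES",
    "semantic_vectors",
    "train_babbling",
    "train_imitation",
    "recall_auditory",
    "produce_word",
    "babbling_error_rate",
    "word_learning_report",
]

#: canonical state-map shapes
STATE_MAP_SHAPES = {
    "auditory": (24, 64),
    "somatosensory": (4, 64),
    "motor_program": (2, 64, 10),
    # motor_plan is flat already; its length is set by the plan encoding
}

SEMANTIC_DIM = 470


@dataclass(frozen=True)
class StateMaps:
    """One training item: patterns for every attached state map."""

    auditory: np.ndarray
    somatosensory: np.ndarray
    motor_program: np.ndarray
    motor_plan: np.ndarray
    semantic: np.ndarray | None = None  # binary feature vector (imitation)
    label: str = ""  # "word=syllable" or plain syllable identity

    def __post_init__(self) -> None:
        for name, shape in STATE_MAP_SHAPES.items():
            if getattr(self, name).shape != shape:
                raise ValueError(
                    f"{name} pattern must have shape {shape}, "
                    f"got {getattr(self, name).shape}"
                )
        if self.semantic is not None and self.semantic.shape != (SEMANTIC_DIM,):
            raise ValueError(f"semantic vector must have shape ({SEMANTIC_DIM},)")


def semantic_vectors(
    words: list[str], seed: int, dim: int = SEMANTIC_DIM, active: int = 25
) -> dict[str, np.ndarray]:
    """Synthetic binary semantic feature bundles, ``active`` of ``dim`` bits set.

    The semantic feature inventory content is synthetic (seeded random bit
    patterns); only the dimensionality is meaningful.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for w in sorted(words):
        vec = np.zeros(dim, dtype=np.float32)
        vec[rng.choice(dim, size=active, replace=False)] = 1.0
        out[w] = vec
    return out


@dataclass(frozen=True)
class GsomConfig:
    """G-SOM hyperparameters (growth rule and schedules).

    ``gt`` is the cumulative quantization error (squared driver-pattern
    distance) a node tolerates before recruiting its free grid neighbors;
    its scale follows the driver pattern's squared-distance scale, so the
    semantic map (binary feature vectors) uses its own ``gt_semantic``.
    Learning rate and neighborhood radius decay exponentially over cycles.
    """

    gt: float = 3000.0
    gt_semantic: float = 3000.0
    #: novelty recruitment: a stimulus farther than this (squared driver
    #: distance) from every node recruits a fresh node of its own; sits
    #: between the sensory noise floor and the closest between-item gaps
    gt_novelty: float = 1.7
    gt_novelty_semantic: float = 20.0
    #: novelty recruitment only operates once the neighborhood has shrunk
    #: to this radius (coarse ordering first, fine recruitment second);
    #: while the radius is larger, growth is driven by cumulative error
    recruit_radius: float = 0.6
    #: fresh sensory (driver) noise per babbling presentation -- babbling
    #: explores, so no two productions are identical
    presentation_noise: float = 0.02
    lr_initial: float = 0.35
    lr_final: float = 0.05
    #: imitation tracks the mean of a syllable's fixed renditions, so its
    #: rate starts lower than the babbling phase's
    imitation_lr_initial: float = 0.15
    radius_initial: float = 2.0
    #: imitation continues on an already-organized map, so its neighborhood
    #: restarts narrower than the babbling phase's
    imitation_radius_initial: float = 0.7
    radius_final: float = 0.3
    cutoff_sigmas: float = 3.0
    steps_per_item_per_cycle: int = 7
    link_lr: float = 0.1
    #: links decay once per cycle so stale associations from early map
    #: reorganization fade in favor of the settled topology
    link_cycle_decay: float = 0.9
    capacity: int = 324  # preallocated node slots


_NEIGH4 = ((0, 1), (0, -1), (1, 0), (-1, 0))
_NEIGH8 = ((0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (1, -1), (-1, 1), (-1, -1))


class GsomStateError(RuntimeError):
    """Operation requires a trained map."""


class Gsom:
    """A growing SOM with named attached state maps on an integer grid.

    Internally all attached maps live in one composite weight matrix; the
    BMU is searched on the driver map's columns only.
    """

    def __init__(
        self,
        map_dims: dict[str, int],
        driver: str,
        config: GsomConfig = GsomConfig(),
        seed: int = 0,
    ):
        self.config = config
        self.driver = driver
        self.map_dims = dict(map_dims)
        self.seed = int(seed)
        self.rng = np.random.default_rng(seed)
        # driver columns first so the BMU slice is leading and contiguous
        names = [driver] + [n for n in map_dims if n != driver]
        self.slices: dict[str, slice] = {}
        off = 0
        for n in names:
            self.slices[n] = slice(off, off + map_dims[n])
            off += map_dims[n]
        self.total_dim = off
        cap = config.capacity
        self.W = np.zeros((cap, off), dtype=np.float32)
        self._driver_norm2 = np.zeros(cap, dtype=np.float64)  # cached |w_driver|^2
        self.coords = np.zeros((cap, 2), dtype=np.int64)
        self.err = np.zeros(cap)
        self.n_nodes = 0
        self._index: dict[tuple[int, int], int] = {}
        self._initialized = False
        self.occupancy: dict[int, list[str]] = {}
        self.max_train_dist: float = 0.0
        for r, c in ((0, 0), (0, 1), (1, 0), (1, 1)):
            self._add_node((r, c))

    # -- structure ---------------------------------------------------------

    def weight(self, name: str, node: int) -> np.ndarray:
        return self.W[node, self.slices[name]]

    def _refresh_norms(self, rows) -> None:
        sl = self.slices[self.driver]
        w = self.W[rows, sl]
        self._driver_norm2[rows] = np.einsum("...j,...j->...", w, w)

    def _add_node(
        self, coord: tuple[int, int], init_from: list[int] | None = None
    ) -> None:
        if self.n_nodes >= self.config.capacity:
            return  # capacity exhausted: stop growing
        i = self.n_nodes
        self.coords[i] = coord
        self._index[coord] = i
        if init_from:
            self.W[i] = self.W[init_from].mean(axis=0)
        self._refresh_norms(i)
        self.n_nodes += 1

    def _boundary_free(self, node: int) -> list[tuple[int, int]]:
        r, c = self.coords[node]
        return [
            (r + dr, c + dc)
            for dr, dc in _NEIGH4
            if (r + dr, c + dc) not in self._index
        ]

    def neighbors(self, node: int, eight: bool = True) -> list[int]:
        r, c = self.coords[node]
        deltas = _NEIGH8 if eight else _NEIGH4
        return [
            self._index[(r + dr, c + dc)]
            for dr, dc in deltas
            if (r + dr, c + dc) in self._index
        ]

    # -- training ----------------------------------------------------------

    def compose(self, item: dict[str, np.ndarray]) -> np.ndarray:
        """Concatenate an item's map patterns in this map's column order."""
        vec = np.empty(self.total_dim, dtype=np.float32)
        for name, sl in self.slices.items():
            vec[sl] = np.asarray(item[name], dtype=np.float32).ravel()
        return vec

    def _init_weights(self, composites: np.ndarray) -> None:
        lo = composites.min(axis=0)
        hi = composites.max(axis=0)
        for i in range(self.n_nodes):
            self.W[i] = lo + self.rng.random(self.total_dim).astype(np.float32) * (
                hi - lo
            )
        self._refresh_norms(np.arange(self.n_nodes))
        self._initialized = True

    def bmu(self, pattern: np.ndarray) -> tuple[int, float]:
        x = np.asarray(pattern, dtype=np.float32).ravel()
        dist2 = self._driver_dist2(x)
        i = int(np.argmin(dist2))
        return i, float(dist2[i])

    def _driver_dist2(self, x: np.ndarray) -> np.ndarray:
        sl = self.slices[self.driver]
        w = self.W[: self.n_nodes, sl]
        return np.maximum(
            self._driver_norm2[: self.n_nodes] - 2.0 * (w @ x) + float(x @ x), 0.0
        )

    def _recruit(self, near: int, composite: np.ndarray) -> int | None:
        """Recruit a free grid position near ``near`` for a novel stimulus."""
        if self.n_nodes >= self.config.capacity:
            return None
        # breadth-first outward for the closest node with a free 4-neighbor
        seen = {near}
        frontier = [near]
        while frontier:
            nxt: list[int] = []
            for node in frontier:
                free = self._boundary_free(node)
                if free:
                    self._add_node(free[0])
                    new = self.n_nodes - 1
                    self.W[new] = composite
                    self._refresh_norms(new)
                    return new
                for nb in self.neighbors(node):
                    if nb not in seen:
                        seen.add(nb)
                        nxt.append(nb)
            frontier = nxt
        return None

    def _update(self, composite: np.ndarray, lr: float, radius: float) -> int:
        dist2 = self._driver_dist2(composite[self.slices[self.driver]])
        bmu = int(np.argmin(dist2))
        if (
            self.config.gt_novelty
            and radius <= self.config.recruit_radius
            and dist2[bmu] > self.config.gt_novelty
        ):
            new = self._recruit(bmu, composite)
            if new is not None:
                return new
        coords = self.coords[: self.n_nodes]
        delta = coords - coords[bmu]
        grid_d2 = np.einsum("ij,ij->i", delta, delta)
        cutoff = (self.config.cutoff_sigmas * radius) ** 2
        idx = np.where(grid_d2 <= cutoff)[0]
        h = (lr * np.exp(-grid_d2[idx] / (2.0 * radius * radius))).astype(np.float32)
        self.W[idx] += h[:, None] * (composite[None, :] - self.W[idx])
        self._refresh_norms(idx)
        # growth bookkeeping
        self.err[bmu] += dist2[bmu]
        if self.err[bmu] > self.config.gt:
            free = self._boundary_free(bmu)
            if free:
                for coord in free:
                    self._add_node(coord, init_from=self.neighbors(bmu) + [bmu])
                self.err[bmu] = 0.0
            else:  # interior node: distribute the pressure outward
                nbrs = self.neighbors(bmu)
                self.err[bmu] = self.config.gt / 2.0
                for nb in nbrs:
                    self.err[nb] += self.config.gt / (2.0 * len(nbrs))
        return bmu

    def train(
        self,
        items: list[dict[str, np.ndarray]],
        cycles: int,
        rng: np.random.Generator,
        steps_per_item: int | None = None,
    ) -> None:
        """Cycle-wise stochastic training with decaying rate and radius."""
        if not items:
            raise ValueError("item list must be non-empty")
        composites = np.stack([self.compose(it) for it in items])
        if not self._initialized:
            self._init_weights(composites)
        cfg = self.config
        spi = cfg.steps_per_item_per_cycle if steps_per_item is None else steps_per_item
        for cycle in range(cycles):
            frac = cycle / max(cycles - 1, 1)
            lr = cfg.lr_initial * (cfg.lr_final / cfg.lr_initial) ** frac
            radius = cfg.radius_initial * (cfg.radius_final / cfg.radius_initial) ** frac
            order = np.tile(np.arange(len(items)), spi)
            rng.shuffle(order)
            dsl = self.slices[self.driver]
            for j in order:
                x = composites[j]
                if cfg.presentation_noise > 0:
                    x = x.copy()
                    x[dsl] += rng.normal(
                        0.0, cfg.presentation_noise, dsl.stop - dsl.start
                    ).astype(np.float32)
                self._update(x, lr, radius)

    def label_occupancy(self, items: list[dict[str, np.ndarray]]) -> None:
        """Label each node with the items whose driver pattern it wins."""
        self.occupancy = {}
        self.max_train_dist = 0.0
        for it in items:
            i, d2 = self.bmu(it[self.driver])
            self.occupancy.setdefault(i, [])
            label = str(it.get("label", ""))
            if label not in self.occupancy[i]:
                self.occupancy[i].append(label)
            self.max_train_dist = max(self.max_train_dist, float(np.sqrt(d2)))

    @property
    def free_nodes(self) -> list[int]:
        return [i for i in range(self.n_nodes) if i not in self.occupancy]

    def save(self, path: str) -> None:
        """Serialize weights, occupancy, config and seed to one archive."""
        np.savez_compressed(
            path,
            coords=self.coords[: self.n_nodes],
            err=self.err[: self.n_nodes],
            driver=np.array(self.driver),
            seed=np.array(self.seed),
            occupancy_nodes=np.array(list(self.occupancy), dtype=np.int64),
            occupancy_labels=np.array(["|".join(v) for v in self.occupancy.values()]),
            **{f"W_{k}": self.W[: self.n_nodes, sl] for k, sl in self.slices.items()},
        )


# ---------------------------------------------------------------------------
# Phase drivers
# ---------------------------------------------------------------------------


def _flatten_items(items: list[StateMaps]) -> list[dict[str, np.ndarray]]:
    out = []
    for it in items:
        d = {
            "auditory": it.auditory.ravel().astype(np.float32),
            "somatosensory": it.somatosensory.ravel().astype(np.float32),
            "motor_program": it.motor_program.ravel().astype(np.float32),
            "motor_plan": it.motor_plan.ravel().astype(np.float32),
            "label": it.label,
        }
        if it.semantic is not None:
            d["semantic"] = it.semantic.ravel().astype(np.float32)
        out.append(d)
    return out


_PHONETIC_MAPS = ("auditory", "somatosensory", "motor_program", "motor_plan")


def train_babbling(
    g: Gsom | None,
    items: list[StateMaps],
    cycles: int = 10,
    config: GsomConfig = GsomConfig(),
    seed: int = 0,
) -> Gsom:
    """Babble the proto-item set, associating sensory and motor states.

    Returns the trained phonetic map with occupancy labels set.  Node count
    never decreases (growth-only rule).
    """
    flat = _flatten_items(items)
    if g is None:
        dims = {name: flat[0][name].size for name in _PHONETIC_MAPS}
        g = Gsom(dims, driver="auditory", config=config, seed=seed)
    rng = np.random.default_rng(seed + 1)
    g.train(flat, cycles, rng)
    g.label_occupancy(flat)
    return g


@dataclass
class ImitationResult:
    phonetic: Gsom
    semantic: Gsom
    links: np.ndarray  # (semantic nodes, phonetic nodes) co-activation weights
    word_syllable: dict[str, str]


def train_imitation(
    g: Gsom,
    items: list[StateMaps],
    cycles: int = 50,
    renditions: int = 3,
    config: GsomConfig = GsomConfig(),
    seed: int = 0,
) -> ImitationResult:
    """Joint phonetic/semantic training with Hebbian word<->syllable links.

    ``items`` are syllable renditions (each carrying the semantic vector of
    its word, label "word=syllable"); every item is presented
    ``steps_per_item_per_cycle`` times per cycle (210 items x 7 = 1470
    steps per cycle in the standard protocol).
    """
    if len(items) % renditions != 0:
        raise ValueError(
            f"item count {len(items)} not divisible by {renditions} renditions"
        )
    if any(it.semantic is None for it in items):
        raise ValueError("imitation items need semantic vectors")
    flat = _flatten_items(items)
    sem_config = replace(
        config, gt=config.gt_semantic, gt_novelty=config.gt_novelty_semantic
    )
    sem = Gsom(
        {"semantic": SEMANTIC_DIM}, driver="semantic", config=sem_config,
        seed=seed + 2,
    )
    sem_composites = np.stack([sem.compose(it) for it in flat])
    sem._init_weights(sem_composites)
    phon_composites = np.stack([g.compose(it) for it in flat])
    if not g._initialized:
        g._init_weights(phon_composites)

    cfg = config
    links = np.zeros((cfg.capacity, cfg.capacity), dtype=np.float32)
    rng = np.random.default_rng(seed + 3)
    r0 = cfg.imitation_radius_initial
    lr0 = cfg.imitation_lr_initial
    for cycle in range(cycles):
        frac = cycle / max(cycles - 1, 1)
        lr = lr0 * (cfg.lr_final / lr0) ** frac
        radius = r0 * (cfg.radius_final / r0) ** frac
        links *= cfg.link_cycle_decay
        order = np.tile(np.arange(len(flat)), cfg.steps_per_item_per_cycle)
        rng.shuffle(order)
        for j in order:
            p_bmu = g._update(phon_composites[j], lr, radius)
            s_bmu = sem._update(sem_composites[j], lr, radius)
            links[s_bmu, p_bmu] += cfg.link_lr
    g.label_occupancy(flat)
    sem.label_occupancy(flat)
    word_syllable = {}
    for it in items:
        word, _, syllable = it.label.partition("=")
        word_syllable[word] = syllable or word
    return ImitationResult(
        phonetic=g, semantic=sem, links=links, word_syllable=word_syllable
    )


# ---------------------------------------------------------------------------
# Recall
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Recall:
    node: int
    motor_program: np.ndarray
    somatosensory: np.ndarray
    distance: float
    low_confidence: bool


def recall_auditory(g: Gsom, pattern: np.ndarray) -> Recall:
    """BMU by auditory distance; associated states read from the BMU weights.

    Degenerate inputs still return a node but carry a low-confidence flag
    (distance far above anything seen in training).
    """
    if not g._initialized or not g.occupancy:
        raise GsomStateError("map must be trained (and occupancy-labeled) first")
    node, d2 = g.bmu(pattern)
    dist = float(np.sqrt(d2))
    return Recall(
        node=node,
        motor_program=g.weight("motor_program", node).reshape(
            STATE_MAP_SHAPES["motor_program"]
        ),
        somatosensory=g.weight("somatosensory", node).reshape(
            STATE_MAP_SHAPES["somatosensory"]
        ),
        distance=dist,
        low_confidence=dist > 1.5 * g.max_train_dist,
    )


@dataclass(frozen=True)
class WordProduction:
    word: str
    semantic_node: int
    phonetic_node: int | None
    motor_program: np.ndarray | None
    occupants: tuple[str, ...]
    error: str | None  # None | "shared_node" | "missing_link" | "low_confidence"


def produce_word(
    result: ImitationResult, word: str, semantic_vector: np.ndarray
) -> WordProduction:
    """Semantic BMU -> strongest-linked phonetic node -> motor program.

    A production error (reported, not raised) occurs when the word's
    phonetic node is shared with another word or no link was learned.
    """
    sem = result.semantic
    s_node, d2 = sem.bmu(semantic_vector)
    if not np.any(semantic_vector) or np.sqrt(d2) > 1.5 * max(
        sem.max_train_dist, 1e-9
    ):
        return WordProduction(word, s_node, None, None, (), "low_confidence")
    row = result.links[s_node, : result.phonetic.n_nodes]
    if row.max() <= 0:
        return WordProduction(word, s_node, None, None, (), "missing_link")
    p_node = int(np.argmax(row))
    occupants = tuple(
        sorted(
            {
                lab.partition("=")[2] or lab
                for lab in result.phonetic.occupancy.get(p_node, [])
            }
        )
    )
    target = result.word_syllable.get(word)
    error = None
    if target not in occupants:
        error = "missing_link"
    elif len(occupants) > 1:
        error = "shared_node"
    motor = result.phonetic.weight("motor_program", p_node).reshape(
        STATE_MAP_SHAPES["motor_program"]
    )
    return WordProduction(word, s_node, p_node, motor, occupants, error)


# ---------------------------------------------------------------------------
# Evaluation helpers
# ---------------------------------------------------------------------------


def babbling_error_rate(g: Gsom, items: list[StateMaps]) -> float:
    """Percentage of items whose auditory recall returns another item's motor state."""
    motors = np.stack([it.motor_program.ravel() for it in items]).astype(np.float32)
    errors = 0
    for it in items:
        rec = recall_auditory(g, it.auditory)
        d = motors - rec.motor_program.ravel()[None, :].astype(np.float32)
        nearest = int(np.argmin(np.einsum("ij,ij->i", d, d)))
        mine = it.label.partition("=")[2] or it.label
        found = items[nearest].label.partition("=")[2] or items[nearest].label
        if found != mine:
            errors += 1
    return 100.0 * errors / len(items)


def word_learning_report(
    result: ImitationResult, semantic: dict[str, np.ndarray]
) -> dict[str, object]:
    """Count words with a unique, correct syllable association.

    Two words whose productions converge on one phonetic node count as
    errors (one node then represents two different words).
    """
    productions = {w: produce_word(result, w, vec) for w, vec in semantic.items()}
    node_of = {w: p.phonetic_node for w, p in productions.items()}
    learned = []
    for w, p in productions.items():
        if p.error is not None:
            continue
        if sum(1 for n2 in node_of.values() if n2 == p.phonetic_node) > 1:
            continue
        learned.append(w)
    n = len(semantic)
    return {
        "n_words": n,
        "learned_words": len(learned),
        "word_error_rate": 100.0 * (n - len(learned)) / n,
        "productions": productions,
    }
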