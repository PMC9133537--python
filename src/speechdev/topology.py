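"""Feature-region analysis of trained phonetic maps.

After imitation training, occupied map nodes are labeled with the
phonological features of the syllables they represent (vocalic, glottal,
manner, place and syllable-type feature groups).  A *feature region* is a
set of occupied nodes sharing a feature value, built in three steps:

1. *subregions*: connected components (8-neighborhood) of occupied nodes
   carrying the feature;
2. *merging*: two subregions count as one region when a pathway of free
   (unoccupied) nodes connects them that is (a) near -- fewer than 10 free
   nodes long, (b) coherent -- it crosses at most one region of a competing
   feature value, and (c) neutral -- it contains no occupied nodes; merges
   are closed transitively;
3. *outliers*: single-node subregions are excluded from the count.

Region counts per feature and their medians over trained model instances
quantify how well the map's topology sorts syllables by phonological
features.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import phonology as ph

__all__ = [
    "FEATURE_GROUPS",
    "ALL_FEATURES",
    "exp1_feature_labels",
    "FeatureLabeling",
    "label_map",
    "Region",
    "extract_regions",
    "region_count_table",
    "RegionReport",
    "report_to_tsv",
]

Coord = tuple[int, int]

#: Feature groups of the babbling/imitation analysis (one value set per group).
FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "vocalic": ("front", "back", "low"),
    "glottal": ("voiced", "voiceless", "glottal_stop", "vless_voiced"),
    "manner": ("plosive", "lateral", "nasal", "plosive_lateral"),
    "place": ("labial", "alveolar", "velar", "glottal",
              "labial_alveolar", "velar_alveolar"),
    "syllable_type": ("CV", "CCV"),
}

ALL_FEATURES: tuple[str, ...] = tuple(
    f for values in FEATURE_GROUPS.values() for f in values
)

_GROUP_OF = {f: g for g, values in FEATURE_GROUPS.items() for f in values}


def exp1_feature_labels(syllable: ph.Syllable) -> frozenset[str]:
    """Analysis features of one syllable (vocalic/glottal/manner/place/type)."""
    feats: set[str] = {syllable.structure}
    v = syllable.nucleus
    if v.symbol in ("i", "e"):
        feats.add("front")
    if v.symbol in ("o", "u"):
        feats.add("back")
    if v.symbol == "a":
        feats.add("low")
    onset = syllable.onset
    if syllable.structure == "CV":
        c = onset[0]
        if c.sound_class == ph.GLOTTAL_STOP:
            feats |= {"glottal_stop", "glottal"}
        else:
            feats.add("voiced" if c.voicing == "voiced" else "voiceless")
            feats.add({"labial": "labial", "apical": "alveolar",
                       "dorsal": "velar"}[c.place])
            feats.add({ph.PLOSIVE: "plosive", ph.NASAL: "nasal",
                       ph.LATERAL: "lateral"}[c.sound_class])
    elif syllable.structure == "CCV":
        c1 = onset[0]
        feats.add("plosive_lateral")
        feats.add("voiced" if c1.voicing == "voiced" else "vless_voiced")
        feats.add("labial_alveolar" if c1.place == "labial" else "velar_alveolar")
    return frozenset(feats)


@dataclass(frozen=True)
class FeatureLabeling:
    """Grid labeling of a trained map.

    ``nodes``: every grid position of the map; ``features``: occupied
    position -> feature values of the syllables represented there.
    """

    nodes: frozenset[Coord]
    features: Mapping[Coord, frozenset[str]]

    @property
    def occupied(self) -> frozenset[Coord]:
        return frozenset(self.features)

    def with_feature(self, feature: str) -> frozenset[Coord]:
        return frozenset(c for c, fs in self.features.items() if feature in fs)


class LabelingError(KeyError):
    pass


def label_map(g, inventory: ph.Inventory = ph.EXP1_INVENTORY) -> FeatureLabeling:
    """Feature labeling of a trained G-SOM from its occupancy labels."""
    if not g.occupancy:
        raise LabelingError("map carries no occupancy labels; train it first")
    lookup = {s.sampa: s for s in ph.vocabulary(inventory)}
    nodes = frozenset(tuple(c) for c in g.coords[: g.n_nodes])
    features: dict[Coord, frozenset[str]] = {}
    for node, labels in g.occupancy.items():
        feats: set[str] = set()
        for label in labels:
            sampa = label.partition("=")[2] or label
            if sampa not in lookup:
                raise LabelingError(f"occupant {sampa!r} not in the inventory")
            feats |= exp1_feature_labels(lookup[sampa])
        features[tuple(g.coords[node])] = frozenset(feats)
    return FeatureLabeling(nodes=nodes, features=features)


# ---------------------------------------------------------------------------
# Region extraction
# ---------------------------------------------------------------------------

_NEIGH8 = ((0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (1, -1), (-1, 1), (-1, -1))

#: nearness rule: a connecting pathway may contain at most this many free nodes
MAX_PATH_FREE_NODES = 9  # "length of less than 10 (free) network nodes"
#: coherence rule: at most this many competing regions crossed
MAX_CROSSED_REGIONS = 1


@dataclass(frozen=True)
class Region:
    """One feature region: merged member subregions of occupied nodes."""

    feature: str
    members: frozenset[Coord]
    subregions: tuple[frozenset[Coord], ...]
    merge_paths: tuple[tuple[Coord, ...], ...]


def _adj(c: Coord) -> list[Coord]:
    return [(c[0] + dr, c[1] + dc) for dr, dc in _NEIGH8]


def _components(cells: frozenset[Coord]) -> list[frozenset[Coord]]:
    todo = set(cells)
    comps = []
    while todo:
        seed = todo.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            cur = frontier.pop()
            for nb in _adj(cur):
                if nb in todo:
                    todo.remove(nb)
                    comp.add(nb)
                    frontier.append(nb)
        comps.append(frozenset(comp))
    return comps


def _free_attributions(
    labeling: FeatureLabeling, competing_regions: list[frozenset[Coord]]
) -> dict[Coord, frozenset[int]]:
    """Attribute each free node to the competing regions it lies within.

    A free node counts as part of a competing region's area when at least
    two of its 8-neighbors belong to that region; touching a region with a
    single neighbor is skirting it, not crossing it.
    """
    free = labeling.nodes - labeling.occupied
    att: dict[Coord, frozenset[int]] = {}
    for c in free:
        ids = {
            i
            for i, reg in enumerate(competing_regions)
            if sum(nb in reg for nb in _adj(c)) >= 2
        }
        att[c] = frozenset(ids)
    return att


def _find_path(
    a: frozenset[Coord],
    b: frozenset[Coord],
    labeling: FeatureLabeling,
    attributions: dict[Coord, frozenset[int]],
) -> tuple[Coord, ...] | None:
    """Shortest-first search for a merging pathway from subregion a to b.

    Pathways run over free nodes only (neutrality), contain at most
    MAX_PATH_FREE_NODES free nodes (nearness) and accumulate at most
    MAX_CROSSED_REGIONS distinct competing-region attributions (coherence).
    BFS states are (free node, crossed-region key), so a longer path with a
    different crossing pattern is still found.
    """
    free = labeling.nodes - labeling.occupied
    starts = [c for c in free if any(nb in a for nb in _adj(c))]
    goal = {c for c in free if any(nb in b for nb in _adj(c))}
    # state: (coord, crossed regions frozenset with size <= MAX_CROSSED_REGIONS)
    queue: deque[tuple[Coord, frozenset[int], tuple[Coord, ...]]] = deque()
    seen: set[tuple[Coord, frozenset[int]]] = set()
    for c in sorted(starts):
        crossed = attributions[c]
        if len(crossed) > MAX_CROSSED_REGIONS:
            continue
        state = (c, crossed)
        if state not in seen:
            seen.add(state)
            queue.append((c, crossed, (c,)))
    while queue:
        c, crossed, path = queue.popleft()
        if c in goal:
            return path
        if len(path) >= MAX_PATH_FREE_NODES:
            continue
        for nb in _adj(c):
            if nb not in free:
                continue
            nxt = crossed | attributions[nb]
            if len(nxt) > MAX_CROSSED_REGIONS:
                continue
            state = (nb, nxt)
            if state not in seen:
                seen.add(state)
                queue.append((nb, nxt, path + (nb,)))
    return None


def extract_regions(
    labeling: FeatureLabeling,
    feature: str,
    competing: Iterable[str] | None = None,
) -> list[Region]:
    """Feature regions for one feature value on a labeled map.

    ``competing`` defaults to the other feature values of the same group
    (crossing them violates coherence).  Output regions partition the
    non-outlier occupied nodes carrying the feature.
    """
    if competing is None:
        group = _GROUP_OF.get(feature)
        competing = tuple(f for f in FEATURE_GROUPS.get(group, ()) if f != feature)
    cells = labeling.with_feature(feature)
    if not cells and feature not in ALL_FEATURES:
        known = {f for fs in labeling.features.values() for f in fs}
        if feature not in known:
            raise LabelingError(f"unknown feature {feature!r} labels no node")
    subregions = [c for c in _components(cells) if len(c) > 1]  # drop outliers
    competing_regions = [
        comp for f in competing for comp in _components(labeling.with_feature(f))
    ]
    attributions = _free_attributions(labeling, competing_regions)

    parent = list(range(len(subregions)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    paths: dict[tuple[int, int], tuple[Coord, ...]] = {}
    for i in range(len(subregions)):
        for j in range(i + 1, len(subregions)):
            path = _find_path(subregions[i], subregions[j], labeling, attributions)
            if path is not None:
                paths[(i, j)] = path
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(len(subregions)):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members_idx in groups.values():
        members = frozenset().union(*(subregions[i] for i in members_idx))
        merge_paths = tuple(
            paths[k] for k in paths if k[0] in members_idx and k[1] in members_idx
        )
        out.append(
            Region(
                feature=feature,
                members=members,
                subregions=tuple(subregions[i] for i in sorted(members_idx)),
                merge_paths=merge_paths,
            )
        )
    out.sort(key=lambda r: sorted(r.members)[0] if r.members else (0, 0))
    return out


# ---------------------------------------------------------------------------
# Table-style reports
# ---------------------------------------------------------------------------


@dataclass
class RegionReport:
    """Region counts per feature per model instance, with medians."""

    counts: pd.DataFrame  # index: feature, columns: instance names
    feature_medians: pd.Series
    group_medians: pd.Series

    @property
    def max_median(self) -> float:
        return float(
            max(self.feature_medians.max(), self.group_medians.max())
        )


def region_count_table(
    labelings: Sequence[FeatureLabeling],
    features: Sequence[str] = ALL_FEATURES,
    instance_names: Sequence[str] | None = None,
) -> RegionReport:
    """Region counts for every feature over a set of trained instances.

    Medians are taken per single feature (over instances) and per feature
    group (over all instance x feature cells of the group).
    """
    if not labelings:
        raise ValueError("need at least one instance")
    names = instance_names or [f"tr{i + 1:02d}" for i in range(len(labelings))]
    data = {
        name: [len(extract_regions(lab, f)) for f in features]
        for name, lab in zip(names, labelings)
    }
    counts = pd.DataFrame(data, index=list(features))
    feature_medians = counts.median(axis=1)
    group_values = {
        g: counts.loc[[f for f in values if f in counts.index]].to_numpy().ravel()
        for g, values in FEATURE_GROUPS.items()
    }
    group_medians = pd.Series(
        {g: float(np.median(v)) for g, v in group_values.items() if v.size}
    )
    return RegionReport(counts, feature_medians, group_medians)


def report_to_tsv(report: RegionReport) -> str:
    """TSV export mirroring the region-count table layout."""
    df = report.counts.copy()
    df["median_single_feature"] = report.feature_medians
    df["group"] = [_GROUP_OF.get(f, "") for f in df.index]
    df["median_feature_group"] = [
        report.group_medians.get(_GROUP_OF.get(f, ""), np.nan) for f in df.index
    ]
    return df.to_csv(sep="\t")
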