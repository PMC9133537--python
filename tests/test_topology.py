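"""Feature-region extraction vs an exhaustive path-search oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speechdev import phonology as ph
from speechdev import topology as tp


def make_labeling(nodes, features):
    return tp.FeatureLabeling(
        nodes=frozenset(nodes),
        features={c: frozenset(f) for c, f in features.items()},
    )


def grid(rows, cols):
    return {(r, c) for r in range(rows) for c in range(cols)}


# --- exhaustive oracle -----------------------------------------------------


def oracle_region_count(labeling, feature, competing):
    """Independent re-implementation: enumerate every simple free-node path
    (up to the nearness bound) between subregion pairs and apply the
    coherence/neutrality rules literally; then transitive closure."""
    cells = labeling.with_feature(feature)
    comps = [c for c in tp._components(cells) if len(c) > 1]
    competing_regions = [
        comp for f in competing for comp in tp._components(labeling.with_feature(f))
    ]
    free = labeling.nodes - labeling.occupied

    def attributions(node):
        return {
            i for i, reg in enumerate(competing_regions)
            if sum(nb in reg for nb in tp._adj(node)) >= 2
        }

    def connectable(a, b):
        starts = [c for c in free if any(nb in a for nb in tp._adj(c))]
        goals = {c for c in free if any(nb in b for nb in tp._adj(c))}

        def dfs(node, visited, crossed):
            if len(crossed) > tp.MAX_CROSSED_REGIONS:
                return False
            if node in goals:
                return True
            if len(visited) >= tp.MAX_PATH_FREE_NODES:
                return False
            for nb in tp._adj(node):
                if nb in free and nb not in visited:
                    if dfs(nb, visited | {nb}, crossed | attributions(nb)):
                        return True
            return False

        return any(dfs(s, {s}, attributions(s)) for s in starts)

    parent = list(range(len(comps)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(len(comps)):
        for j in range(i + 1, len(comps)):
            if connectable(comps[i], comps[j]):
                parent[find(i)] = find(j)
    return len({find(i) for i in range(len(comps))})


# --- hand-built cases ------------------------------------------------------


def test_single_cluster_is_one_region():
    lab = make_labeling(grid(4, 4), {(0, 0): {"x"}, (0, 1): {"x"}, (1, 1): {"x"}})
    regions = tp.extract_regions(lab, "x", competing=())
    assert len(regions) == 1
    assert regions[0].members == frozenset({(0, 0), (0, 1), (1, 1)})


def test_bridge_of_free_nodes_merges_two_clusters():
    # two 2-node clusters joined by a 5-free-node corridor
    features = {(0, 0): {"x"}, (1, 0): {"x"}, (0, 7): {"x"}, (1, 7): {"x"}}
    lab = make_labeling(grid(3, 8), features)
    regions = tp.extract_regions(lab, "x", competing=())
    assert len(regions) == 1
    assert len(regions[0].subregions) == 2
    assert regions[0].merge_paths


def test_singleton_subregion_is_outlier():
    features = {(0, 0): {"x"}, (0, 1): {"x"}, (3, 3): {"x"}}
    lab = make_labeling(grid(5, 5), features)
    regions = tp.extract_regions(lab, "x", competing=())
    assert len(regions) == 1
    assert (3, 3) not in regions[0].members


def test_long_gap_blocks_merging():
    # clusters further apart than the nearness bound stay separate
    features = {(0, 0): {"x"}, (1, 0): {"x"}, (0, 13): {"x"}, (1, 13): {"x"}}
    lab = make_labeling(grid(2, 14), features)
    assert len(tp.extract_regions(lab, "x", competing=())) == 2


def test_occupied_nodes_block_the_pathway():
    # a wall of occupied (other-item) nodes violates neutrality
    features = {(1, 0): {"x"}, (1, 1): {"x"}, (1, 6): {"x"}, (1, 7): {"x"}}
    for r in range(3):
        features[(r, 3)] = {"y"}
    lab = make_labeling(grid(3, 8), features)
    regions = tp.extract_regions(lab, "x", competing=())
    assert len(regions) == 2


def test_crossing_two_competing_regions_blocks_merging():
    # corridor forced through the areas of two competing regions
    features = {(1, 0): {"x"}, (2, 0): {"x"}, (1, 9): {"x"}, (2, 9): {"x"}}
    for c in (2, 3):
        features[(0, c)] = {"y"}
        features[(3, c)] = {"y"}
    for c in (6, 7):
        features[(0, c)] = {"z"}
        features[(3, c)] = {"z"}
    lab = make_labeling(grid(4, 10), features)
    assert len(tp.extract_regions(lab, "x", competing=("y",))) == 1
    assert len(tp.extract_regions(lab, "x", competing=("y", "z"))) == 2


def test_unknown_feature_raises():
    lab = make_labeling(grid(2, 2), {(0, 0): {"x"}})
    with pytest.raises(tp.LabelingError):
        tp.extract_regions(lab, "no_such_feature", competing=())


# --- oracle equivalence on random small maps -------------------------------


@given(st.integers(0, 10_000))
@settings(max_examples=40, derandomize=True, deadline=None)
def test_matches_exhaustive_oracle(case_seed):
    rng = np.random.default_rng(case_seed)
    rows, cols = rng.integers(4, 8, size=2)
    nodes = grid(int(rows), int(cols))
    n_occ = int(rng.integers(4, 13))
    occupied = [tuple(map(int, c)) for c in
                rng.permutation(sorted(nodes))[:n_occ]]
    values = ["x", "y", "z"]
    features = {c: {values[int(rng.integers(0, 3))]} for c in occupied}
    lab = make_labeling(nodes, features)
    present = {v for fs in features.values() for v in fs}
    for feature in sorted(present):
        competing = tuple(v for v in values if v != feature)
        got = len(tp.extract_regions(lab, feature, competing))
        expected = oracle_region_count(lab, feature, competing)
        assert got == expected


def test_counts_invariant_under_grid_symmetries():
    rng = np.random.default_rng(99)
    nodes = grid(6, 6)
    occupied = [tuple(map(int, c)) for c in rng.permutation(sorted(nodes))[:12]]
    values = ["x", "y"]
    features = {c: {values[int(rng.integers(0, 2))]} for c in occupied}

    def transform(fn, features, nodes):
        return make_labeling({fn(c) for c in nodes},
                             {fn(c): v for c, v in features.items()})

    base = make_labeling(nodes, features)
    counts = [len(tp.extract_regions(base, v)) for v in ("x",)]
    transforms = [
        lambda c: (c[1], c[0]),
        lambda c: (-c[0], c[1]),
        lambda c: (c[0], -c[1]),
        lambda c: (-c[1], -c[0]),
    ]
    for fn in transforms:
        lab = transform(fn, features, nodes)
        assert [len(tp.extract_regions(lab, v, ("y",))) for v in ("x",)] == [
            len(tp.extract_regions(base, v, ("y",))) for v in ("x",)
        ]


def test_regions_partition_non_outlier_nodes():
    rng = np.random.default_rng(123)
    nodes = grid(7, 7)
    occupied = [tuple(map(int, c)) for c in rng.permutation(sorted(nodes))[:14]]
    features = {c: {"x"} for c in occupied}
    lab = make_labeling(nodes, features)
    regions = tp.extract_regions(lab, "x", competing=())
    member_union = [m for r in regions for m in r.members]
    assert len(member_union) == len(set(member_union))
    non_outlier = {
        c for comp in tp._components(lab.with_feature("x")) if len(comp) > 1
        for c in comp
    }
    assert set(member_union) == non_outlier


# --- table reports ---------------------------------------------------------


def test_exp1_feature_labels():
    vocab = {s.sampa: s for s in ph.vocabulary(ph.EXP1_INVENTORY)}
    assert tp.exp1_feature_labels(vocab["te"]) == frozenset(
        {"CV", "front", "voiceless", "alveolar", "plosive"})
    assert tp.exp1_feature_labels(vocab["gla"]) == frozenset(
        {"CCV", "low", "voiced", "plosive_lateral", "velar_alveolar"})
    assert tp.exp1_feature_labels(vocab["?o"]) == frozenset(
        {"CV", "back", "glottal_stop", "glottal"})


def test_region_table_median_of_identical_instances():
    features = {(0, 0): {"front"}, (0, 1): {"front"}, (3, 3): {"back"},
                (3, 4): {"back"}}
    lab = make_labeling(grid(5, 5), features)
    report = tp.region_count_table([lab] * 4, features=("front", "back"))
    assert (report.counts.loc["front"] == 1).all()
    assert report.feature_medians["front"] == 1.0
    assert report.group_medians["vocalic"] == 1.0
    tsv = tp.report_to_tsv(report)
    assert "median_single_feature" in tsv.splitlines()[0]
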