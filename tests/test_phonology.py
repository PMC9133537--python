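"""Vocabulary construction and the four-layer structure description."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speechdev import phonology as ph

# printed value lists of the four structure layers (45-syllable language)
CV_SCORES = {"BV", "PV", "NV", "LV"}
CCV_SCORES = {"PLV", "BLV", "PNV", "BNV"}
CV_SEGMENTS = {"Ca", "Ci", "Cu"} | {f"{c}V" for c in "bdgptkmnl"}
CCV_SEGMENTS = {"CCa", "CCi", "CCu", "bCV", "gCV", "pCV", "kCV", "ClV", "CnV"}
CV_FEATURES = {
    "V_high", "V_low", "V_front", "V_back",
    "C_full", "C_lat", "C_lab", "C_api", "C_dors",
    "C_nas", "C_nonas", "C_voice", "C_vless",
}
CCV_FEATURES = {
    "V_high", "V_low", "V_front", "V_back",
    "C1_lab", "C1_dors", "C2_lat", "C2_nas", "CC_nonas", "C1_voice", "C1_vless",
}

# golden rows: feature value -> (onsets carrying it, score types or None)
TABLE4_CV = {
    "C_full": (set("bdgptknm"), {"BV", "PV", "NV"}),
    "C_lat": ({"l"}, {"LV"}),
    "C_lab": (set("bpm"), None),
    "C_api": (set("dtnl"), None),
    "C_dors": (set("gk"), None),
    "C_nas": (set("mn"), {"NV"}),
    "C_nonas": (set("bdgptkl"), {"BV", "PV", "LV"}),
    "C_voice": (set("bdgmnl"), {"BV", "NV", "LV"}),
    "C_vless": (set("ptk"), {"PV"}),
}
TABLE4_CCV = {
    "C1_lab": ({"bl", "pl"}, None),
    "C1_dors": ({"gl", "kl", "gn", "kn"}, None),
    "C2_lat": ({"bl", "gl", "pl", "kl"}, {"BLV", "PLV"}),
    "C2_nas": ({"gn", "kn"}, {"BNV", "PNV"}),
    "CC_nonas": ({"bl", "gl", "pl", "kl"}, {"BLV", "PLV"}),
    "C1_voice": ({"bl", "gl", "gn"}, {"BLV", "BNV"}),
    "C1_vless": ({"pl", "kl", "kn"}, {"PLV", "PNV"}),
}


@pytest.mark.parametrize(
    "inventory, total, n_cv, n_ccv",
    [(ph.EXP2_INVENTORY, 45, 27, 18), (ph.EXP1_INVENTORY, 70, 50, 20)],
)
def test_vocabulary_sizes(inventory, total, n_cv, n_ccv):
    vocab = ph.vocabulary(inventory)
    assert len(vocab) == total
    assert sum(s.structure == "CV" for s in vocab) == n_cv
    assert sum(s.structure == "CCV" for s in vocab) == n_ccv
    assert len({s.sampa for s in vocab}) == total


def test_vocabulary_minimal_and_errors():
    b = ph.EXP2_INVENTORY.lookup("b")
    a = ph.EXP2_INVENTORY.lookup("a")
    assert [s.sampa for s in ph.build_vocabulary([b], [a])] == ["ba"]
    with pytest.raises(ph.InventoryError):
        ph.build_vocabulary([b], [a], clusters=[("x", "l")])
    with pytest.raises(ph.InventoryError):
        ph.build_vocabulary([], [a])


def test_vocabulary_order_deterministic(vocab45):
    # consonant-major enumeration in printed inventory order
    assert [s.sampa for s in vocab45[:6]] == ["bi", "ba", "bu", "di", "da", "du"]
    assert vocab45[27].sampa == "bli"


@pytest.mark.parametrize(
    "sampa, syll, score, segments, features",
    [
        ("du", "CV", "BV", {"dV", "Cu"},
         {"C_full", "C_api", "C_nonas", "C_voice", "V_high", "V_back"}),
        ("pla", "CCV", "PLV", {"CCa", "pCV", "ClV"},
         {"C1_lab", "C2_lat", "CC_nonas", "C1_vless", "V_low"}),
        ("ma", "CV", "NV", {"mV", "Ca"},
         {"C_full", "C_lab", "C_nas", "C_voice", "V_low"}),
        ("gnu", "CCV", "BNV", {"CCu", "gCV", "CnV"},
         {"C1_dors", "C2_nas", "C1_voice", "V_high", "V_back"}),
    ],
)
def test_profile_examples(by_sampa, sampa, syll, score, segments, features):
    p = ph.profile(by_sampa[sampa])
    assert p.syllable_type == syll
    assert p.score_type == score
    assert set(p.segment_types) == segments
    assert set(p.segment_features) == features


def test_profile_layer_values_within_printed_lists(vocab45, vocab70):
    """Every layer value of every syllable comes from the printed value lists."""
    for s in vocab45:
        p = ph.profile(s)
        if s.structure == "CV":
            assert p.score_type in CV_SCORES
            assert p.segment_types <= CV_SEGMENTS
            assert p.segment_features <= CV_FEATURES
        else:
            assert p.score_type in CCV_SCORES
            assert p.segment_types <= CCV_SEGMENTS
            assert p.segment_features <= CCV_FEATURES
    # the babbling language adds /?/, /e/, /o/: check structural consistency
    for s in vocab70:
        p = ph.profile(s)
        assert p.syllable_type == s.structure
        assert p.score_type.endswith("V")


def test_profile_matches_golden_table(vocab45):
    """The set of syllables carrying each consonantal feature, and their
    score types, equal the printed rows of the feature/segment/score table."""
    cv = [s for s in vocab45 if s.structure == "CV"]
    ccv = [s for s in vocab45 if s.structure == "CCV"]
    for table, pool in ((TABLE4_CV, cv), (TABLE4_CCV, ccv)):
        for feature, (onsets, scores) in table.items():
            carriers = [s for s in pool if feature in ph.profile(s).segment_features]
            got_onsets = {"".join(p.symbol for p in s.onset) for s in carriers}
            assert got_onsets == onsets, feature
            if scores is not None:
                assert {ph.profile(s).score_type for s in carriers} == scores, feature
    # vowel rows: keyed by the nucleus across both structures
    for v, feats in (("i", {"V_high", "V_front"}), ("a", {"V_low"}),
                     ("u", {"V_high", "V_back"})):
        for s in vocab45:
            p = ph.profile(s)
            if s.nucleus.symbol == v:
                assert feats <= p.segment_features
            else:
                assert not (feats <= p.segment_features)


def test_nasal_segment_implies_nasal_feature(vocab45):
    for s in vocab45:
        p = ph.profile(s)
        if "mV" in p.segment_types or "nV" in p.segment_types:
            assert "C_nas" in p.segment_features


@pytest.mark.parametrize("level", sorted(ph.KNOWLEDGE_LEVELS))
def test_restrict_idempotent_and_monotone(by_sampa, level):
    lv = ph.KNOWLEDGE_LEVELS[level]
    for sampa in ("du", "pla", "ma"):
        p = ph.profile(by_sampa[sampa])
        r = ph.restrict(p, lv)
        assert ph.restrict(r, lv) == r
        for layer, values in r.atoms().items():
            assert values <= p.atoms()[layer]
    assert ph.restrict(ph.profile(by_sampa["du"]), ph.KNOWLEDGE_LEVELS["all"]) == (
        ph.profile(by_sampa["du"])
    )


def test_restrict_minus_features_empties_only_that_layer(by_sampa):
    p = ph.profile(by_sampa["du"])
    r = ph.restrict(p, ph.KNOWLEDGE_LEVELS["minus_features"])
    assert r.segment_features == frozenset()
    assert r.segment_types == p.segment_types
    assert r.score_type == p.score_type


def test_knowledge_levels_require_syllable_layer():
    with pytest.raises(ValueError):
        ph.KnowledgeLevel("bad", frozenset({"score"}))
    for lv in ph.KNOWLEDGE_LEVELS.values():
        assert "syllable" in lv.layers_present


# --- syllabification -------------------------------------------------------


def _chunkings(pattern, known):
    """All ways to split a C/V pattern string into known structures."""
    if not pattern:
        return [[]]
    out = []
    for k in known:
        if pattern.startswith(k):
            out += [[k] + rest for rest in _chunkings(pattern[len(k):], known)]
    return out


def _oracle_chunking(pattern, known):
    """Greedy longest-match reference: of all valid chunkings, the one that
    is lexicographically first by (longest-chunk-first) choice order."""
    options = _chunkings(pattern, known)
    if not options:
        return None
    return max(options, key=lambda c: [len(x) for x in c])


@given(st.lists(st.sampled_from("bdgptkmnl iau".replace(" ", "")), min_size=1,
                max_size=8))
@settings(max_examples=60, derandomize=True, deadline=None)
def test_syllabify_matches_bruteforce(symbols):
    inv = ph.EXP2_INVENTORY
    phonemes = [inv.lookup(c) for c in symbols]
    pattern = "".join("V" if p.is_vowel else "C" for p in phonemes)
    known = ("CCV", "CV", "V")
    expected = _oracle_chunking(pattern, known)
    if expected is None:
        with pytest.raises(ph.PlanningError):
            ph.syllabify(phonemes, known)
    else:
        got = [s.pattern for s in ph.syllabify(phonemes, known)]
        assert got == expected


def test_syllabify_examples():
    inv = ph.EXP2_INVENTORY
    t, a = inv.lookup("t"), inv.lookup("a")
    assert [s.sampa for s in ph.syllabify([t, a])] == ["ta"]
    assert [s.sampa for s in ph.syllabify([t, a, t, a])] == ["ta", "ta"]
    with pytest.raises(ph.PlanningError):
        ph.syllabify([t, t], known_structures=("CV", "CCV"))


# --- lexicon and serialization --------------------------------------------


def test_lexicon_and_exports(vocab45):
    lex = ph.make_lexicon(vocab45, seed=3)
    assert len(lex) == 45
    assert ph.make_lexicon(vocab45, seed=3) == lex
    assert ph.make_lexicon(vocab45, seed=4) != lex
    tsv = ph.vocabulary_to_tsv(vocab45, lex)
    lines = tsv.strip().split("\n")
    assert lines[0].split("\t") == ["word_id", "syllable", "structure", "score_type"]
    assert len(lines) == 46


def test_inventory_yaml_roundtrip():
    text = ph.inventory_to_yaml(ph.EXP2_INVENTORY)
    back = ph.inventory_from_yaml(text)
    assert back == ph.EXP2_INVENTORY


def test_phoneme_invariants():
    with pytest.raises(ValueError):
        ph.Phoneme("x", ph.VOWEL, voicing="voiced")
    with pytest.raises(ValueError):
        ph.Phoneme("x", ph.PLOSIVE, vowel_height="high")
    with pytest.raises(ph.UnsupportedStructureError):
        ph.Syllable((ph.EXP2_INVENTORY.lookup("a"), ph.EXP2_INVENTORY.lookup("a"),
                     ph.EXP2_INVENTORY.lookup("a")))
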