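"""Gesture expansion, raw/full scores, adaptation and substitution counts."""

import dataclasses

import pytest

from speechdev import gestures as ge
from speechdev import phonology as ph

INV = ph.EXP1_INVENTORY


def syll(sampa):
    return ph.Syllable(tuple(INV.lookup(c) for c in sampa))


def gtypes(bundle):
    return {g.gtype for g in bundle}


# --- phoneme -> gesture bundles (one row per phoneme class) ----------------


@pytest.mark.parametrize(
    "symbol, expected",
    [
        ("a", {ge.TRACT_SHAPING, ge.LABIAL_SHAPING, ge.VELO_CLOSING,
               ge.GLOTTAL_CLOSING}),
        ("b", {ge.FULL_CLOSING, ge.VELO_TIGHT_CLOSING, ge.GLOTTAL_CLOSING}),
        ("p", {ge.FULL_CLOSING, ge.VELO_TIGHT_CLOSING, ge.GLOTTAL_OPENING}),
        ("n", {ge.FULL_CLOSING, ge.VELO_OPENING, ge.GLOTTAL_CLOSING}),
        ("l", {ge.LATERAL_CONSTRICTION, ge.VELO_CLOSING, ge.GLOTTAL_CLOSING}),
        ("?", {ge.GLOTTAL_TIGHT_CLOSING, ge.VELO_CLOSING}),
    ],
)
def test_expand_phoneme_bundles(symbol, expected):
    assert gtypes(ge.expand_phoneme(INV.lookup(symbol))) == expected


def test_expand_phoneme_articulators():
    b = ge.expand_phoneme(INV.lookup("b"))
    closing = next(g for g in b if g.gtype == ge.FULL_CLOSING)
    assert closing.articulator == "labial"
    n = ge.expand_phoneme(INV.lookup("n"))
    assert next(g for g in n if g.gtype == ge.FULL_CLOSING).articulator == "apical"


@pytest.mark.parametrize(
    "gesture, features",
    [
        (ge.Gesture(ge.VELO_OPENING), {"nasal"}),
        (ge.Gesture(ge.GLOTTAL_OPENING), {"voiceless"}),
        (ge.Gesture(ge.TRACT_SHAPING, "tongue_body", "a"),
         {"high-low", "front-back"}),
        (ge.Gesture(ge.FULL_CLOSING, "apical", "closure"),
         {"full_closure", "apical"}),
    ],
)
def test_gesture_features(gesture, features):
    assert ge.gesture_features(gesture) == features


def test_gesture_invariants():
    with pytest.raises(ge.ExpansionError):
        ge.Gesture(ge.FULL_CLOSING, articulator=None)
    with pytest.raises(ge.ExpansionError):
        ge.Gesture(ge.VELO_OPENING, articulator="apical")


def test_features_roundtrip_against_profile(vocab45):
    """The union of per-segment gesture features reproduces the profile's
    segment-feature layer for every syllable of the model language."""
    for s in vocab45:
        prof = ph.profile(s)
        feats = set()
        if s.structure == "CV":
            feats |= ge.segment_features_from_gestures(
                ge.expand_phoneme(s.phonemes[0]), "C")
        else:
            feats |= ge.segment_features_from_gestures(
                ge.expand_phoneme(s.phonemes[0]), "C1")
            feats |= ge.segment_features_from_gestures(
                ge.expand_phoneme(s.phonemes[1]), "C2")
        feats |= ge.segment_features_from_gestures(
            ge.expand_phoneme(s.nucleus), "V", s.nucleus)
        assert feats == set(prof.segment_features), s.sampa


# --- raw gesture scores ----------------------------------------------------


def test_raw_score_plan_assimilation():
    """/plan/: the three voiced sounds /lan/ share one merged phonation
    gesture; the velic tier ends with an opening gesture on the nasal coda."""
    raw = ge.build_raw_score(syll("plan"))
    glottal = raw.tiers["glottal"]
    assert [(g.gesture.gtype, g.span) for g in glottal] == [
        (ge.GLOTTAL_OPENING, (0, 0)),
        (ge.GLOTTAL_CLOSING, (1, 3)),
    ]
    velo = raw.tiers["velo"]
    assert velo[-1].gesture.gtype == ge.VELO_OPENING
    assert velo[-1].span == (3, 3)
    constr = [(g.gesture.gtype, g.gesture.articulator) for g in raw.tiers["constr"]]
    assert constr == [
        (ge.FULL_CLOSING, "labial"),
        (ge.LATERAL_CONSTRICTION, "apical"),
        (ge.FULL_CLOSING, "apical"),
    ]


def test_raw_score_ma_and_single_vowel():
    raw = ge.build_raw_score(syll("ma"))
    assert [(g.gesture.gtype, g.span) for g in raw.tiers["glottal"]] == [
        (ge.GLOTTAL_CLOSING, (0, 1))
    ]
    assert [g.gesture.gtype for g in raw.tiers["velo"]] == [
        ge.VELO_OPENING, ge.VELO_CLOSING
    ]
    single = ge.build_raw_score(syll("a"))
    assert all(len(tg) <= 2 for tg in single.tiers.values())
    assert all(tg.span == (0, 0) for t in ge.TIERS for tg in single.tiers[t])


def test_assimilation_merges_only_identical_and_unmerges(vocab45):
    for s in vocab45:
        raw = ge.build_raw_score(s)
        for tier in ge.TIERS:
            for a, b in zip(raw.tiers[tier], raw.tiers[tier][1:]):
                assert a.gesture != b.gesture  # merged runs are maximal
        # splitting spans recovers the per-phoneme bundles exactly
        split = ge.unmerge(raw)
        for pos, p in enumerate(s.phonemes):
            bundle = {
                tg.gesture
                for tier in ge.TIERS
                for tg in split[tier]
                if tg.span == (pos, pos)
            }
            assert bundle == set(ge.expand_phoneme(p)), (s.sampa, pos)


def test_tight_and_plain_velic_closing_never_assimilate():
    # /?a/: glottal stop's velic closing then the vowel's -- identical type,
    # so they merge; /pa/: tight closing vs closing stay separate
    raw = ge.build_raw_score(syll("pa"))
    assert [g.gesture.gtype for g in raw.tiers["velo"]] == [
        ge.VELO_TIGHT_CLOSING, ge.VELO_CLOSING
    ]


# --- fully specified scores ------------------------------------------------


def test_specify_full_plan_layout():
    full = ge.specify_full(ge.build_raw_score(syll("plan")))
    by_type = {}
    for fg in full.gestures:
        by_type.setdefault(fg.gesture.gtype, []).append(fg)
    closure_p = min(by_type[ge.FULL_CLOSING], key=lambda f: f.target_start)
    velo_open = by_type[ge.VELO_OPENING][0]
    assert closure_p.target_start == min(f.target_start for f in full.gestures
                                         if f.tier != "tract" or True)
    assert velo_open.target_start == max(f.target_start for f in full.gestures)
    tract = [f for f in full.gestures if f.tier == "tract"]
    assert all(f.activation_onset == 0.0 for f in tract)
    for fg in full.gestures:
        assert 0.0 <= fg.activation_onset <= fg.target_start
        assert fg.target_start <= fg.target_end <= fg.activation_offset <= 640.0


def test_specify_full_zero_release(vocab45):
    policy = ge.TimingPolicy(release_ms=0.0)
    full = ge.specify_full(ge.build_raw_score(vocab45[0]), policy)
    for fg in full.gestures:
        assert fg.activation_offset == fg.target_end


def test_specify_full_inverted_policy_raises():
    policy = ge.TimingPolicy(release_ms=-300.0)
    with pytest.raises(ge.SpecificationError):
        ge.specify_full(ge.build_raw_score(syll("pa")), policy)


def test_full_score_raw_roundtrip(vocab45):
    for s in vocab45[:10]:
        raw = ge.build_raw_score(s)
        assert ge.specify_full(raw).raw() == raw


# --- adaptation and substitution counting ----------------------------------


def _plan(sampa):
    return ge.build_raw_score(syll(sampa))


def _program(sampa):
    return ge.specify_full(_plan(sampa))


def test_adapt_da_to_du_single_vowel_substitution():
    adapted = ge.adapt_score(_program("da"), _plan("du"))
    summary = ge.substitution_count(_plan("da"), _plan("du"))
    assert summary.count == 1 and summary.stratum == "vowel_only"
    # donor timing is copied bitwise
    donor = {(fg.tier, i): fg for i, fg in enumerate(_program("da").gestures)}
    for i, fg in enumerate(adapted.gestures):
        d = donor[(fg.tier, i)]
        assert (fg.activation_onset, fg.target_start, fg.target_end,
                fg.activation_offset) == (
            d.activation_onset, d.target_start, d.target_end, d.activation_offset)
    assert ge.substitution_count(adapted.raw(), _plan("du")).count == 0


def test_adapt_identity_and_place_substitution():
    assert ge.adapt_score(_program("da"), _plan("da")) == _program("da")
    summary = ge.substitution_count(_plan("pa"), _plan("ta"))
    assert summary.count == 1
    assert summary.stratum == "consonantal_1"
    adapted = ge.adapt_score(_program("pa"), _plan("ta"))
    assert ge.substitution_count(adapted.raw(), _plan("ta")).count == 0


def test_substitution_strata():
    # /du/ vs /ta/ share the apical closure: only voicing differs consonantally
    s = ge.substitution_count(_plan("du"), _plan("ta"))
    assert s.vowel_substitutions == 1
    assert s.consonantal_substitutions == 1
    assert s.stratum == "consonantal_1"
    # /du/ vs /pa/: place target and voicing gesture beside the vowel
    s2 = ge.substitution_count(_plan("du"), _plan("pa"))
    assert s2.consonantal_substitutions == 2
    assert s2.stratum == "consonantal_2"
    assert ge.substitution_count(_plan("du"), _plan("du")).count == 0


def test_adapt_incompatible_skeleton():
    with pytest.raises(ge.AdaptationError):
        ge.adapt_score(_program("da"), _plan("pla"))
    with pytest.raises(ge.AdaptationError):
        ge.substitution_count(_plan("da"), _plan("pla"))


def test_adapted_scores_over_vocabulary(vocab45):
    """Adapting any learned CV/a donor to any CV plan reproduces the plan."""
    donors = [s for s in vocab45 if s.structure == "CV" and s.nucleus.symbol == "a"]
    targets = [s for s in vocab45 if s.structure == "CV"][:9]
    for d in donors[:4]:
        for t in targets:
            adapted = ge.adapt_score(
                ge.specify_full(ge.build_raw_score(d)), ge.build_raw_score(t))
            assert ge.substitution_count(
                adapted.raw(), ge.build_raw_score(t)).count == 0


# --- serialization ---------------------------------------------------------


def test_textgrid_and_json_export():
    full = _program("pla")
    tg = ge.score_to_textgrid(full)
    assert tg.startswith('File type = "ooTextFile"')
    assert '"IntervalTier"' in tg and "glottal" in tg
    import json

    doc = json.loads(ge.full_score_to_json(full))
    assert doc["sampa"] == "pla"
    assert len(doc["gestures"]) == len(full.gestures)
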