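import pytest

from mirminer.datasets import load_table1, table1_fixture
from mirminer.filtering import (FilterConfig, HairpinEvaluation, apply_criteria,
                                compute_mfei, count_substitutions, name_mirnas,
                                parse_family, star_mismatches)
from mirminer.folding import fold_mfe, hairpin_geometry, parse_dotbracket
from mirminer.homology import MatureHit
from mirminer.precursor import PrecursorCandidate
from mirminer.seqio import reverse_complement

from _oracles import random_rna


def test_count_substitutions():
    assert count_substitutions("CAGAAGAUAGAGAGCACAGA", "CAGAAGAUAGAGAGCACAGA") == 0
    two_off = "CAGAAGAUAGAGAGCACAGA"
    variant = "CGGAAGAUAGAGAGCACAGU"
    assert count_substitutions(variant, two_off) == 2
    with pytest.raises(ValueError):
        count_substitutions("ACGU", "ACG")


def test_star_report_on_perfect_duplex(rng):
    stem = random_rna(rng, 20)
    s = fold_mfe(stem + "AAAA" + reverse_complement(stem))
    g = hairpin_geometry(s, (1, 20))
    report = star_mismatches(s, (1, 20), g.star_span)
    assert report.mismatch_count == 0
    assert not report.star_has_loop_or_break


def test_star_interrupted_by_internal_loop():
    # constructed pairing: two 8-bp helices split by a 5-nt bulge on the star side
    seq = "GGGGGGGGGGGGGGGGAAAACCCCCCCCAAAAACCCCCCCC"
    db = "((((((((((((((((....)))))))).....))))))))"
    s = parse_dotbracket(seq, db)
    report = star_mismatches(s, (1, 16), (21, 41), loop_break_min=3)
    assert report.star_has_loop_or_break


def test_star_mismatch_threshold_boundary(rng):
    cfg = FilterConfig()
    stem = random_rna(rng, 20)
    s = fold_mfe(stem + "AAAA" + reverse_complement(stem))
    g = hairpin_geometry(s, (1, 20))
    report = star_mismatches(s, (1, 20), g.star_span)
    # a perfect duplex passes; six hypothetical unpaired positions would not
    assert report.mismatch_count <= cfg.max_star_mismatches
    assert not 6 <= cfg.max_star_mismatches


def test_compute_mfei_arithmetic_and_errors():
    amfe, mfei = compute_mfei(-40.0, 100, 42.0)
    assert amfe == pytest.approx(40.0)
    assert mfei == pytest.approx(0.952, abs=1e-3)
    assert compute_mfei(0.0, 100, 42.0) == (0.0, 0.0)
    with pytest.raises(ValueError):
        compute_mfei(-40.0, 100, 0.0)
    with pytest.raises(ValueError):
        compute_mfei(-40.0, 0, 42.0)
    with pytest.raises(ValueError):
        compute_mfei(+1.0, 100, 42.0)


def _passing_evaluation(**overrides):
    """A synthetic evaluation with every statistic in the passing range."""
    mature = "GGGGGGGGGGAAAAAAAAAA"
    window = mature + "CAAG" + reverse_complement(mature)
    hit = MatureHit("ath-miR156a", "s", 1, 20, "+", 0, mature, mature)
    cand = PrecursorCandidate(hit, window, 1, len(window), 1, False)
    structure = fold_mfe(window)
    ev = HairpinEvaluation(
        candidate=cand, structure=structure, lp_nt=44, lm_nt=20, nm_subst=0,
        arm="5", star_mismatch_count=0, star_loop_or_break=False,
        au_frac=0.50, mfe_kcal_mol=-20.0, amfe=45.0, mfei=1.0)
    for key, val in overrides.items():
        setattr(ev, key, val)
    return apply_criteria(ev, FilterConfig())


@pytest.mark.parametrize("overrides,expected,failing", [
    ({}, True, None),
    ({"mfei": 0.84}, False, "mfei"),
    ({"mfei": 0.86}, True, None),
    ({"au_frac": 0.29}, False, "au_content"),
    ({"au_frac": 0.30}, True, None),
    ({"au_frac": 0.70}, True, None),
    ({"au_frac": 0.71}, False, "au_content"),
    ({"au_frac": 0.75}, False, "au_content"),
    ({"nm_subst": 4}, False, "substitutions"),
    ({"star_mismatch_count": 6}, False, "star_mismatches"),
    ({"star_mismatch_count": 5}, True, None),
    ({"star_loop_or_break": True}, False, "star_loop_or_break"),
    ({"arm": None}, False, "mature_in_arm"),
])
def test_acceptance_thresholds_behave_as_printed_bounds(overrides, expected, failing):
    ev = _passing_evaluation(**overrides)
    assert ev.accepted is expected
    if failing == "au_content":
        assert not ev.au_ok and "au_content" in ev.rejection_reasons
    elif failing:
        assert not ev.criteria_verdicts[failing]
        assert [failing] == [k for k, v in ev.criteria_verdicts.items() if not v]


def _accepted(query_id, subject="s", start=1):
    mature = "GGGGGGGGGGAAAAAAAAAA"
    hit = MatureHit(query_id, subject, start, start + 19, "+", 0, mature, mature)
    cand = PrecursorCandidate(hit, mature + "AAAA" + reverse_complement(mature),
                              1, 44, 1, False)
    return HairpinEvaluation(candidate=cand, accepted=True)


def test_naming_letters_members_in_order():
    evs = [_accepted("ath-miR156a"), _accepted("osa-miR156b"),
           _accepted("ath-miR156c"), _accepted("ath-miR164a")]
    named = name_mirnas(evs, "vun")
    assert [e.name for e in named] == \
        ["vun-MIR156a", "vun-MIR156b", "vun-MIR156c", "vun-MIR164"]


def test_naming_requires_parseable_family_and_nonempty_input():
    with pytest.raises(ValueError, match="family"):
        name_mirnas([_accepted("not-a-mirna-id")])
    with pytest.raises(ValueError, match="no accepted"):
        name_mirnas([])


@pytest.mark.parametrize("mir_id,family", [
    ("ath-miR156a", 156), ("vun-MIR2118", 2118), ("gma-MIR482", 482),
    ("osa-miR001", 1),
])
def test_parse_family(mir_id, family):
    assert parse_family(mir_id) == family


def test_packaged_mature_set_consistency():
    recs = table1_fixture()
    assert len(recs) == 47
    assert recs[0].seq_id == "vun-MIR156a"
    assert recs[0].residues == "UGACAGAAGAUAGAGAGCAC"
    by_id = {r.seq_id: r for r in recs}
    assert by_id["vun-MIR395a"].residues == "CUGAAGUGUUUGGGGGAACUCC"
    df = load_table1()
    # every printed MFEI clears the 0.85 screen, including the closest row
    assert (df.mfei > 0.85).all()
    assert df.loc[df.name == "vun-MIR172d", "mfei"].item() == pytest.approx(0.87)
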