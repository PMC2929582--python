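import pytest

from mirminer.seqio import SequenceRecord, reverse_complement
from mirminer.targets import classify_site, duplex_energy, scan_targets

from _oracles import random_rna

GC_RICH_MIR = "GCGGCCGCAUGGCCGGCGCCGG"  # 22 nt, strongly pairing


def _perfect_site(mirna):
    return reverse_complement(mirna)


def test_perfect_gc_rich_site_is_reported(rng):
    site = _perfect_site(GC_RICH_MIR)
    transcript = SequenceRecord("t", random_rna(rng, 80) + site + random_rna(rng, 80))
    mir = SequenceRecord("m", GC_RICH_MIR)
    sites = scan_targets(mir, [transcript])
    hit = [s for s in sites if s.site_start == 81]
    assert len(hit) == 1
    assert hit[0].mismatch_count == 0
    assert hit[0].duplex_energy_kcal_mol < -28.2


def test_four_mismatches_not_reported(rng):
    site = list(_perfect_site(GC_RICH_MIR))
    for p in (3, 8, 13, 18):
        site[p] = "A" if site[p] != "A" else "C"
    transcript = SequenceRecord("t", random_rna(rng, 50) + "".join(site)
                                + random_rna(rng, 50))
    sites = scan_targets(SequenceRecord("m", GC_RICH_MIR), [transcript])
    assert not any(s.site_start == 51 for s in sites)


def test_weak_au_duplex_fails_energy_cutoff():
    """A perfectly complementary but A/U-only 16-mer pairs too weakly."""
    mir = "AUAUAUAUAUAUAUAU"
    site = _perfect_site(mir)
    assert duplex_energy(mir, site) > -28.2
    transcript = SequenceRecord("t", "C" * 40 + site + "C" * 40)
    assert scan_targets(SequenceRecord("m", mir), [transcript]) == []


def test_duplex_energy_properties(rng):
    for _ in range(20):
        mir = random_rna(rng, 21)
        perfect = _perfect_site(mir)
        e0 = duplex_energy(mir, perfect)
        # one mismatch never strengthens the duplex
        p = rng.randrange(21)
        mutated = list(perfect)
        mutated[p] = {"A": "C", "C": "A", "G": "U", "U": "G"}[mutated[p]]
        assert e0 < duplex_energy(mir, "".join(mutated)) + 1e-9
        # symmetric under strand swap
        assert duplex_energy(mir, perfect) == pytest.approx(
            duplex_energy(perfect, mir))


def test_duplex_energy_edge_cases():
    with pytest.raises(ValueError):
        duplex_energy("", "")
    with pytest.raises(ValueError):
        duplex_energy("ACGU" * 5, "ACGU" * 4)
    # no complementary positions at all: initiation penalty only
    assert duplex_energy("A" * 20, "A" * 20) == pytest.approx(4.09)


def test_scan_matches_brute_force_on_short_transcripts(rng):
    mir = SequenceRecord("m", GC_RICH_MIR)
    body = random_rna(rng, 300) + _perfect_site(GC_RICH_MIR) + random_rna(rng, 100)
    transcript = SequenceRecord("t", body)
    sites = scan_targets(mir, [transcript])
    # brute force: every window, same thresholds
    from mirminer.energy import default_model
    from mirminer.targets import _pairing
    model = default_model()
    L = len(mir)
    expected = []
    for start in range(len(body) - L + 1):
        window = body[start:start + L]
        _, mm = _pairing(mir.residues, window, model)
        if mm <= 3 and duplex_energy(mir.residues, window) < -28.2:
            expected.append(start + 1)
    reported_or_overlapped = set()
    for s in sites:
        reported_or_overlapped.update(range(s.site_start - L + 1, s.site_end + 1))
    assert all(start in reported_or_overlapped for start in expected)
    assert all(s.site_start in expected for s in sites)


def test_raising_threshold_never_removes_sites(rng):
    mir = SequenceRecord("m", GC_RICH_MIR)
    transcript = SequenceRecord(
        "t", random_rna(rng, 60) + _perfect_site(GC_RICH_MIR) + random_rna(rng, 60))
    strict = scan_targets(mir, [transcript], energy_threshold=-30.0)
    loose = scan_targets(mir, [transcript], energy_threshold=-5.0)
    strict_keys = {(s.transcript_id, s.site_start) for s in strict}
    loose_keys = {(s.transcript_id, s.site_start) for s in loose}
    assert strict_keys <= loose_keys


def test_classify_site_against_orf_layout(rng):
    utr5 = random_rna(rng, 100).replace("AUG", "ACG")
    orf = "AUG" + "GCUGAACUGAAG" * 24 + "UAA"          # 98 codons + stop
    utr3 = random_rna(rng, 100)
    tr = SequenceRecord("t", utr5 + orf + utr3)
    assert classify_site((10, 31), tr) == "five_prime_utr"
    assert classify_site((101 + len(orf) - 10, 101 + len(orf) + 10), tr) == "orf"
    assert classify_site((120, 140), tr) == "orf"
    assert classify_site((len(utr5) + len(orf) + 20,
                          len(utr5) + len(orf) + 40), tr) == "three_prime_utr"
    no_start = SequenceRecord("t2", ("UUC" * 120))
    assert classify_site((10, 30), no_start) == "unclassified"


def test_many_to_many_reporting(rng):
    mir_a = SequenceRecord("mirA", GC_RICH_MIR)
    mir_b = SequenceRecord("mirB", "GGCCGCGGCCAUGCGGCCGGCC")
    shared = SequenceRecord(
        "t_shared", _perfect_site(mir_a.residues) + random_rna(rng, 30)
        + _perfect_site(mir_b.residues))
    other = SequenceRecord("t_other", "UU" + _perfect_site(mir_a.residues) + "UU")
    sites = scan_targets(mir_a, [shared, other]) + scan_targets(mir_b, [shared, other])
    pairs = {(s.mirna_id, s.transcript_id) for s in sites}
    assert {("mirA", "t_shared"), ("mirA", "t_other"), ("mirB", "t_shared")} <= pairs
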