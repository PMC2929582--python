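"""miRNA target scanning by antisense complementarity and duplex energy.

Plant miRNAs pair near-perfectly with their targets, so the scan is an
exhaustive ungapped antisense window walk: a transcript window is a site
when fewer than 4 of its positions fail to pair with the miRNA and the
bimolecular nearest-neighbor duplex energy is below the cutoff
(-28.2 kcal/mol by default).  Sites are classified against the longest
forward-frame ORF as 5'UTR, ORF, or 3'UTR.
"""

from __future__ import annotations

from dataclasses import dataclass

from .energy import EnergyModel, default_model
from .precursor import _orf_spans
from .seqio import SequenceRecord

DEFAULT_ENERGY_THRESHOLD = -28.2
DEFAULT_MAX_TARGET_MISMATCHES = 3
DEFAULT_MIN_ORF_AA = 30


@dataclass(frozen=True)
class TargetSite:
    """One predicted binding site; span is 1-based inclusive on the transcript."""

    mirna_id: str
    transcript_id: str
    site_start: int
    site_end: int
    mismatch_count: int
    duplex_energy_kcal_mol: float
    site_class: str                  # five_prime_utr | orf | three_prime_utr | unclassified
    mirna_seq: str
    site_seq: str                    # transcript window, 5'->3'

    @property
    def site_span(self) -> tuple[int, int]:
        return self.site_start, self.site_end


def _pairing(mirna: str, site: str, model: EnergyModel,
             wobble_is_match: bool = True) -> tuple[list[int], int]:
    """Antiparallel pair types per miRNA position, and the mismatch tally.

    miRNA position k pairs with site position L-1-k.  Wobble pairs carry
    their (weak) stack energy and by default do not count as mismatches.
    """
    L = len(mirna)
    pts, mismatches = [], 0
    for k in range(L):
        pt = model.pair_type(mirna[k], site[L - 1 - k])
        pts.append(pt)
        if pt < 0:
            mismatches += 1
        elif pt >= 4 and not wobble_is_match:     # GU / UG
            mismatches += 1
    return pts, mismatches


def duplex_energy(mirna: str, site: str, model: EnergyModel | None = None) -> float:
    """Bimolecular hybridization energy of an equal-length antisense duplex.

    Initiation penalty plus nearest-neighbor stacks over consecutive paired
    positions; each internal run of unpaired positions costs an opening
    penalty plus a per-nucleotide term.  Unpaired duplex ends are free.
    """
    model = model or default_model()
    if not mirna or len(mirna) != len(site):
        raise ValueError("duplex requires two equal-length non-empty strands")
    pts, _ = _pairing(mirna, site, model)
    energy = model.duplex_init
    L = len(mirna)
    paired_idx = [k for k in range(L) if pts[k] >= 0]
    for k in range(L - 1):
        if pts[k] >= 0 and pts[k + 1] >= 0:
            energy += model.stack[pts[k], pts[k + 1]]
    if paired_idx:
        first, last = paired_idx[0], paired_idx[-1]
        run = 0
        for k in range(first, last + 1):
            if pts[k] < 0:
                run += 1
            elif run:
                energy += model.duplex_mismatch_open + model.duplex_mismatch_nt * 2 * run
                run = 0
    return energy


def site_passes(mismatch_count: int, energy: float,
                max_mismatches: int = DEFAULT_MAX_TARGET_MISMATCHES,
                energy_threshold: float = DEFAULT_ENERGY_THRESHOLD) -> bool:
    """The site decision rule: fewer than 4 mismatches and energy strictly
    below the cutoff ("lower than -28.2 kcal/mol")."""
    return mismatch_count <= max_mismatches and energy < energy_threshold


def classify_site(site_span: tuple[int, int], transcript: SequenceRecord,
                  min_orf_aa: int = DEFAULT_MIN_ORF_AA) -> str:
    """Place a site relative to the transcript's longest forward-frame ORF."""
    lo, hi = site_span
    if not (1 <= lo <= hi <= len(transcript)):
        raise ValueError(f"site span {site_span} outside transcript")
    orfs = _orf_spans(transcript.residues, min_orf_aa)
    if not orfs:
        return "unclassified"
    a, b = max(orfs, key=lambda s: (s[1] - s[0], -s[0]))  # 0-based [a, b)
    b = min(b + 3, len(transcript))                        # include the stop codon
    if hi <= a:
        return "five_prime_utr"
    if lo > b:
        return "three_prime_utr"
    return "orf"


def scan_targets(mirna: SequenceRecord, transcripts: list[SequenceRecord],
                 max_mismatches: int = DEFAULT_MAX_TARGET_MISMATCHES,
                 energy_threshold: float = DEFAULT_ENERGY_THRESHOLD,
                 wobble_is_match: bool = True,
                 min_orf_aa: int = DEFAULT_MIN_ORF_AA,
                 model: EnergyModel | None = None) -> list[TargetSite]:
    """All binding sites of one miRNA across a transcript collection.

    Overlapping sites on one transcript are collapsed to the lowest-energy
    one; results are sorted by energy, then transcript and position.
    """
    model = model or default_model()
    if len(mirna) < 16:
        raise ValueError("miRNA shorter than 16 nt")
    L = len(mirna)
    sites: list[TargetSite] = []
    for tr in transcripts:
        if tr.is_ambiguous:
            continue
        per_tr: list[TargetSite] = []
        for start0 in range(len(tr) - L + 1):
            window = tr.residues[start0:start0 + L]
            _, mm = _pairing(mirna.residues, window, model, wobble_is_match)
            if mm > max_mismatches:
                continue
            e = duplex_energy(mirna.residues, window, model)
            if not site_passes(mm, e, max_mismatches, energy_threshold):
                continue
            per_tr.append(TargetSite(
                mirna.seq_id, tr.seq_id, start0 + 1, start0 + L, mm, e,
                classify_site((start0 + 1, start0 + L), tr, min_orf_aa),
                mirna.residues, window))
        # collapse overlapping sites, best energy first
        per_tr.sort(key=lambda s: (s.duplex_energy_kcal_mol, s.site_start))
        kept: list[TargetSite] = []
        for cand in per_tr:
            if all(cand.site_end < k.site_start or cand.site_start > k.site_end
                   for k in kept):
                kept.append(cand)
        sites.extend(kept)
    sites.sort(key=lambda s: (s.duplex_energy_kcal_mol, s.transcript_id, s.site_start))
    return sites


SITE_CLASS_LABEL = {
    "five_prime_utr": "5'UTR",
    "orf": "ORF",
    "three_prime_utr": "3'UTR",
    "unclassified": "unclassified",
}
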