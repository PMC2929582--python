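"""The six-criteria hairpin screen, summary statistics, and miRNA naming.

A folded candidate passes when (1) it forms a stem-loop, (2) the mature
sits on one arm, (3) it differs from the known mature by at most 3
substitutions, (4) fewer than 6 of its bases are unpaired against the
miRNA* region, (5) the star region carries no large loop or break, and
(6) the minimal folding free energy index (MFEI) of the trimmed precursor
exceeds 0.85 — together with an A+U content screen of 30-70%.

AMFE = (|MFE| / precursor length) x 100 and MFEI = AMFE / GC%, the usual
index separating miRNA hairpins from other noncoding or coding RNA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .energy import EnergyModel, default_model
from .folding import SecondaryStructure, fold_mfe, hairpin_geometry
from .precursor import PrecursorCandidate
from .seqio import au_fraction, gc_fraction

CRITERIA = ("hairpin", "mature_in_arm", "substitutions", "star_mismatches",
            "star_loop_or_break", "mfei")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the acceptance screen (defaults are the standard ones)."""

    max_substitutions: int = 3       # criterion 3: "no more than 3"
    max_star_mismatches: int = 5     # criterion 4: "less than 6"
    loop_break_min: int = 3          # criterion 5: unpaired run that counts as a break
    mfei_threshold: float = 0.85     # criterion 6, strict
    au_min: float = 0.30
    au_max: float = 0.70
    wobble_is_match: bool = True     # G:U counts as paired in criterion 4
    min_hairpin_pairs: int = 1       # criterion 1: any stem-loop at all
    trim_max_gap: int = 4            # largest bulge/internal gap inside the
                                     # reported precursor stem


@dataclass
class HairpinEvaluation:
    """All statistics for one folded candidate, plus the criteria verdicts."""

    candidate: PrecursorCandidate
    structure: SecondaryStructure | None = None
    trimmed_precursor_span: tuple[int, int] | None = None  # 1-based in window
    precursor_seq: str | None = None
    lp_nt: int | None = None
    lm_nt: int | None = None
    nm_subst: int | None = None
    arm: str | None = None           # "5" or "3" when on an arm
    star_span: tuple[int, int] | None = None
    star_mismatch_count: int | None = None
    star_loop_or_break: bool | None = None
    au_frac: float | None = None
    mfe_kcal_mol: float | None = None
    amfe: float | None = None
    mfei: float | None = None
    criteria_verdicts: dict[str, bool] = field(default_factory=dict)
    au_ok: bool | None = None
    accepted: bool = False
    rejection_reasons: list[str] = field(default_factory=list)
    name: str | None = None


def count_substitutions(mature_candidate: str, known_mature: str) -> int:
    """Hamming distance between the candidate mature and the known mature."""
    if len(mature_candidate) != len(known_mature):
        raise ValueError("substitution count requires an equal-length ungapped alignment")
    return sum(a != b for a, b in zip(mature_candidate, known_mature))


@dataclass(frozen=True)
class StarReport:
    mismatch_count: int
    star_has_loop_or_break: bool


def star_mismatches(structure: SecondaryStructure, mature_span: tuple[int, int],
                    star_span: tuple[int, int], loop_break_min: int = 3,
                    wobble_is_match: bool = True) -> StarReport:
    """Mature/miRNA* duplex quality from the folded pairing table.

    A mature position counts as a mismatch when it is unpaired or paired
    outside the star span (or wobble-paired, if wobble is configured to
    count as a mismatch).  The star has a loop or break when it contains a
    run of >= loop_break_min unpaired bases or a base paired outside the
    mature (a branch into another helix).  The 2-nt 3' overhang is excluded
    from the loop/break scan.
    """
    m_lo, m_hi = mature_span
    s_lo, s_hi = star_span
    loop = structure.hairpin_loop_span
    if loop is not None and m_lo <= loop[1] and m_hi >= loop[0]:
        raise ValueError("mature overlaps the terminal loop; not on a single arm")
    wobble = {frozenset("GU")}
    mismatches = 0
    for p in range(m_lo - 1, m_hi):             # 0-based
        q = structure.partner[p]
        if q < 0 or not (s_lo - 1 <= q <= s_hi - 1):
            mismatches += 1
        elif not wobble_is_match and \
                frozenset((structure.residues[p], structure.residues[q])) in wobble:
            mismatches += 1
    # scan the star core (without the 3' overhang) for breaks
    core_hi = max(s_lo - 1, s_hi - 1 - 2)
    loop_or_break = False
    run = 0
    for q in range(s_lo - 1, core_hi + 1):
        partner = structure.partner[q]
        if partner < 0:
            run += 1
            if run >= loop_break_min:
                loop_or_break = True
                break
        else:
            run = 0
            if not (m_lo - 1 <= partner <= m_hi - 1):
                loop_or_break = True            # star pairs away from the mature
                break
    return StarReport(mismatches, loop_or_break)


def compute_mfei(mfe_kcal_mol: float, lp_nt: int, gc_percent: float
                 ) -> tuple[float, float]:
    """AMFE and MFEI of a precursor: AMFE = (|MFE|/LP)*100, MFEI = AMFE/GC%."""
    if lp_nt <= 0:
        raise ValueError("precursor length must be positive")
    if mfe_kcal_mol > 0:
        raise ValueError("MFE must be <= 0")
    if not (0 < gc_percent < 100):
        raise ValueError("GC percentage must lie strictly between 0 and 100")
    amfe = abs(mfe_kcal_mol) / lp_nt * 100.0
    return amfe, amfe / gc_percent


def evaluate_candidate(candidate: PrecursorCandidate,
                       config: FilterConfig | None = None,
                       model: EnergyModel | None = None) -> HairpinEvaluation:
    """Fold one excised window and compute every statistic the screen needs.

    The reported precursor is the excised window trimmed to the outermost
    paired base of the stem-loop carrying the mature (extended to cover the
    mature itself), and its MFE/MFEI are recomputed on the trimmed sequence.
    """
    config = config or FilterConfig()
    model = model or default_model()
    ev = HairpinEvaluation(candidate=candidate)
    ev.lm_nt = candidate.hit.matched_length
    ev.nm_subst = candidate.hit.mismatch_count

    if any(c not in "ACGU" for c in candidate.window_seq):
        ev.rejection_reasons.append("ambiguous residues in window")
        return ev

    structure = fold_mfe(candidate.window_seq, model)
    ev.structure = structure
    geom = hairpin_geometry(structure, candidate.mature_span)
    if geom.arm in ("5p", "3p"):
        ev.arm = "5" if geom.arm == "5p" else "3"
        ev.star_span = geom.star_span
        star = star_mismatches(structure, candidate.mature_span, geom.star_span,
                               config.loop_break_min, config.wobble_is_match)
        ev.star_mismatch_count = star.mismatch_count
        ev.star_loop_or_break = star.star_has_loop_or_break

        # trim to the enclosing stem-loop, extended to cover mature and star
        loops = [c for c in structure.terminal_loops()
                 if (c[0] + 2, c[1]) == geom.loop_span]
        closing = loops[0] if loops else structure.terminal_loops()[0]
        sa, sb = structure.stemloop_span(closing, config.trim_max_gap)
        lo = min(sa + 1, candidate.mature_span[0], geom.star_span[0])
        hi = max(sb + 1, candidate.mature_span[1], geom.star_span[1])
        ev.trimmed_precursor_span = (lo, hi)
        ev.precursor_seq = candidate.window_seq[lo - 1:hi]
        ev.lp_nt = hi - lo + 1
        pre_structure = fold_mfe(ev.precursor_seq, model) if ev.lp_nt >= 10 else None
        ev.mfe_kcal_mol = pre_structure.mfe_kcal_mol if pre_structure else 0.0
        ev.au_frac = au_fraction(ev.precursor_seq)
        gc = gc_fraction(ev.precursor_seq)
        if 0.0 < gc < 1.0 and ev.mfe_kcal_mol <= 0:
            ev.amfe, ev.mfei = compute_mfei(ev.mfe_kcal_mol, ev.lp_nt, gc * 100.0)
        else:
            ev.amfe, ev.mfei = 0.0, 0.0
    return apply_criteria(ev, config)


def apply_criteria(ev: HairpinEvaluation,
                   config: FilterConfig | None = None) -> HairpinEvaluation:
    """Fill in the six criteria verdicts plus the A+U screen and accept/reject."""
    config = config or FilterConfig()
    s = ev.structure
    v = {
        "hairpin": bool(s is not None and s.n_pairs >= config.min_hairpin_pairs
                        and s.mfe_kcal_mol < 0 and s.terminal_loops()),
        "mature_in_arm": ev.arm in ("5", "3"),
        "substitutions": ev.nm_subst is not None
                         and ev.nm_subst <= config.max_substitutions,
        "star_mismatches": ev.star_mismatch_count is not None
                           and ev.star_mismatch_count <= config.max_star_mismatches,
        "star_loop_or_break": ev.star_loop_or_break is False,
        "mfei": ev.mfei is not None and ev.mfei > config.mfei_threshold,
    }
    ev.criteria_verdicts = v
    ev.au_ok = ev.au_frac is not None and config.au_min <= ev.au_frac <= config.au_max
    ev.accepted = all(v.values()) and ev.au_ok
    ev.rejection_reasons.extend(
        [name for name, ok in v.items() if not ok]
        + ([] if ev.au_ok else ["au_content"]))
    return ev


_FAMILY_RE = re.compile(r"(?i)mir-?0*(\d+)")


def parse_family(mirna_id: str) -> int:
    """Family number from a miRBase-style id (e.g. 'ath-miR156a' -> 156)."""
    m = _FAMILY_RE.search(mirna_id)
    if m is None:
        raise ValueError(f"cannot parse a miRNA family from id {mirna_id!r}")
    return int(m.group(1))


def _letters(k: int) -> str:
    """0 -> 'a', 25 -> 'z', 26 -> 'aa', ..."""
    out = ""
    k += 1
    while k:
        k, r = divmod(k - 1, 26)
        out = chr(ord("a") + r) + out
    return out


def name_mirnas(accepted: list[HairpinEvaluation],
                species_prefix: str = "vun") -> list[HairpinEvaluation]:
    """Assign {prefix}-MIR{family}{letter} names in input encounter order.

    The family number is inherited from the matched known miRNA; families
    with a single member carry no letter.  Stable across re-runs with the
    same input order.
    """
    if not accepted:
        raise ValueError("no accepted candidates to name")
    by_family: dict[int, list[HairpinEvaluation]] = {}
    for ev in accepted:
        fam = parse_family(ev.candidate.hit.query_id)
        by_family.setdefault(fam, []).append(ev)
    for fam, members in by_family.items():
        if len(members) == 1:
            members[0].name = f"{species_prefix}-MIR{fam}"
        else:
            for k, ev in enumerate(members):
                ev.name = f"{species_prefix}-MIR{fam}{_letters(k)}"
    return accepted


REPORT_COLUMNS = ("name", "gene_id", "source", "sequence", "nm", "lm", "lp",
                  "location", "au_fraction", "mfei")


def report_row(ev: HairpinEvaluation, source: str = "UNKNOWN") -> list[str]:
    return [
        ev.name or "-",
        ev.candidate.hit.subject_id,
        source,
        ev.candidate.hit.aligned_subject,
        str(ev.nm_subst),
        str(ev.lm_nt),
        str(ev.lp_nt) if ev.lp_nt is not None else "-",
        ev.arm or "-",
        f"{ev.au_frac:.2f}" if ev.au_frac is not None else "-",
        f"{ev.mfei:.2f}" if ev.mfei is not None else "-",
    ]
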