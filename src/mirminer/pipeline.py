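"""End-to-end orchestration: search -> excise -> screen -> fold -> filter ->
name -> (optional) targets -> (optional) family trees.

Every stage is a pure function of its inputs and the configuration; re-runs
with identical inputs produce byte-identical reports.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import asdict, dataclass, field

import yaml

from .filtering import (FilterConfig, HairpinEvaluation, REPORT_COLUMNS,
                        evaluate_candidate, name_mirnas, parse_family, report_row)
from .homology import MatureHit, SearchParams, search_all
from .phylo import distance_matrix, neighbor_joining
from .precursor import (DEFAULT_FLANK, DEFAULT_MIN_ORF_AA, PrecursorCandidate,
                        coding_screen, excise_window)
from .seqio import SequenceRecord
from .targets import (DEFAULT_ENERGY_THRESHOLD, DEFAULT_MAX_TARGET_MISMATCHES,
                      SITE_CLASS_LABEL, TargetSite, scan_targets)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the pipeline, with the standard screening defaults."""

    word_size: int = 7
    max_mismatches: int = 3
    min_match_length: int = 16
    both_strands: bool = True
    flank: int = DEFAULT_FLANK
    coding_screen_enabled: bool = True
    min_orf_aa: int = DEFAULT_MIN_ORF_AA
    max_star_mismatches: int = 5
    loop_break_min: int = 3
    mfei_threshold: float = 0.85
    au_min: float = 0.30
    au_max: float = 0.70
    wobble_is_match: bool = True
    energy_threshold: float = DEFAULT_ENERGY_THRESHOLD
    max_target_mismatches: int = DEFAULT_MAX_TARGET_MISMATCHES
    species_prefix: str = "vun"

    def search_params(self) -> SearchParams:
        return SearchParams(self.word_size, self.max_mismatches,
                            self.min_match_length, self.both_strands)

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            max_substitutions=self.max_mismatches,
            max_star_mismatches=self.max_star_mismatches,
            loop_break_min=self.loop_break_min,
            mfei_threshold=self.mfei_threshold,
            au_min=self.au_min, au_max=self.au_max,
            wobble_is_match=self.wobble_is_match)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls(**(yaml.safe_load(text) or {}))


@dataclass
class PipelineResult:
    hits: list[MatureHit] = field(default_factory=list)
    candidates: list[PrecursorCandidate] = field(default_factory=list)
    evaluations: list[HairpinEvaluation] = field(default_factory=list)
    accepted: list[HairpinEvaluation] = field(default_factory=list)
    target_sites: list[TargetSite] = field(default_factory=list)
    family_counts: Counter = field(default_factory=Counter)
    rejection_log: list[str] = field(default_factory=list)
    dropped_coding: int = 0

    def table_tsv(self, sources: dict[str, str] | None = None) -> str:
        sources = sources or {}
        lines = ["\t".join(REPORT_COLUMNS)]
        for ev in self.accepted:
            src = sources.get(ev.candidate.hit.subject_id, "UNKNOWN")
            lines.append("\t".join(report_row(ev, src)))
        return "\n".join(lines) + "\n"

    def targets_tsv(self) -> str:
        lines = ["mirna\ttranscript_id\tmismatches\tsite_class\tstart\tend\tenergy"]
        for s in self.target_sites:
            lines.append(f"{s.mirna_id}\t{s.transcript_id}\t({s.mismatch_count})\t"
                         f"{SITE_CLASS_LABEL[s.site_class]}\t{s.site_start}\t"
                         f"{s.site_end}\t{s.duplex_energy_kcal_mol:.2f}")
        return "\n".join(lines) + "\n"

    def family_tsv(self) -> str:
        lines = ["family\tcount"]
        for fam in sorted(self.family_counts):
            lines.append(f"MIR{fam}\t{self.family_counts[fam]}")
        return "\n".join(lines) + "\n"


def run_pipeline(known: list[SequenceRecord], db: list[SequenceRecord],
                 transcripts: list[SequenceRecord] | None = None,
                 config: PipelineConfig | None = None,
                 log=None) -> PipelineResult:
    """Run the full homology screen over a database of EST/GSS records.

    ``known`` is the reference set of mature miRNAs, ``db`` the sequences to
    mine, ``transcripts`` an optional set to scan for targets of accepted
    miRNAs.  Raises with the stage name and offending record id on failure.
    """
    config = config or PipelineConfig()
    result = PipelineResult()
    subjects = {r.seq_id: r for r in db}

    result.hits = search_all(known, db, config.search_params())

    fcfg = config.filter_config()
    for hit in result.hits:
        try:
            cand = excise_window(hit, subjects[hit.subject_id], config.flank)
            if config.coding_screen_enabled and \
                    not any(c not in "ACGU" for c in cand.window_seq) and \
                    coding_screen(cand, config.min_orf_aa) == "drop_coding":
                result.dropped_coding += 1
                result.rejection_log.append(
                    f"{hit.subject_id}:{hit.subject_start}-{hit.subject_end}"
                    f"({hit.query_id})\tcoding_screen")
                continue
            result.candidates.append(cand)
            ev = evaluate_candidate(cand, fcfg)
        except Exception as exc:
            raise RuntimeError(
                f"stage fold/filter failed on {hit.subject_id} "
                f"(query {hit.query_id}): {exc}") from exc
        result.evaluations.append(ev)
        if not ev.accepted:
            result.rejection_log.append(
                f"{hit.subject_id}:{hit.subject_start}-{hit.subject_end}"
                f"({hit.query_id})\t" + ",".join(ev.rejection_reasons))

    # collapse identical loci matched by several known miRNAs: keep the
    # best-matching known (fewest substitutions); distinct mature windows
    # from one precursor stay distinct entries
    best: dict[tuple[str, str, int, int], HairpinEvaluation] = {}
    for ev in result.evaluations:
        if not ev.accepted:
            continue
        h = ev.candidate.hit
        key = (h.subject_id, h.strand, h.subject_start, h.subject_end)
        prev = best.get(key)
        if prev is None or ev.nm_subst < prev.nm_subst:
            best[key] = ev
    result.accepted = sorted(
        best.values(),
        key=lambda e: (parse_family(e.candidate.hit.query_id),
                       e.candidate.hit.subject_id,
                       e.candidate.hit.subject_start,
                       -(e.lm_nt or 0)))
    if result.accepted:
        name_mirnas(result.accepted, config.species_prefix)
        result.family_counts = Counter(
            parse_family(ev.candidate.hit.query_id) for ev in result.accepted)

    if transcripts and result.accepted:
        for ev in result.accepted:
            mir = SequenceRecord(ev.name or ev.candidate.hit.query_id,
                                 ev.candidate.hit.aligned_subject)
            result.target_sites.extend(scan_targets(
                mir, transcripts,
                max_mismatches=config.max_target_mismatches,
                energy_threshold=config.energy_threshold,
                wobble_is_match=config.wobble_is_match))
    if log is not None:
        print(f"pipeline: {len(result.hits)} hits, {result.dropped_coding} dropped "
              f"as coding, {len(result.accepted)} accepted in "
              f"{len(result.family_counts)} families, "
              f"{len(result.target_sites)} target sites", file=log)
    return result


def family_tree(precursors: list[SequenceRecord]) -> str:
    """Newick NJ tree over a family's precursor sequences (>= 3 members)."""
    return neighbor_joining(distance_matrix(precursors))
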