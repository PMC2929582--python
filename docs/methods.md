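# Methods

This note records the models, conventions and design choices behind
`mirminer`, in the order the pipeline applies them.

## Homology search

The search is a deterministic replacement for a permissive BLASTN pass.
Every subject is indexed by exact words (default `word_size = 7`) on both
strands; each query/subject diagonal sharing at least one word is scored
exhaustively. On a diagonal, the reported match is the *longest* window of
at least `min_match_length` (16) nt containing an exact word-length run of
matches and at most `max_mismatches` (3) substitutions; ties resolve to
fewer mismatches, then the smaller start. Matches are ungapped by design:
plant mature homologs differ by substitutions, and the downstream
substitution count (NM) is only well defined on an ungapped alignment.
Preferring the longest window over the fewest-mismatch window matters:
a full-length mature with two substitutions is reported as a 20-nt, NM = 2
match rather than a shorter zero-mismatch core, which is how annotation
tables in this field report NM.

There is no E-value: the scan enumerates every seeded diagonal, so it is
strictly more sensitive than a heuristic aligner at a permissive cutoff,
and specificity is delegated to the structural screen. The cost of that
choice is more candidate windows to fold, which is acceptable at EST-
collection scale.

Both strands are scanned by default (`scan_reverse_strand`); genomic
survey reads carry miRNAs on either strand, and for expressed sequence
input the flag can be turned off.

## Precursor excision and the coding screen

Windows take `flank = 200` nt on each side of the hit, clipped to the
record (`truncated` marks clipping); when the record is shorter the entire
sequence is used. Minus-strand windows are reverse-complemented so the
mature always reads 5′→3′. Coordinates are 1-based inclusive throughout.

The coding screen is a local six-frame heuristic, deliberately standing in
for a remote protein-database search: a window is dropped when any of the
six reading frames contains a *complete* open reading frame — start codon
to an in-frame stop codon actually present in the window — of at least
`min_orf_aa = 80` codons overlapping the mature site. Reading frames that
run off the window without reaching a stop are not counted here (for
transcript site classification, below, they are, since ESTs are partial
cDNAs). The screen has an off switch, and the CLI warns that it is not a
protein-database search. By chance, a random ~350-nt window contains a
qualifying ORF over the mature a few percent of the time; this false-drop
rate is the dominant loss mode of the pipeline on synthetic data (see
"What the fixtures show" below).

## The energy model

Folding and duplex scoring share one simplified Turner-style
nearest-neighbor model at 37 °C, stored in versioned TSV files
(`data/stack_energies.tsv`, `data/loop_params.tsv`):

- a 6×6 stacking table over A-U, U-A, C-G, G-C, G-U, U-G (kcal/mol,
  satisfying the thermodynamic symmetry ΔG(XY/WZ) = ΔG(ZW/YX));
- hairpin, bulge and internal-loop initiation penalties indexed by loop
  size, extrapolated beyond the tables as
  ΔG(n) = ΔG(n_max) + 1.08 · ln(n / n_max);
- an affine multiloop term (closing 3.4, per-branch 0.4, per-unpaired 0.0
  kcal/mol);
- hairpin loops of at least 3 nt; only the six canonical pairs; no
  pseudoknots, dangles, coaxial stacking or terminal-pair corrections.

The model is intentionally compact. Published hairpin statistics (MFE,
MFEI) were historically computed with mfold, whose exact energies are not
reproducible without replicating its full parameter set; instead,
correctness here is defined against the model itself — an exhaustive
enumeration oracle — and the screening thresholds operate at the level
where model differences do not change verdicts (a genuine pre-miRNA
hairpin sits far above MFEI 0.85 under any reasonable parameterization,
see the worked example's values of 1.6–1.9).

## MFE folding

`fold_mfe` is a Zuker-style dynamic program (numba-compiled) over the
model: `V[i,j]` (best structure closed by pair i,j), `WM[i,j]` (multiloop
content with ≥ 1 branch) and an exterior array `W`. Bulge/internal loops
are capped at 30 unpaired nt, the usual search restriction. Input length
is limited to 10–1000 nt and must be unambiguous; ambiguous records are
excluded from folding rather than guessed at.

The returned energy always equals the loop-decomposition energy of the
returned structure (checked to 1e-6 in the suite), and on sequences short
enough to enumerate (≤ 25 nt) the DP energy equals the exhaustive minimum
exactly. Traceback is deterministic: on exact ties it prefers unpaired
exterior bases (fewer pairs), then the smallest admissible loop, then the
leftmost split, so re-runs are byte-identical.

## Hairpin geometry, arm and miRNA*

The terminal loop of the longest stem-loop defines the 5′/3′ axis. For a
given mature span, the arm call uses a **strict majority** of its paired
bases: the mature is on the 5′ (3′) arm when more than half of its paired
bases lie 5′ (3′) of the terminal loop with partners on the far side. An
all-partners rule was rejected deliberately — in realistic folds one or
two terminal mature bases routinely pair into the flanking sequence, and
that must not disqualify an otherwise clean hairpin; those stray positions
still count as mature/miRNA* mismatches downstream.

The miRNA* span is the dominant coherent antiparallel block of partner
positions (consecutive partner jumps above ~10 nt split blocks, so one
stray long-range pair cannot stretch the star across unrelated helices),
extended by the 2-nt 3′ overhang of Dicer products. Star quality is then:

- *mismatches* (criterion 4): mature positions unpaired or paired outside
  the star span — fails at ≥ 6. G:U wobble counts as paired by default
  (`wobble_is_match`), since it is a bona fide structural pair; a flag
  counts it as a mismatch instead.
- *loop or break* (criterion 5): the star core (overhang excluded)
  contains a run of ≥ `loop_break_min = 3` unpaired bases, or a base
  paired away from the mature entirely. The run length is configurable
  because "no loop or break" has no agreed numeric form.

## The reported precursor (LP) and MFEI

The reported precursor is the excised window trimmed to the outermost pair
of the helix chain enclosing the mature's stem-loop, walking outward
through stacks, bulges and internal loops but stopping at any junction
with more than `trim_max_gap = 4` unpaired nt (and at multiloops), then
extended to cover the mature and star if needed. Without the junction cap,
incidental flanking helices chain the "precursor" across the entire
window and dilute MFEI meaninglessly; 4 nt is a typical upper bound for
stem interruptions inside real pre-miRNAs. The trimmed precursor is
refolded, and AMFE = (|MFE| / LP) × 100 and MFEI = AMFE / GC% are computed
on it; MFEI uses |MFE| so the index is positive. The acceptance thresholds
are: MFEI strictly > 0.85, A+U fraction within [0.30, 0.70] inclusive.

## Naming

Accepted candidates inherit the family number of their best-matching known
miRNA; several known miRNAs matching one locus with identical coordinates
collapse to the fewest-substitution match, while distinct mature windows
from one precursor (different lengths or offsets) stay distinct entries.
Members are lettered a, b, c… in input encounter order (no letter for a
single-member family), so re-runs with the same input order give identical
names.

## Target prediction

An exhaustive antisense window walk: miRNA position k pairs with window
position L−1−k. A site is reported when fewer than 4 positions fail to
pair (wobble counting as a pair by default, with its weak stack energy)
and the bimolecular duplex energy is strictly below −28.2 kcal/mol. The
duplex energy is the initiation penalty (4.09 kcal/mol) plus
nearest-neighbor stacks over consecutive paired positions; each internal
mismatch run costs an opening penalty (1.0) plus 0.4 kcal/mol per unpaired
nucleotide on both strands; unpaired duplex ends are free. The model is
symmetric under strand swap and monotone: breaking a pair never lowers the
energy. Overlapping sites keep the lowest-energy representative; the
report is many-to-many across miRNAs and transcripts.

Site classes come from the longest forward-frame reading frame of the
transcript (AUG to stop, read-through allowed because ESTs are partial;
`min_orf_aa = 30`): fully 5′ of the start → 5′UTR, fully 3′ of the stop →
3′UTR, overlapping → ORF, no qualifying frame → unclassified.

## Precursor comparison

Within a family, precursors are compared by Needleman-Wunsch global
alignment (match +1, mismatch −1, gap −2); distance is 1 − identity over
alignment columns. The tree is standard neighbor joining on that matrix —
a transparent substitution for a multiple-alignment guide tree, consistent
(exactly) on additive matrices. Alignment uses Biopython's pairwise
aligner and NJ uses scikit-bio, behind this module's interface.

## The fixture generator

`simulate.plant_hairpin` builds exactly the signal the screen is designed
to detect: a known mature (optionally carrying 0–2 substitutions) opening
the 5′ arm of a perfect inverted repeat (stem = mature length + 4 pairs,
6-nt loop), embedded in i.i.d. background of 45% GC with 150-nt flanks —
EST-like reads of ~350 nt. Every record is a pure function of its seed.

What it emulates: a conserved mature, a thermodynamically dominant
stem-loop, A+U content in the screened range, and background that can form
incidental secondary structure and, occasionally, chance open reading
frames. What it does not emulate: sequencing error, chimeric reads,
imperfect miRNA/miRNA* duplexes (bulged stars), multi-hairpin polycistrons,
or real genomic base composition. Passing the planted-recovery and
negative-control suites therefore shows that the machinery is correct and
the thresholds behave as printed bounds — not that the thresholds'
biological sensitivity/specificity on real ESTs is reproduced, which would
require the original survey-scale data.

On these fixtures the pipeline recovers ≥ 95% of planted hairpins at
default thresholds across seeds (typically 96–100 of 100); the residual
losses are almost entirely chance complete ORFs over the mature triggering
the coding screen, plus rare substitution placements that destroy every
exact 7-mer seed in a 20-nt mature. Background-only negatives yield zero
accepted candidates.

## Problem sizes and numerics

The test and acceptance runs use sizes chosen to make brute-force oracles
exact and runs quick: enumeration oracles on 200–500 sequences of 10–25 nt
(every nested structure is enumerable there), homology oracles on 21-nt
queries against 80–200-nt subjects, 100 planted fixtures plus 100
negatives for the end-to-end rates, and 50 random additive 6-taxon
matrices for NJ. Energy comparisons use 1e-6 absolute tolerance (DP vs.
oracle summation order); traceback tie detection uses 1e-7. All
randomness is seeded; identical inputs and configuration produce
byte-identical reports.

## Known limitations

- Energies are model energies: comparable across candidates, not equal to
  mfold/ViennaRNA outputs; MFEI values for one sequence differ between
  parameterizations even though screen verdicts rarely do.
- The coding screen is a length heuristic with a measurable false-drop
  rate on random sequence and no protein-homology evidence.
- The precursor trimming convention (junction gap ≤ 4 nt) is one of
  several defensible definitions; published precursor lengths depend on an
  unstated convention and are not recomputed here.
- Gapped mature homologs (indels vs. the known miRNA) are invisible to the
  ungapped scan by design.
- NJ on pairwise identities is a coarse family summary, not a substitute
  for model-based phylogenetics.
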