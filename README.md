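# mirminer

Homology-based discovery of plant microRNAs in EST/GSS sequence
collections, with hairpin screening, target prediction, and precursor
phylogenetics.

## The problem

Plant mature miRNAs are short (~19–24 nt) and strongly conserved across
species, and their precursors fold into characteristic stem-loop hairpins.
For a species without a sequenced genome — the motivating case is cowpea,
*Vigna unguiculata* — new miRNAs can therefore be found by scanning its
Expressed Sequence Tags (ESTs) and Genomic Survey Sequences (GSSs) for
near-exact matches to known plant matures, and then asking whether the
surrounding sequence folds into a credible pre-miRNA hairpin.

`mirminer` implements that workflow end to end for researchers mining
transcript or survey-sequence collections:

1. **Homology search** — each known mature is matched against every
   subject (both strands) with a deterministic 7-mer-seeded ungapped scan;
   matches must cover ≥ 16 nt with < 4 substitutions.
2. **Precursor excision** — up to 200 nt of flank on each side of a hit is
   cut out (the whole record when shorter) and passed through a six-frame
   ORF screen that discards likely protein-coding windows.
3. **Folding** — each window is folded to its minimum-free-energy (MFE)
   nested secondary structure under a nearest-neighbor energy model.
4. **Hairpin screen** — a candidate is accepted only if (1) it forms a
   stem-loop, (2) the mature lies on one arm, (3) it has ≤ 3 substitutions
   vs. the known mature, (4) < 6 of its bases are unpaired against the
   miRNA\* region, (5) the miRNA\* carries no loop or break, and (6) the
   minimal folding free energy index exceeds 0.85, with A+U content within
   30–70%. Here

       AMFE = (|MFE| / precursor length) × 100,    MFEI = AMFE / GC%,

   the standard index separating miRNA hairpins from other RNAs.
5. **Naming** — accepted candidates are named `{prefix}-MIR{family}{letter}`
   with the family inherited from the best-matching known miRNA.
6. **Targets** — transcripts are scanned for antisense sites with < 4
   mismatches and duplex free energy below −28.2 kcal/mol, each site
   classified as 5′UTR / ORF / 3′UTR against the longest reading frame.
7. **Phylogenetics** — precursors of one family are compared by global
   alignment identity and summarised as a neighbor-joining tree.

The package ships the 47-entry cowpea miRNA annotation table (13 families)
as a reference dataset, and a seeded generator of EST-like fixtures with
planted hairpins so the full pipeline is testable without any downloads.

## Worked example

Generate a small synthetic EST set with four planted hairpins (two known
matures, 0–2 substitutions each) plus background records, then run the
screen:

```sh
python - <<'EOF'
from mirminer import simulate
from mirminer.seqio import write_fasta, SequenceRecord
known = [SequenceRecord("ath-miR156a", "UGACAGAAGAGAGUGAGCAC"),
         SequenceRecord("ath-miR399a", "UGCCAAAGGAGAUUUGCCCUG")]
write_fasta(known, "known.fa")
records, _ = simulate.planted_collection(
    [k.residues for k in known], n_each=2, n_background=2, seed=11)
write_fasta(records, "ests.fa")
EOF
printf 'both_strands: false\n' > config.yaml
mirminer filter known.fa ests.fa --config config.yaml
```

which prints:

```
name	gene_id	source	sequence	nm	lm	lp	location	au_fraction	mfei
vun-MIR156a	synthEST_0	UNKNOWN	UGACAGAAGAGAGUGAGCAC	0	20	56	5	0.59	1.90
vun-MIR156b	synthEST_1	UNKNOWN	UGCCAGAAGAGAGUGAGCAC	1	20	60	5	0.48	1.59
vun-MIR399a	synthEST_2	UNKNOWN	UGCCAAAGGAGAUUUGUCUUG	2	21	82	5	0.60	1.66
vun-MIR399b	synthEST_3	UNKNOWN	UGCCAAAGGAGAUUUGCCCUG	0	21	58	5	0.48	1.72
```

Each row is one accepted miRNA: `nm` substitutions against the known
mature, mature length `lm`, trimmed precursor length `lp`, the hairpin arm
carrying the mature (`5` or `3`), and the precursor's A+U fraction and
MFEI — every accepted row necessarily has `nm ≤ 3`, A+U in [0.30, 0.70]
and MFEI > 0.85. The planted matures are recovered with exactly the
substitution counts the generator introduced (0, 1, 2, 0), and the two
background-only records yield nothing.

Folding is available directly as a library call:

```python
>>> from mirminer import fold_mfe
>>> s = fold_mfe("GGGGCUUCGGCCCC")
>>> s.dotbracket, round(s.mfe_kcal_mol, 2)
('(((((....)))))', -7.6)
```

Other subcommands: `mirminer search` (hit TSV), `excise` (precursor FASTA),
`fold` (dot-bracket), `targets` (binding-site TSV), `tree` (newick),
`all` (full pipeline with reports), `simulate` (fixtures).

## Layout

- `src/mirminer/seqio.py` — FASTA I/O, RNA alphabet, composition utilities
- `src/mirminer/homology.py` — seeded ungapped mature-miRNA search
- `src/mirminer/precursor.py` — window excision and the coding screen
- `src/mirminer/energy.py`, `folding.py`, `_kernel.py` — nearest-neighbor
  energy model and MFE folding (parameters in `data/*.tsv`)
- `src/mirminer/filtering.py` — the six-criteria screen, statistics, naming
- `src/mirminer/targets.py` — target scanning and duplex energies
- `src/mirminer/phylo.py` — pairwise identities and NJ trees
- `src/mirminer/simulate.py`, `datasets.py` — fixture generator and the
  packaged reference table
- `src/mirminer/pipeline.py`, `cli.py` — orchestration and the CLI

See `docs/methods.md` for the model details, parameter choices, and known
limitations.
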