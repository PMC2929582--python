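"""Packaged reference dataset: the 47 cowpea (Vigna unguiculata) miRNAs.

The table carries, for each predicted miRNA, its GenBank source id and type
(EST or GSS), the mature sequence, the number of substitutions against the
best-matching known plant miRNA (NM), mature and precursor lengths (LM,
LP), the hairpin arm carrying the mature (5 or 3), and the precursor's A+U
fraction and MFEI.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .filtering import parse_family
from .seqio import SequenceRecord, SourceTag


def load_table1() -> pd.DataFrame:
    """The full 47-row annotation table as a DataFrame."""
    path = resources.files("mirminer.data").joinpath("vigna_table1.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", dtype={"gene_id": str})
    return df


def table1_fixture() -> list[SequenceRecord]:
    """The 47 mature miRNA sequences as records named vun-MIR156a..vun-MIR2118."""
    df = load_table1()
    return [
        SequenceRecord(row.name_, row.sequence, f"gene_id={row.gene_id}",
                       SourceTag(row.source))
        for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def table1_families() -> dict[str, int]:
    """Map each packaged miRNA name to its family number."""
    return {rec.seq_id: parse_family(rec.seq_id) for rec in table1_fixture()}
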