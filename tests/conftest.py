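from __future__ import annotations

import random

import pytest

from mirminer.seqio import SequenceRecord


@pytest.fixture()
def rng():
    return random.Random(20260928)


@pytest.fixture(scope="session")
def known_matures():
    """A small reference set of real plant mature miRNAs (two families)."""
    return [
        SequenceRecord("ath-miR156a", "UGACAGAAGAGAGUGAGCAC"),
        SequenceRecord("ath-miR172a", "AGAAUCUUGAUGAUGCUGCAU"),
    ]


@pytest.fixture()
def fasta_file(tmp_path):
    def write(records, name="seqs.fa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rec_id, seq in records:
                fh.write(f">{rec_id}\n{seq}\n")
        return path
    return write
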