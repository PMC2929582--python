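"""Synthetic EST/GSS fixtures: planted miRNA hairpins in random backgrounds.

The generator emulates exactly the signal the screen is built to detect: a
conserved mature sequence (optionally carrying substitutions) on the 5' arm
of a thermodynamically strong stem-loop, embedded in i.i.d. background of
configurable GC content.  Every record is a pure function of its seed, so
fixtures are byte-identical across runs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .seqio import SequenceRecord, SourceTag, reverse_complement

DEFAULT_LOOP_NT = 6
DEFAULT_FLANK_NT = 150
DEFAULT_GC = 0.45


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for one EST-like sequence with a planted miRNA hairpin."""

    known_mature: str
    n_substitutions: int = 0
    stem_pairs: int | None = None      # default: mature length + 4
    loop_nt: int = DEFAULT_LOOP_NT
    flank_nt: int = DEFAULT_FLANK_NT
    gc_background: float = DEFAULT_GC
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loop_nt < 3:
            raise ValueError("hairpin loop must be at least 3 nt")
        stem = self.effective_stem_pairs
        if stem < 0.7 * len(self.known_mature):
            raise ValueError("stem must cover at least 70% of the mature length")
        if not 0.0 < self.gc_background < 1.0:
            raise ValueError("gc_background must be in (0, 1)")

    @property
    def effective_stem_pairs(self) -> int:
        return self.stem_pairs if self.stem_pairs is not None \
            else len(self.known_mature) + 4


@dataclass(frozen=True)
class PlantTruth:
    """Ground truth for one planted hairpin, 1-based coordinates."""

    mature_seq: str
    mature_start: int
    mature_end: int
    hairpin_start: int
    hairpin_end: int
    arm: str
    n_substitutions: int


def _random_rna(rng: random.Random, length: int, gc: float) -> str:
    out = []
    for _ in range(length):
        if rng.random() < gc:
            out.append(rng.choice("GC"))
        else:
            out.append(rng.choice("AU"))
    return "".join(out)


def _mutate(seq: str, n: int, rng: random.Random) -> str:
    if n > len(seq):
        raise ValueError("more substitutions than positions")
    positions = rng.sample(range(len(seq)), n)
    chars = list(seq)
    for p in positions:
        chars[p] = rng.choice([b for b in "ACGU" if b != chars[p]])
    return "".join(chars)


def plant_hairpin(spec: PlantSpec, seq_id: str | None = None
                  ) -> tuple[SequenceRecord, PlantTruth]:
    """Build one planted-hairpin record plus its truth annotation.

    The mature (after substitutions) starts the 5' arm; the 3' arm is its
    perfect reverse complement, so the duplex is clean and the stem energy
    dominates any background pairing.
    """
    rng = random.Random(spec.seed)
    mature = _mutate(spec.known_mature, spec.n_substitutions, rng)
    stem = spec.effective_stem_pairs
    arm5 = mature + _random_rna(rng, stem - len(mature), 0.55)
    loop = _random_rna(rng, spec.loop_nt, 0.2)
    hairpin = arm5 + loop + reverse_complement(arm5)
    flank5 = _random_rna(rng, spec.flank_nt, spec.gc_background)
    flank3 = _random_rna(rng, spec.flank_nt, spec.gc_background)
    residues = flank5 + hairpin + flank3
    rec = SequenceRecord(
        seq_id or f"synthEST_{spec.seed}", residues,
        "synthetic EST with planted hairpin", SourceTag.EST)
    truth = PlantTruth(
        mature_seq=mature,
        mature_start=spec.flank_nt + 1,
        mature_end=spec.flank_nt + len(mature),
        hairpin_start=spec.flank_nt + 1,
        hairpin_end=spec.flank_nt + len(hairpin),
        arm="5",
        n_substitutions=spec.n_substitutions,
    )
    return rec, truth


def background_record(length: int = 350, gc: float = DEFAULT_GC, seed: int = 0,
                      seq_id: str | None = None) -> SequenceRecord:
    """A background-only EST-like record (negative control)."""
    rng = random.Random(seed)
    return SequenceRecord(
        seq_id or f"synthBG_{seed}", _random_rna(rng, length, gc),
        "synthetic background EST", SourceTag.EST)


def planted_collection(known_matures: list[str], n_each: int = 1,
                       n_background: int = 0, seed: int = 0,
                       max_substitutions: int = 2,
                       **spec_kwargs) -> tuple[list[SequenceRecord], list[PlantTruth]]:
    """A mixed EST set: planted hairpins (rotating substitution counts
    0..max_substitutions) plus background-only records."""
    records, truths = [], []
    k = 0
    for mature in known_matures:
        for rep in range(n_each):
            spec = PlantSpec(known_mature=mature,
                             n_substitutions=k % (max_substitutions + 1),
                             seed=seed * 100003 + k, **spec_kwargs)
            rec, truth = plant_hairpin(spec, seq_id=f"synthEST_{k}")
            records.append(rec)
            truths.append(truth)
            k += 1
    for b in range(n_background):
        records.append(background_record(seed=seed * 100003 + k + b,
                                         seq_id=f"synthBG_{b}"))
    return records, truths
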