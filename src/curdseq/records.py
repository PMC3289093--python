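"""Core record types shared across the pipeline.

All coordinates are 0-based half-open on the forward strand of the
reference (transcript, unigene or contaminant) they refer to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    """A short sequencing read with per-base phred+33 qualities."""

    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quality)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ESTRecord:
    """A Sanger-style expressed sequence tag (no per-base qualities)."""

    est_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FastaRecord:
    """A plain identified DNA sequence (transcripts, contaminants, references)."""

    seq_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Unigene:
    """An assembled non-redundant transcript fragment.

    ``provenance`` records which arm of the hybrid assembly produced it:
    ``est`` (EST overlap assembly), ``denovo`` (short-read de Bruijn
    assembly) or ``merged`` (meta-assembly of the two).
    """

    unigene_id: str
    sequence: str
    provenance: str = "est"

    def __post_init__(self) -> None:
        if self.provenance not in ("est", "denovo", "merged"):
            raise ValueError(f"invalid provenance {self.provenance!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlignmentHit:
    """Best placement of a read on a unigene set.

    ``placements`` lists every equally-best ``(unigene_id, start, strand)``
    placement (fewest mismatches); the multimapping policy downstream
    decides what to do when there is more than one.
    """

    read_id: str
    placements: list = field(default_factory=list)
    mismatches: int = 0

    @property
    def unigene_id(self) -> str:
        return self.placements[0][0]

    @property
    def start(self) -> int:
        return self.placements[0][1]

    @property
    def strand(self) -> str:
        return self.placements[0][2]

    @property
    def n_best(self) -> int:
        return len(self.placements)


def format_unigene_id(index: int) -> str:
    """Unigene identifiers are 'PP' followed by six zero-padded digits."""
    if not 0 <= index <= 999_999:
        raise ValueError(f"unigene index {index} out of PP-id range")
    return f"PP{index:06d}"
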