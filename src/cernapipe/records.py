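"""Sequence records and FASTA I/O for miRNAs, 3'UTRs and circRNAs.

All sequences are stored 5'->3' over the RNA alphabet {A, C, G, U};
DNA input (T) is normalized to U on read.  The miRNA seed is defined as
nucleotides 2-7 (1-based from the 5' end), and the seed string doubles
as the family identifier: miRNAs sharing a seed belong to one family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: Watson-Crick pairs (target base, miRNA base)
WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")})
#: G:U wobble pairs
GU_PAIRS = frozenset({("G", "U"), ("U", "G")})


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,U}."""


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T to U; validate the alphabet."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise AlphabetError(f"invalid RNA characters: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string (U<->A, G<->C)."""
    return seq.translate(_COMPLEMENT)[::-1]


def pair_class(target_base: str, mir_base: str) -> str:
    """Classify a base apposition as 'WC', 'GU' or 'mismatch'."""
    p = (target_base, mir_base)
    if p in WC_PAIRS:
        return "WC"
    if p in GU_PAIRS:
        return "GU"
    return "mismatch"


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA.  ``seed`` (positions 2-7) identifies the family."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if not 18 <= len(self.sequence) <= 26:
            raise ValueError(
                f"{self.name}: mature miRNA length must be 18-26 nt, "
                f"got {len(self.sequence)}"
            )

    @property
    def seed(self) -> str:
        return self.sequence[1:7]

    @property
    def family(self) -> str:
        return self.seed

    def seed_match(self, extended: bool = False) -> str:
        """Target-side complement of the seed.

        ``extended=True`` returns the 7-nt match to positions 2-8 (the
        core of 8mer and 7mer-m8 sites); otherwise the 6-nt match to
        positions 2-7.
        """
        end = 8 if extended else 7
        return revcomp(self.sequence[1:end])


@dataclass(frozen=True)
class UTRSequence:
    """A 3'UTR attributed to a gene (one transcript)."""

    gene_id: str
    sequence: str
    transcript_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if not self.sequence:
            raise ValueError(f"{self.gene_id}: empty UTR sequence")


@dataclass(frozen=True)
class CircSequence:
    """A circRNA: the mature back-spliced circle, linearized at the junction.

    Coordinates on the circle are modular; position 0 is the (arbitrary)
    linearization point immediately downstream of the backsplice junction.
    """

    circ_id: str
    host_gene: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if not self.sequence:
            raise ValueError(f"{self.circ_id}: empty circRNA sequence")


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: RNA sequence} mapping."""
    return {
        rec.id: normalize_rna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA, preserving order."""
    seqrecs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_mirnas(path: str | Path) -> list[MiRNA]:
    return [MiRNA(name, seq) for name, seq in read_fasta(path).items()]


def read_utrs(path: str | Path) -> list[UTRSequence]:
    """Read UTRs; header ``gene`` or ``gene|transcript``."""
    utrs = []
    for name, seq in read_fasta(path).items():
        gene, _, tx = name.partition("|")
        utrs.append(UTRSequence(gene, seq, transcript_id=tx))
    return utrs


def read_circs(path: str | Path, circ_to_gene: dict[str, str]) -> list[CircSequence]:
    """Read circRNAs, resolving host genes through ``circ_to_gene``."""
    circs = []
    for name, seq in read_fasta(path).items():
        if name not in circ_to_gene:
            raise KeyError(f"circRNA {name} missing from circ->gene map")
        circs.append(CircSequence(name, circ_to_gene[name], seq))
    return circs
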