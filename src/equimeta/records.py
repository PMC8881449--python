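"""Shared record types flowing between pipeline stages.

These are deliberately plain dataclasses: every stage exchanges either these
records or pandas DataFrames, and all of them round-trip through standard
text formats (FASTA/FASTQ/TSV/JSON) so external tools can be substituted at
any stage boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class GenomeRecord:
    """A reference replicon with the metadata the curation step consumes.

    ``replicon`` distinguishes chromosome, plasmid and unresolved contig
    records; plasmids carry the accession of their host chromosome in
    ``parent``.
    """

    accession: str
    species: str
    genus: str
    sequence: str
    completeness: str = "complete"  # complete | draft
    replicon: str = "chromosome"    # chromosome | plasmid | contig
    parent: str | None = None
    kingdom: str = "bacteria"

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        if not self.sequence:
            return 0.0
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s)

    @property
    def named(self) -> bool:
        """False for placeholder binomials such as ``Genus sp. 3``."""
        return " sp." not in self.species

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"genome {self.accession}: empty sequence")


@dataclass
class ReadRecord:
    """One sequencing read with Phred qualities (Phred+33 on disk)."""

    read_id: str
    sequence: str
    qualities: list[int]
    mate: str = "R1"  # R1 | R2

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence/quality length mismatch"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadPair:
    r1: ReadRecord
    r2: ReadRecord

    @property
    def pair_id(self) -> str:
        return self.r1.read_id

    def __post_init__(self) -> None:
        if self.r1.read_id != self.r2.read_id:
            raise ValueError(
                f"mate id mismatch: {self.r1.read_id} vs {self.r2.read_id}"
            )


@dataclass
class AlignmentHit:
    """A read-to-target assignment; the common currency of all profilers."""

    read_id: str
    target_id: str
    score: float
    evalue: float
    identity: float
    target_kind: str = "genome"  # genome | arg_gene | cazy_gene | host


@dataclass
class ARGene:
    """Antimicrobial-resistance gene with its phenotype (drug-class) label."""

    gene_id: str
    phenotype: str
    mechanism: str
    sequence: str


@dataclass
class CAZyGene:
    """Carbohydrate-active enzyme gene: family label plus protein length."""

    gene_id: str
    family: str
    sequence: str  # amino acids

    @property
    def length_aa(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        import re

        if not re.fullmatch(r"(GH|GT|PL|CE|AA|CBM)\d+", self.family):
            raise ValueError(f"malformed CAZy family label: {self.family!r}")
        if self.length_aa < 1:
            raise ValueError(f"gene {self.gene_id}: empty sequence")


@dataclass
class SpikedGene:
    """Ground-truth record of a gene embedded in a synthetic genome."""

    gene_id: str
    accession: str
    start: int
    end: int
    catalog: str  # ARG | CAZy


@dataclass
class InteractionEdge:
    """One resistome-network edge: phenotype x genome within a cohort.

    ``weight`` is the cohort-mean frequency of read pairs co-assigned to
    both the phenotype and the genome.
    """

    phenotype: str
    genome_node: str
    replicon: str
    cohort: str
    weight: float
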