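"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: FASTA/FASTQ via Biopython, tables as TSV via
pandas, ground truth as JSON. Quality encoding is fixed to Phred+33.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import ARGene, CAZyGene, GenomeRecord, ReadPair, ReadRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_paired_fastq",
    "write_paired_fastq",
    "read_genomes",
    "write_genomes",
    "read_arg_catalog",
    "write_arg_catalog",
    "read_cazy_catalog",
    "write_cazy_catalog",
    "read_design",
    "write_design",
    "read_truth",
    "write_truth",
]


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTA/FASTQ


def read_fasta(path) -> dict[str, str]:
    with _open(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with _open(path, "wt") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_fastq(path) -> list[ReadRecord]:
    reads = []
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            reads.append(
                ReadRecord(
                    read_id=rec.id.rsplit("/", 1)[0],
                    sequence=str(rec.seq),
                    qualities=list(rec.letter_annotations["phred_quality"]),
                    mate="R2" if rec.id.endswith("/2") else "R1",
                )
            )
    return reads


def write_fastq(path, reads: Iterable[ReadRecord]) -> None:
    with _open(path, "wt") as fh:
        for r in reads:
            suffix = "/1" if r.mate == "R1" else "/2"
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}{suffix}\n{r.sequence}\n+\n{qual}\n")


def read_paired_fastq(path1, path2) -> list[ReadPair]:
    r1s = read_fastq(path1)
    r2s = read_fastq(path2)
    if len(r1s) != len(r2s):
        raise ValueError(f"unequal pair counts: {len(r1s)} vs {len(r2s)}")
    return [ReadPair(a, b) for a, b in zip(r1s, r2s)]


def write_paired_fastq(path1, path2, pairs: Iterable[ReadPair]) -> None:
    pairs = list(pairs)
    write_fastq(path1, (p.r1 for p in pairs))
    write_fastq(path2, (p.r2 for p in pairs))


# -------------------------------------------------------------------- genomes


def write_genomes(fasta_path, meta_path, genomes: Iterable[GenomeRecord]) -> None:
    genomes = list(genomes)
    write_fasta(fasta_path, {g.accession: g.sequence for g in genomes})
    pd.DataFrame(
        {
            "accession": [g.accession for g in genomes],
            "species": [g.species for g in genomes],
            "genus": [g.genus for g in genomes],
            "kingdom": [g.kingdom for g in genomes],
            "completeness": [g.completeness for g in genomes],
            "replicon": [g.replicon for g in genomes],
            "parent": [g.parent or "" for g in genomes],
        }
    ).to_csv(meta_path, sep="\t", index=False)


def read_genomes(fasta_path, meta_path) -> list[GenomeRecord]:
    seqs = read_fasta(fasta_path)
    meta = pd.read_csv(meta_path, sep="\t", keep_default_na=False)
    genomes = []
    for row in meta.itertuples():
        if row.accession not in seqs:
            raise ValueError(f"metadata accession {row.accession} missing from FASTA")
        genomes.append(
            GenomeRecord(
                accession=row.accession,
                species=row.species,
                genus=row.genus,
                sequence=seqs[row.accession],
                completeness=row.completeness,
                replicon=row.replicon,
                parent=row.parent or None,
                kingdom=getattr(row, "kingdom", "bacteria"),
            )
        )
    return genomes


# ----------------------------------------------------------------- catalogs


def write_arg_catalog(fasta_path, meta_path, genes: Iterable[ARGene]) -> None:
    genes = list(genes)
    write_fasta(fasta_path, {g.gene_id: g.sequence for g in genes})
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "phenotype": [g.phenotype for g in genes],
            "mechanism": [g.mechanism for g in genes],
        }
    ).to_csv(meta_path, sep="\t", index=False)


def read_arg_catalog(fasta_path, meta_path) -> list[ARGene]:
    seqs = read_fasta(fasta_path)
    meta = pd.read_csv(meta_path, sep="\t", keep_default_na=False)
    return [
        ARGene(row.gene_id, row.phenotype, row.mechanism, seqs[row.gene_id])
        for row in meta.itertuples()
    ]


def write_cazy_catalog(fasta_path, meta_path, genes: Iterable[CAZyGene]) -> None:
    genes = list(genes)
    write_fasta(fasta_path, {g.gene_id: g.sequence for g in genes})
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "family": [g.family for g in genes],
            "length_aa": [g.length_aa for g in genes],
        }
    ).to_csv(meta_path, sep="\t", index=False)


def read_cazy_catalog(fasta_path, meta_path) -> list[CAZyGene]:
    seqs = read_fasta(fasta_path)
    meta = pd.read_csv(meta_path, sep="\t", keep_default_na=False)
    return [CAZyGene(row.gene_id, row.family, seqs[row.gene_id]) for row in meta.itertuples()]


# -------------------------------------------------------------- design/truth


def write_design(path, design: pd.DataFrame) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "site", "habitat"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    if design["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in design table")
    return design


def write_truth(path, truth: dict) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
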