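"""Plain-text interchange: FASTA for ORFs, TSV for tables, CSV for results.

The writers and readers round-trip the synthetic generator's output
bit-identically, and also accept externally supplied files in real-data
mode: coding sequences as nucleotide FASTA (length divisible by 3; a
terminal stop codon is trimmed), a codon decoding-time table as a two-column
TSV, and per-gene mRNA levels / ribosome densities as TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic_genome import CodonDecodingTable, GeneRecord, Genome

__all__ = [
    "write_orfs_fasta",
    "read_orfs_fasta",
    "write_gene_table",
    "read_gene_table",
    "write_codon_table",
    "read_codon_table",
    "read_genome",
]

log = logging.getLogger(__name__)

_STOPS = {"TAA", "TAG", "TGA"}
PathLike = Union[str, Path]


def write_orfs_fasta(genome_or_genes, path: PathLike) -> None:
    genes = genome_or_genes.genes if isinstance(genome_or_genes, Genome) else list(genome_or_genes)
    records = [
        SeqRecord(Seq("".join(g.orf)), id=g.gene_id, description="")
        for g in genes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_orfs_fasta(path: PathLike) -> dict[str, list[str]]:
    """ORFs as codon lists, keyed by record id.  A trailing stop codon is
    trimmed (and logged); an internal stop or a length not divisible by 3
    is an error."""
    orfs: dict[str, list[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if len(seq) % 3:
            raise ValueError(f"{rec.id}: CDS length {len(seq)} not divisible by 3")
        codons = [seq[i: i + 3] for i in range(0, len(seq), 3)]
        if codons and codons[-1] in _STOPS:
            log.info("trimming stop codon from %s", rec.id)
            codons = codons[:-1]
        inside = [c for c in codons if c in _STOPS]
        if inside:
            raise ValueError(f"{rec.id}: internal stop codon(s) {inside}")
        orfs[rec.id] = codons
    return orfs


def write_gene_table(genome_or_genes, path: PathLike) -> None:
    genes = genome_or_genes.genes if isinstance(genome_or_genes, Genome) else list(genome_or_genes)
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "mrna_level": [repr(g.mrna_level) for g in genes],
            "initiation_rate": [repr(g.initiation_rate) for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"gene_id", "mrna_level", "initiation_rate"}
    if not required <= set(df.columns):
        raise ValueError(f"gene table must have columns {sorted(required)}")
    return df


def write_codon_table(table: CodonDecodingTable, path: PathLike) -> None:
    df = pd.DataFrame(
        {"codon": list(table.entries), "decoding_time_s": [repr(t) for t in table.entries.values()]}
    )
    df.to_csv(path, sep="\t", index=False)


def read_codon_table(path: PathLike) -> CodonDecodingTable:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if not {"codon", "decoding_time_s"} <= set(df.columns):
        raise ValueError("codon table must have columns codon, decoding_time_s")
    return CodonDecodingTable(entries=dict(zip(df["codon"], df["decoding_time_s"].astype(float))))


def read_genome(
    fasta_path: PathLike,
    gene_table_path: PathLike,
    total_mrna: float | None = None,
    total_ribosomes: float = 200_000.0,
) -> Genome:
    """Assemble a genome from an ORF FASTA plus a gene-table TSV."""
    orfs = read_orfs_fasta(fasta_path)
    df = read_gene_table(gene_table_path)
    genes = []
    for row in df.itertuples(index=False):
        if row.gene_id not in orfs:
            raise ValueError(f"gene {row.gene_id} in table but not in FASTA")
        genes.append(
            GeneRecord(
                gene_id=row.gene_id,
                orf=orfs[row.gene_id],
                mrna_level=float(row.mrna_level),
                initiation_rate=float(row.initiation_rate),
            )
        )
    if total_mrna is None:
        total_mrna = sum(g.mrna_level for g in genes)
    return Genome(genes=genes, total_mrna=float(total_mrna), total_ribosomes=float(total_ribosomes))
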