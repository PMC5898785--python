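"""Map ORFs to ribosome-flow chains, and calibrate genome-wide rates.

An ORF of K codons is partitioned into n+1 pieces of roughly q=10 codons
(about one ribosome footprint): the first piece holds q-1 codons and folds
into the initiation rate, pieces 2..n hold q codons each, and the last piece
holds between q/2 and 3q/2 codons.  Elongation rates are reciprocals of the
summed per-codon decoding times within a piece; the initiation-side rate
combines the gene's initiation rate p with the first piece:

    lambda_i = 1 / sum(tau_k, k in piece i+1)          i = 1..n
    lambda_0 = 1 / (1/p + sum(tau_k, k in first piece))

Two genome-wide calibrations are provided: rescaling the decoding-time table
so the median per-gene codon elongation rate is 6.4 codons/s, and converting
ribosome density per mRNA into initiation rates with median 0.8 /s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rfm_core import RFMIOSpec
from .synthetic_genome import CodonDecodingTable, GeneRecord, Genome, median_low

__all__ = [
    "PiecePartition",
    "partition_orf",
    "rates_from_orf",
    "normalize_decoding_times",
    "estimate_initiation",
]


@dataclass(frozen=True)
class PiecePartition:
    """Partition of a K-codon ORF into n+1 pieces; piece 1 maps to lambda_0,
    pieces 2..n+1 map to lambda_1..lambda_n."""

    q: int
    piece_sizes: tuple[int, ...]

    @property
    def n(self) -> int:
        return len(self.piece_sizes) - 1

    @property
    def K(self) -> int:
        return sum(self.piece_sizes)

    def codon_slices(self) -> list[slice]:
        """0-based codon index slice of each piece, in order."""
        out, start = [], 0
        for size in self.piece_sizes:
            out.append(slice(start, start + size))
            start += size
        return out


def partition_orf(K: int, q: int = 10) -> PiecePartition:
    """Partition a K-codon ORF: first piece q-1 codons, middle pieces q each,
    last piece the remainder, kept within [q/2, 3q/2] by half-up rounding of
    the piece count."""
    if q < 2 or q % 2:
        raise ValueError("q must be even and >= 2")
    if K < q - 1 + q // 2:
        raise ValueError(f"ORF of {K} codons is too short to partition with q={q}")
    r = K - (q - 1)
    m = max(1, int(np.floor(r / q + 0.5)))  # half-up
    last = r - (m - 1) * q
    if not (q // 2 <= last <= 3 * q // 2):
        raise ValueError(f"cannot partition K={K} with q={q}: last piece {last} outside [{q//2}, {3*q//2}]")
    sizes = (q - 1,) + (q,) * (m - 1) + (last,)
    return PiecePartition(q=q, piece_sizes=sizes)


def rates_from_orf(gene: GeneRecord, table: CodonDecodingTable, q: int = 10) -> RFMIOSpec:
    """Build the chain spec for one gene from its codons and decoding times."""
    part = partition_orf(gene.length, q=q)
    taus = np.array([table.tau(c) for c in gene.orf])
    sums = [float(taus[s].sum()) for s in part.codon_slices()]
    p = gene.initiation_rate
    lam = np.empty(part.n + 1)
    lam[0] = 1.0 / (1.0 / p + sums[0])
    lam[1:] = [1.0 / s for s in sums[1:]]
    return RFMIOSpec(rates=lam, copy_weight=gene.mrna_level, gene_id=gene.gene_id)


def gene_elongation_rate(gene: GeneRecord, table: CodonDecodingTable) -> float:
    """Average codon elongation rate of one gene: K / sum(tau) (codons/s)."""
    total = sum(table.tau(c) for c in gene.orf)
    return gene.length / total


def normalize_decoding_times(
    table: CodonDecodingTable,
    genome: Genome,
    target: float = 6.4,
    per_codon: bool = False,
) -> CodonDecodingTable:
    """Rescale all decoding times by one constant so the median codon
    elongation rate over the genome equals ``target``.

    The median is taken per gene (each mRNA's mean elongation rate
    K_g / sum tau, then the median over genes).  ``per_codon=True`` switches
    to the alternative reading: median of 1/tau over the 61 codons.
    """
    if len(genome) == 0:
        raise ValueError("genome is empty")
    if per_codon:
        med = table.median_rate()
    else:
        med = median_low([gene_elongation_rate(g, table) for g in genome])
    return table.scaled(med / target)


def estimate_initiation(
    density: np.ndarray, mrna: np.ndarray, target_median: float = 0.8
) -> np.ndarray:
    """Initiation rates proportional to ribosome density per mRNA copy,
    scaled so the genome median is ``target_median``."""
    density = np.asarray(density, dtype=float)
    mrna = np.asarray(mrna, dtype=float)
    if density.shape != mrna.shape:
        raise ValueError("density and mrna vectors must have the same length")
    if np.any(mrna <= 0):
        raise ValueError("all mRNA levels must be positive")
    if np.any(density <= 0):
        raise ValueError("all densities must be positive")
    ratio = density / mrna
    return ratio * (target_median / median_low(ratio))
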