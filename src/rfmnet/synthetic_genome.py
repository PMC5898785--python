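"""Synthetic genomes, codon decoding-time tables, and a heterologous reporter.

Everything downstream of this module (chain construction, pooled-network
simulation, oscillation experiments) consumes only three ingredients: a
per-codon decoding-time table, a set of open reading frames with mRNA copy
numbers and initiation rates, and a total ribosome budget.  This module
fabricates all three with the statistical structure of a budding-yeast cell:
about 200,000 ribosomes serving 60,000 mRNAs, a median initiation rate of
0.8 /s, a median codon decoding rate of 6.4 codons/s, and ORF lengths
spanning 25 to 4911 codons.

All draws are deterministic given a seed.  Stop codons are excluded
throughout: an ORF is a list of sense codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "SENSE_CODONS",
    "SYNONYMOUS_GROUPS",
    "CodonDecodingTable",
    "GeneRecord",
    "Genome",
    "generate_codon_table",
    "generate_genome",
    "generate_reporter",
]

#: The 61 sense codons of the standard genetic code, sorted lexicographically.
SENSE_CODONS: tuple[str, ...] = tuple(sorted(standard_dna_table.forward_table))

#: Amino acid -> sorted list of synonymous codons (standard code, 20 groups).
SYNONYMOUS_GROUPS: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in standard_dna_table.forward_table.items() if a == aa))
    for aa in sorted(set(standard_dna_table.forward_table.values()))
}

_CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)


def median_low(values) -> float:
    """Median with a deterministic tie convention: for an even count return
    the lower of the two middle order statistics."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("median of empty sequence")
    return float(v[(v.size - 1) // 2])


@dataclass(frozen=True)
class CodonDecodingTable:
    """Per-codon decoding times (seconds/codon) over the 61 sense codons.

    ``entries`` maps codon -> tau; ``groups`` maps amino acid -> synonymous
    codons.  The decoding *rate* of a codon is 1/tau.
    """

    entries: dict[str, float]
    groups: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(SYNONYMOUS_GROUPS))

    def __post_init__(self) -> None:
        if set(self.entries) != set(SENSE_CODONS):
            missing = set(SENSE_CODONS) - set(self.entries)
            extra = set(self.entries) - set(SENSE_CODONS)
            raise ValueError(f"table must cover exactly the 61 sense codons (missing={sorted(missing)}, extra={sorted(extra)})")
        grouped = [c for g in self.groups.values() for c in g]
        if sorted(grouped) != sorted(SENSE_CODONS):
            raise ValueError("synonymous groups must partition the sense codons")
        taus = np.array([self.entries[c] for c in SENSE_CODONS])
        if not np.all(np.isfinite(taus)) or np.any(taus <= 0):
            raise ValueError("all decoding times must be positive and finite")

    def tau(self, codon: str) -> float:
        try:
            return self.entries[codon]
        except KeyError:
            raise KeyError(f"codon {codon!r} not in decoding table") from None

    def synonyms(self, codon: str) -> tuple[str, ...]:
        return self.groups[_CODON_TO_AA[codon]]

    def scaled(self, factor: float) -> "CodonDecodingTable":
        """A new table with every tau multiplied by ``factor``."""
        return replace(self, entries={c: t * factor for c, t in self.entries.items()})

    def median_rate(self) -> float:
        """Median per-codon decoding rate 1/tau (codons/s)."""
        return median_low([1.0 / t for t in self.entries.values()])


@dataclass
class GeneRecord:
    """One gene: an ORF as a codon list, its mRNA copy number, and its
    initiation rate p (/s)."""

    gene_id: str
    orf: list[str]
    mrna_level: float
    initiation_rate: float

    def __post_init__(self) -> None:
        if len(self.orf) < 25:
            raise ValueError(f"{self.gene_id}: ORF must be at least 25 codons, got {len(self.orf)}")
        bad = [c for c in self.orf if c not in _CODON_TO_AA]
        if bad:
            raise ValueError(f"{self.gene_id}: non-sense codons in ORF: {bad[:5]}")
        if self.mrna_level < 0:
            raise ValueError("mRNA level must be nonnegative")
        if self.initiation_rate <= 0:
            raise ValueError("initiation rate must be positive")

    @property
    def length(self) -> int:
        return len(self.orf)


@dataclass
class Genome:
    """A set of genes plus the cell's mRNA and ribosome budgets."""

    genes: list[GeneRecord]
    total_mrna: float
    total_ribosomes: float

    def __post_init__(self) -> None:
        if self.total_ribosomes <= 0:
            raise ValueError("total_ribosomes must be positive")
        s = sum(g.mrna_level for g in self.genes)
        if s > 0 and abs(s - self.total_mrna) > 1e-9 * self.total_mrna:
            raise ValueError(f"gene mRNA levels sum to {s}, expected {self.total_mrna}")

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def generate_codon_table(seed: int, spread: float = 0.5, median_rate: float = 6.4) -> CodonDecodingTable:
    """Draw a decoding-time table: tau i.i.d. log-normal with log-sd ``spread``,
    rescaled so the median per-codon decoding rate 1/tau equals ``median_rate``
    (6.4 codons/s by default).

    ``spread=0`` degenerates to all codons identical, tau = 1/median_rate.
    """
    if spread < 0:
        raise ValueError("spread must be >= 0")
    rng = np.random.default_rng(seed)
    taus = np.exp(rng.normal(0.0, spread, size=len(SENSE_CODONS)))
    # median(1/(s*tau)) = median(1/tau)/s = median_rate  =>  s = median(1/tau)/median_rate
    s = median_low(1.0 / taus) / median_rate
    taus = taus * s
    return CodonDecodingTable(entries=dict(zip(SENSE_CODONS, map(float, taus))))


def generate_genome(
    n_genes: int,
    seed: int,
    length_range: tuple[int, int] = (25, 4911),
    total_mrna: float = 60_000.0,
    total_ribosomes: float = 200_000.0,
    mrna_log_sigma: float = 1.5,
    initiation_log_sigma: float = 0.5,
    median_initiation: float = 0.8,
) -> Genome:
    """Draw a synthetic genome.

    ORF lengths are log-uniform over ``length_range`` (heavy right tail, as in
    the yeast ORF-length histogram); codons are uniform over the sense codons;
    mRNA copy numbers are log-normal rescaled to sum to ``total_mrna``
    (expression spans several orders of magnitude); initiation rates are
    log-normal rescaled so their low-median equals ``median_initiation``.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    lo, hi = length_range
    if lo < 25:
        raise ValueError("minimum ORF length is 25 codons")
    if hi < lo:
        raise ValueError("length_range must be nondecreasing")
    rng = np.random.default_rng(seed)

    lengths = np.rint(np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))).astype(int)
    lengths = np.clip(lengths, lo, hi)

    mrna = np.exp(rng.normal(0.0, mrna_log_sigma, size=n_genes))
    mrna *= total_mrna / mrna.sum()

    p = np.exp(rng.normal(0.0, initiation_log_sigma, size=n_genes))
    p *= median_initiation / median_low(p)

    codon_idx = [rng.integers(0, len(SENSE_CODONS), size=k) for k in lengths]
    genes = [
        GeneRecord(
            gene_id=f"G{i:05d}",
            orf=[SENSE_CODONS[j] for j in codon_idx[i]],
            mrna_level=float(mrna[i]),
            initiation_rate=float(p[i]),
        )
        for i in range(n_genes)
    ]
    return Genome(genes=genes, total_mrna=float(total_mrna), total_ribosomes=float(total_ribosomes))


def generate_reporter(protein_length: int = 239, seed: int = 0, initiation_rate: float = 0.8) -> GeneRecord:
    """A heterologous reporter (GFP stand-in) of ``protein_length`` sense
    codons drawn uniformly; mRNA level 0 (set by the experiment drivers)."""
    if protein_length < 25:
        raise ValueError("protein_length must be >= 25")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(SENSE_CODONS), size=protein_length)
    return GeneRecord(
        gene_id="REPORTER",
        orf=[SENSE_CODONS[j] for j in idx],
        mrna_level=0.0,
        initiation_rate=float(initiation_rate),
    )
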