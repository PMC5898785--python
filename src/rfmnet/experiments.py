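"""Experiment drivers: the oscillation designs run end-to-end.

Three designs are provided, each returning a tidy ``pandas.DataFrame`` with
one row per condition:

* :func:`run_endogenous` — oscillate sets of endogenous genes, either the
  top-p genes by mRNA level (a bound on the maximal effect) or random p-gene
  subsets averaged over repetitions (the typical effect).
* :func:`run_heterologous` — add a reporter gene at a grid of nominal levels
  (in % of the mRNA pool), initiation rates and amplitudes, oscillate it,
  and measure the effect on the endogenous genes.
* :func:`run_zbar_sweep` — repeat one heterologous condition across several
  calibrated free-pool fractions.

Desk-scale genomes shrink the cell proportionally: a genome of m genes
carries H0 = 200,000 * m / 6310 ribosomes and L_T = 60,000 * m / 6310 mRNAs,
preserving the per-gene ribosome:mRNA economy of the full yeast cell while
keeping the ODE dimension tractable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .amplitude_stats import normalize_per_unit, summarize
from .dtm_mutants import VariantRule, design_variant
from .genome_mapping import normalize_decoding_times, rates_from_orf
from .oscillation_engine import OscillationSpec, build_modulated_group, simulate_entrained
from .rfm_core import RFMIOSpec
from .rfmnp_network import calibrate_pool
from .synthetic_genome import (
    CodonDecodingTable,
    GeneRecord,
    Genome,
    generate_codon_table,
    generate_genome,
    generate_reporter,
)

__all__ = ["ExperimentConfig", "make_desk_genome", "run_endogenous", "run_heterologous", "run_zbar_sweep"]

log = logging.getLogger(__name__)

#: Yeast reference scale the desk genomes are shrunk from.
FULL_GENES = 6310
FULL_RIBOSOMES = 200_000.0
FULL_MRNA = 60_000.0


@dataclass
class ExperimentConfig:
    """Shared knobs of the experiment drivers (defaults follow the reference
    parameterization: A = 1/2, T = 16, zbar = 30%, alpha = 0.8)."""

    n_genes: int = 50
    seed: int = 0
    length_range: tuple[int, int] = (25, 4911)
    codon_spread: float = 0.5
    A: float = 0.5
    T: float = 16.0
    zbar_pct: float = 30.0
    alpha: float = 0.8
    Lh_pct: tuple[float, ...] = (10.0, 20.0, 30.0)
    A_grid: tuple[float, ...] = (0.5,)
    zbar_grid: tuple[float, ...] = (10.0, 15.0, 20.0, 25.0, 30.0)
    set_sizes: tuple[int, ...] = (1, 5, 10)
    repetitions: int = 30
    selection: str = "sorted_by_mrna"  # sorted_by_mrna | random | named_subset | heterologous
    named_genes: tuple[str, ...] = ()
    entrain_tol: float = 1e-6
    max_periods: int = 200
    samples_per_period: int = 128
    exclude_oscillating: bool = True

    @property
    def H0(self) -> float:
        return FULL_RIBOSOMES * self.n_genes / FULL_GENES

    @property
    def L_T(self) -> float:
        return FULL_MRNA * self.n_genes / FULL_GENES


def make_desk_genome(config: ExperimentConfig) -> tuple[Genome, CodonDecodingTable]:
    """Synthetic genome + normalized decoding table at desk scale."""
    genome = generate_genome(
        n_genes=config.n_genes,
        seed=config.seed,
        length_range=config.length_range,
        total_mrna=config.L_T,
        total_ribosomes=config.H0,
    )
    table = generate_codon_table(seed=config.seed + 1, spread=config.codon_spread)
    table = normalize_decoding_times(table, genome)
    return genome, table


def _entrain_and_summarize(specs, pool, config: ExperimentConfig, T: float):
    traj = simulate_entrained(
        specs,
        pool,
        T=T,
        tol=config.entrain_tol,
        max_periods=config.max_periods,
        samples_per_period=config.samples_per_period,
    )
    log.info("entrained after %d periods, residual %.3e", traj.n_periods, traj.residual)
    exclude = None if config.exclude_oscillating else frozenset()
    return traj, summarize(traj, exclude=exclude)


def _oscillated_specs(base_specs: Sequence[RFMIOSpec], targets: set[str], osc: OscillationSpec):
    """Replace each targeted gene's chain by its baseline+modulated pair."""
    out: list[RFMIOSpec] = []
    for s in base_specs:
        if s.gene_id in targets:
            out.extend(build_modulated_group(s, osc, L_h=s.copy_weight))
        else:
            out.append(s)
    return out


def run_endogenous(config: ExperimentConfig, genome: Optional[Genome] = None,
                   table: Optional[CodonDecodingTable] = None) -> pd.DataFrame:
    """Oscillate endogenous gene sets; one row per (mode, set size[, repeat])."""
    if genome is None or table is None:
        genome, table = make_desk_genome(config)
    m = len(genome)
    base_specs = [rates_from_orf(g, table) for g in genome]
    pool = calibrate_pool(base_specs, genome.total_ribosomes, config.zbar_pct)
    by_level = sorted(genome.genes, key=lambda g: -g.mrna_level)
    rng = np.random.default_rng(config.seed + 1000)

    rows = []
    for p in config.set_sizes:
        if p > m:
            raise ValueError(f"set size {p} exceeds genome size {m}")
        if config.selection == "sorted_by_mrna":
            subsets = [tuple(g.gene_id for g in by_level[:p])]
        elif config.selection == "random":
            all_ids = [g.gene_id for g in genome]
            subsets = [tuple(rng.choice(all_ids, size=p, replace=False)) for _ in range(config.repetitions)]
        elif config.selection == "named_subset":
            subsets = [tuple(config.named_genes)]
        else:
            raise ValueError(f"selection mode {config.selection!r} not valid for endogenous runs")

        stats_rows = []
        for targets in subsets:
            osc = OscillationSpec(target_genes=targets, A=config.A, T=config.T)
            specs = _oscillated_specs(base_specs, set(targets), osc)
            _, stats = _entrain_and_summarize(specs, pool, config, config.T)
            stats_rows.append(stats.as_dict())
        mean_stats = {k: float(np.mean([r[k] for r in stats_rows])) for k in stats_rows[0]}
        rows.append(
            {"mode": config.selection, "p": p, "A": config.A, "T": config.T,
             "zbar_target": config.zbar_pct, "seed": config.seed,
             "repetitions": len(subsets), **mean_stats}
        )
    return pd.DataFrame(rows)


def _reporter_specs(
    genome: Genome,
    table: CodonDecodingTable,
    reporter: GeneRecord,
    Lh: float,
    alpha: float,
) -> tuple[list[RFMIOSpec], RFMIOSpec]:
    rep = replace_gene(reporter, mrna_level=Lh, initiation_rate=alpha)
    rep_spec = rates_from_orf(rep, table)
    return [rates_from_orf(g, table) for g in genome] + [rep_spec], rep_spec


def replace_gene(gene: GeneRecord, **kw) -> GeneRecord:
    d = {"gene_id": gene.gene_id, "orf": list(gene.orf),
         "mrna_level": gene.mrna_level, "initiation_rate": gene.initiation_rate}
    d.update(kw)
    return GeneRecord(**d)


def run_heterologous(
    config: ExperimentConfig,
    variant: Optional[str] = None,
    genome: Optional[Genome] = None,
    table: Optional[CodonDecodingTable] = None,
    reporter: Optional[GeneRecord] = None,
    normalized: bool = True,
) -> pd.DataFrame:
    """Oscillate a reporter gene over the (A, Lh%, alpha) grid; one row per
    grid point.  ``variant`` recodes the reporter (HIGH_RD, LOW_RD, MDN_RD,
    SPD_TR, SLW_TR); None keeps the chassis codons."""
    if genome is None or table is None:
        genome, table = make_desk_genome(config)
    if reporter is None:
        reporter = generate_reporter(seed=config.seed + 2)
    if variant is not None:
        rule = VariantRule.built_in(variant, len(reporter.orf))
        reporter = replace_gene(reporter, orf=design_variant(reporter.orf, table, rule))

    rows = []
    for alpha in np.atleast_1d(config.alpha):
        for Lh_pct in config.Lh_pct:
            Lh = Lh_pct * config.L_T / 100.0
            specs, _ = _reporter_specs(genome, table, reporter, Lh, float(alpha))
            pool = calibrate_pool(specs, genome.total_ribosomes, config.zbar_pct)
            for A in config.A_grid:
                osc = OscillationSpec(target_genes=(reporter.gene_id,), A=A, T=config.T, L_h=Lh)
                forced = _oscillated_specs(specs, {reporter.gene_id}, osc)
                _, stats = _entrain_and_summarize(forced, pool, config, config.T)
                row = {
                    "variant": variant or "ORG", "A": A, "T": config.T,
                    "Lh_pct": Lh_pct, "alpha": float(alpha),
                    "zbar_target": config.zbar_pct, "seed": config.seed,
                    **stats.as_dict(),
                }
                if normalized:
                    for key in ("z_a", "Rbar_a", "rhobar_a", "Rhat_a", "rhohat_a"):
                        row[f"norm_{key}"] = normalize_per_unit(row[key], Lh_pct)
                rows.append(row)
    return pd.DataFrame(rows)


def run_zbar_sweep(
    config: ExperimentConfig,
    variant: Optional[str] = "HIGH_RD",
    genome: Optional[Genome] = None,
    table: Optional[CodonDecodingTable] = None,
    reporter: Optional[GeneRecord] = None,
) -> pd.DataFrame:
    """One heterologous condition repeated across the calibrated free-pool
    fractions in ``config.zbar_grid``; one row per zbar target."""
    if genome is None or table is None:
        genome, table = make_desk_genome(config)
    frames = []
    for zbar in config.zbar_grid:
        cfg = replace(config, zbar_pct=float(zbar), A_grid=(config.A,),
                      Lh_pct=(config.Lh_pct[0],))
        df = run_heterologous(cfg, variant=variant, genome=genome, table=table,
                              reporter=reporter)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
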