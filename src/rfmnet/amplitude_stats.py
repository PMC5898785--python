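"""Amplitude statistics of an entrained trajectory.

All quantities are carried on the 0-100 percent scale:

* ``zbar``   — mean free pool over the period, as % of the total pool H0;
* ``z_a``    — free-pool amplitude (half peak-to-peak), as % of the mean pool;
* ``Ra_i``   — per-gene translation-rate amplitude, % of that gene's mean rate;
* ``rhoa_i`` — per-gene mean-density amplitude, % of that gene's mean density;
* ``Rbar_a``/``rhobar_a`` — gene averages, ``Rhat_a``/``rhohat_a`` — gene
  (population) variances of those amplitudes.

By default the oscillating genes themselves are excluded, so the statistics
measure the pool-mediated effect on *the rest* of the genes; pass
``exclude=frozenset()`` to include every gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .oscillation_engine import PeriodicTrajectory

__all__ = ["AmplitudeStats", "period_stats", "summarize", "normalize_per_unit"]


@dataclass
class AmplitudeStats:
    zbar: float
    z_a: float
    Rbar_a: float
    rhobar_a: float
    Rhat_a: float
    rhohat_a: float
    per_gene_Ra: np.ndarray
    per_gene_rhoa: np.ndarray
    gene_ids: list[str]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def as_dict(self) -> dict[str, float]:
        return {
            "zbar": self.zbar,
            "z_a": self.z_a,
            "Rbar_a": self.Rbar_a,
            "rhobar_a": self.rhobar_a,
            "Rhat_a": self.Rhat_a,
            "rhohat_a": self.rhohat_a,
        }


def period_stats(samples: np.ndarray) -> tuple[float, float]:
    """Mean and half peak-to-peak amplitude of one period of samples."""
    s = np.asarray(samples, dtype=float)
    if s.size == 0:
        raise ValueError("empty sample vector")
    if s.size < 8:
        raise ValueError("need at least 8 samples per period")
    return float(s.mean()), float(0.5 * (s.max() - s.min()))


def summarize(
    traj: PeriodicTrajectory,
    H0: Optional[float] = None,
    exclude: Optional[Iterable[str]] = None,
) -> AmplitudeStats:
    """Compute the full amplitude-statistics block from a converged period.

    ``exclude`` defaults to the trajectory's own oscillating gene set.
    """
    H0 = traj.H0 if H0 is None else H0
    excluded = set(traj.oscillating if exclude is None else exclude)

    z_mean, z_amp = period_stats(traj.z)
    zbar = 100.0 * z_mean / H0
    z_a = 100.0 * z_amp / z_mean

    keep = [k for k, g in enumerate(traj.gene_ids) if g not in excluded]
    ids = [traj.gene_ids[k] for k in keep]
    Ra = np.empty(len(keep))
    rhoa = np.empty(len(keep))
    for j, k in enumerate(keep):
        r_mean, r_amp = period_stats(traj.R[k])
        d_mean, d_amp = period_stats(traj.rho[k])
        if r_mean <= 0:
            raise ValueError(f"gene {traj.gene_ids[k]} has zero mean translation rate")
        Ra[j] = 100.0 * r_amp / r_mean
        rhoa[j] = 100.0 * d_amp / d_mean

    if len(keep) == 0:
        nan = float("nan")
        return AmplitudeStats(zbar, z_a, nan, nan, nan, nan, Ra, rhoa, ids)
    return AmplitudeStats(
        zbar=zbar,
        z_a=z_a,
        Rbar_a=float(Ra.mean()),
        rhobar_a=float(rhoa.mean()),
        Rhat_a=float(Ra.var()),  # population variance (divide by m)
        rhohat_a=float(rhoa.var()),
        per_gene_Ra=Ra,
        per_gene_rhoa=rhoa,
        gene_ids=ids,
    )


def normalize_per_unit(stat_value: float, Lh_pct: float) -> float:
    """Statistic per 1% of the total mRNA pool (per 600 mRNAs when the pool
    is 60,000): divide the raw percentage by the gene's level in % of L_T."""
    if Lh_pct <= 0:
        raise ValueError("Lh_pct must be positive")
    return stat_value / Lh_pct
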