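"""Pooled translation network: many chains competing for free ribosomes.

Each gene's chain receives initiation input ``u_j = G(z)`` where ``z`` is the
free ribosomal pool and ``G`` is an increasing saturating function with
``G(0) = 0`` (default ``tanh(z/c)``).  The pool gains each chain's exit flow
and loses each chain's initiation flow, both weighted by the chain's mRNA
copy number ``w_j``:

    dz/dt = sum_j w_j * lambda_n^j * x_n^j
          - sum_j w_j * lambda_0^j * mod_j(t) * (1 - x_1^j) * G(z)

so the total ribosome count H = z + sum_j w_j * sum_i x_i^j is an exact
(linear) invariant of the flow; Runge-Kutta and multistep integrators
preserve it to roundoff.  For constant modulations the network has a unique
globally stable steady state fixed by the rates and H(0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .rfm_core import RFMIOSpec, steady_state_chain

__all__ = [
    "PoolSpec",
    "NetworkState",
    "Network",
    "network_rhs",
    "total_ribosomes",
    "solve_network_steady",
    "calibrate_pool",
]


@dataclass
class PoolSpec:
    """Free-pool coupling: total ribosomes ``H0`` and the response
    ``G(z) = tanh(z/c)`` (family "tanh") or ``G(z) = z/c`` (family "linear")."""

    H0: float
    c: float = 1.0
    G_family: str = "tanh"

    def __post_init__(self) -> None:
        if self.H0 <= 0:
            raise ValueError("H0 must be positive")
        if self.c <= 0:
            raise ValueError("pool scale c must be positive")
        if self.G_family not in ("tanh", "linear"):
            raise ValueError(f"unknown G family {self.G_family!r}")

    def G(self, z: float) -> float:
        if self.G_family == "tanh":
            return float(np.tanh(z / self.c))
        return z / self.c


@dataclass
class NetworkState:
    """Occupancies of every chain plus the free pool ``z``."""

    chains: list[np.ndarray]
    z: float

    def pack(self) -> np.ndarray:
        return np.concatenate([*self.chains, [self.z]])


class Network:
    """Flattened view of a chain collection for fast vectorized dynamics.

    The packed state vector is all chain occupancies gene-by-gene, pool last.
    """

    def __init__(self, specs: Sequence[RFMIOSpec], pool: PoolSpec):
        self.specs = list(specs)
        self.pool = pool
        ns = np.array([s.n for s in self.specs])
        self.offsets = np.concatenate([[0], np.cumsum(ns)])
        self.N = int(self.offsets[-1])  # total sites
        self.first = self.offsets[:-1]
        self.last = self.offsets[1:] - 1
        self.lam0 = np.array([s.rates[0] for s in self.specs])
        self.lam_rest = np.concatenate([s.rates[1:] for s in self.specs])  # length N
        self.w = np.array([s.copy_weight for s in self.specs])
        # acceptor occupancy index: x_{i+1} within the chain, 0 past the end
        self._next_ok = np.ones(self.N, dtype=bool)
        self._next_ok[self.last] = False
        self._mods = [s.modulation for s in self.specs]
        self._has_mod = any(m is not None for m in self._mods)

    # -- dynamics ---------------------------------------------------------
    def modulation(self, t: float) -> np.ndarray:
        if not self._has_mod:
            return np.ones(len(self.specs))
        return np.array([1.0 if m is None else m(t) for m in self._mods])

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        x = y[:-1]
        z = y[-1]
        G = self.pool.G(max(z, 0.0))
        mod = self.modulation(t)
        xnext = np.zeros(self.N)
        xnext[:-1] = x[1:]
        xnext[self.last] = 0.0
        h = self.lam_rest * x * (1.0 - xnext)  # outflow of each site
        inflow = self.lam0 * mod * G * (1.0 - x[self.first])
        dx = np.empty(self.N)
        dx[1:] = h[:-1] - h[1:]
        dx[self.first] = inflow - h[self.first]
        dz = float(self.w @ h[self.last] - self.w @ inflow)
        return np.concatenate([dx, [dz]])

    # -- bookkeeping ------------------------------------------------------
    def unpack(self, y: np.ndarray) -> NetworkState:
        chains = [y[self.offsets[j]: self.offsets[j + 1]].copy() for j in range(len(self.specs))]
        return NetworkState(chains=chains, z=float(y[-1]))

    def total_ribosomes(self, y: np.ndarray) -> float:
        x = y[:-1]
        return float(y[-1] + sum(self.w[j] * x[self.first[j]: self.last[j] + 1].sum()
                                 for j in range(len(self.specs))))

    def outputs(self, y: np.ndarray) -> np.ndarray:
        """Per-chain translation rate lambda_n x_n (per mRNA copy)."""
        return self.lam_rest[self.last] * y[self.last]

    def densities(self, y: np.ndarray) -> np.ndarray:
        """Per-chain mean site occupancy."""
        x = y[:-1]
        return np.array([x[self.first[j]: self.last[j] + 1].mean() for j in range(len(self.specs))])

    def integrate(
        self,
        y0: np.ndarray,
        t_span: tuple[float, float],
        t_eval: Optional[np.ndarray] = None,
        method: str = "RK45",
        rtol: float = 1e-8,
        atol: float = 1e-10,
    ):
        sol = solve_ivp(self.rhs, t_span, y0, t_eval=t_eval, method=method, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"network integration failed: {sol.message}")
        return sol


def network_rhs(state: NetworkState, specs: Sequence[RFMIOSpec], pool: PoolSpec, t: float = 0.0) -> np.ndarray:
    """Derivative of the full packed state (convenience wrapper)."""
    net = Network(specs, pool)
    y = state.pack()
    if y.size != net.N + 1:
        raise ValueError("state dimensions do not match specs")
    return net.rhs(t, y)


def total_ribosomes(state: NetworkState, specs: Sequence[RFMIOSpec]) -> float:
    """Conserved total H = z + sum_j w_j sum_i x_i^j."""
    return float(state.z + sum(s.copy_weight * np.sum(x) for s, x in zip(specs, state.chains)))


def _steady_occupancy(specs: Sequence[RFMIOSpec], pool: PoolSpec, z: float,
                      mod_values: np.ndarray) -> tuple[float, list[np.ndarray]]:
    """Total bound ribosomes and chain profiles when the pool sits at z."""
    G = pool.G(z)
    profiles = []
    bound = 0.0
    for s, m in zip(specs, mod_values):
        u = G * m
        if u <= 0:
            e = np.zeros(s.n)
        else:
            # fold the constant modulation into lambda_0 and solve the chain
            e, _, _ = steady_state_chain(s, u=u)
        profiles.append(e)
        bound += s.copy_weight * e.sum()
    return bound, profiles


def solve_network_steady(
    specs: Sequence[RFMIOSpec],
    pool: PoolSpec,
    tol: float = 1e-10,
    mod_values: Optional[np.ndarray] = None,
    max_iter: int = 200,
) -> NetworkState:
    """Unique unforced steady state of the pooled network.

    At steady state every chain is at its own steady profile for input
    ``G(z)``, and the pool level is fixed by ribosome conservation:
    ``z + bound(z) = H0``.  ``bound(z)`` is strictly increasing in z, so the
    root is found by bisection on ``z in [0, H0]``.

    ``mod_values`` freezes each chain's modulation at a constant (default 1,
    or the modulation's value at t=0 ... callers freeze forcing at its mean).
    """
    specs = list(specs)
    if mod_values is None:
        mod_values = np.ones(len(specs))
    H0 = pool.H0

    def excess(z: float) -> float:
        bound, _ = _steady_occupancy(specs, pool, z, mod_values)
        return z + bound - H0

    # excess(0) = -H0 < 0 and excess(H0) >= 0; excess strictly increasing
    z = float(brentq(excess, 0.0, H0, xtol=tol * max(H0, 1.0), maxiter=max_iter))
    _, profiles = _steady_occupancy(specs, pool, z, mod_values)
    return NetworkState(chains=profiles, z=z)


def calibrate_pool(
    specs: Sequence[RFMIOSpec],
    H0: float,
    target_zbar_pct: float,
    G_family: str = "tanh",
    tol_pct: float = 0.1,
    mod_values: Optional[np.ndarray] = None,
    max_iter: int = 100,
) -> PoolSpec:
    """Find the pool-response scale ``c`` whose unforced steady state leaves
    ``target_zbar_pct`` percent of the ribosomes free.

    Larger ``c`` weakens binding (smaller G at a given z) and so raises the
    steady free fraction; the map c -> zbar is monotone and is bisected.
    Raises ``ValueError`` with the achievable bracket when the target cannot
    be met.
    """
    if not (0.0 < target_zbar_pct < 100.0):
        raise ValueError("target_zbar_pct must be in (0, 100)")

    def zbar(c: float) -> float:
        pool = PoolSpec(H0=H0, c=c, G_family=G_family)
        st = solve_network_steady(specs, pool, mod_values=mod_values)
        return 100.0 * st.z / H0

    # c is searched over [1e-6, 1e3] * H0; outside that band G is effectively
    # a step (all-bound) or zero (all-free) and the target is declared
    # unachievable with the bracket of reachable zbar values.
    c_lo, c_hi = 1e-6 * H0, 1e3 * H0
    z_lo = zbar(c_lo)
    z_hi = zbar(c_hi)
    if not (z_lo <= target_zbar_pct <= z_hi):
        raise ValueError(
            f"target zbar {target_zbar_pct}% outside achievable range "
            f"[{z_lo:.4f}%, {z_hi:.4f}%] for H0={H0}"
        )
    for _ in range(max_iter):
        c_mid = np.sqrt(c_lo * c_hi)  # bisect in log space: c spans decades
        z_mid = zbar(c_mid)
        if abs(z_mid - target_zbar_pct) <= tol_pct:
            return PoolSpec(H0=H0, c=c_mid, G_family=G_family)
        if z_mid < target_zbar_pct:
            c_lo = c_mid
        else:
            c_hi = c_mid
    raise RuntimeError("pool calibration exhausted its iteration budget")
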