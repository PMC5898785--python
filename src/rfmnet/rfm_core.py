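"""Single-mRNA ribosome traffic: the ribosome flow model (RFM) and its
input-controlled extension (RFMIO).

The mRNA is coarse-grained into ``n`` sites; ``x_i(t) in [0,1]`` is the
normalized ribosome occupancy of site ``i``.  Flow from site ``i`` to
``i+1`` is ``lambda_i * x_i * (1 - x_{i+1})`` — a soft exclusion principle:
flow rises with the donor occupancy and falls as the acceptor fills.  The
RFMIO gates the initiation flow by an external input ``u >= 0``:

    dx_1/dt = lambda_0 * u * (1 - x_1) - lambda_1 * x_1 * (1 - x_2)
    dx_i/dt = h_{i-1}(x) - h_i(x),      h_i = lambda_i * x_i * (1 - x_{i+1})
    dx_n/dt = h_{n-1}(x) - lambda_n * x_n

with output (translation rate) ``R(t) = lambda_n * x_n(t)``.  The chain is a
tridiagonal cooperative system: for constant ``u > 0`` it has a unique,
globally asymptotically stable steady state in the open unit cube.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp

__all__ = ["RFMIOSpec", "rfm_rhs", "steady_state_chain", "steady_state_by_integration"]


@dataclass
class RFMIOSpec:
    """One translation chain: site count ``n``, rates ``lambda_0..lambda_n``,
    the number of mRNA copies this chain stands for (``copy_weight``), and an
    optional time->[0,1] modulation multiplying the initiation term."""

    rates: np.ndarray  # length n+1, positive
    copy_weight: float = 1.0
    modulation: Optional[Callable[[float], float]] = None
    gene_id: str = ""

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 1 or self.rates.size < 2:
            raise ValueError("rates must be a vector of length n+1 >= 2")
        if np.any(self.rates <= 0) or not np.all(np.isfinite(self.rates)):
            raise ValueError("all rates must be positive and finite")
        if self.copy_weight < 0:
            raise ValueError("copy_weight must be nonnegative")

    @property
    def n(self) -> int:
        return self.rates.size - 1


def rfm_rhs(x: np.ndarray, spec: RFMIOSpec, u: float = 1.0) -> np.ndarray:
    """Occupancy derivatives of one chain at state ``x`` with input ``u``."""
    x = np.asarray(x, dtype=float)
    lam = spec.rates
    n = spec.n
    if x.size != n:
        raise ValueError(f"state has {x.size} sites, spec has {n}")
    if u < 0:
        raise ValueError("input u must be nonnegative")
    # h[i] = flow out of site i+1 (h[n-1] = exit flow lambda_n x_n)
    h = np.empty(n)
    h[:-1] = lam[1:-1] * x[:-1] * (1.0 - x[1:])
    h[-1] = lam[-1] * x[-1]
    inflow = lam[0] * u * (1.0 - x[0])
    dx = np.empty(n)
    dx[0] = inflow - h[0]
    dx[1:] = h[:-1] - h[1:]
    return dx


def _profile_for_rate(lam: np.ndarray, u: float, R: float) -> Optional[np.ndarray]:
    """Back-substitute the steady occupancy profile for a trial flow ``R``.

    At steady state every inter-site flow equals R:
        lambda_n e_n = R,  lambda_i e_i (1 - e_{i+1}) = R.
    Returns None when R is infeasible (some occupancy would reach 1).
    """
    n = lam.size - 1
    e = np.empty(n)
    e[-1] = R / lam[-1]
    if e[-1] >= 1.0:
        return None
    for i in range(n - 2, -1, -1):
        denom = lam[i + 1] * (1.0 - e[i + 1])
        e[i] = R / denom
        if e[i] >= 1.0:
            return None
    return e


def steady_state_chain(
    spec: RFMIOSpec, u: float = 1.0, tol: float = 1e-12, max_iter: int = 200
) -> tuple[np.ndarray, float, float]:
    """Unique steady state of one chain at constant input ``u``.

    Returns ``(e, R, rho)``: the occupancy profile, the steady translation
    rate ``R = lambda_n e_n`` and the mean density ``rho = mean(e)``.

    The steady state is found by bisection on the through-flow R: given R,
    the profile back-substitutes in closed form, and the initiation residual
    ``lambda_0 u (1 - e_1) - R`` is strictly decreasing in R, so the root is
    unique and bracketed in ``(0, min(lambda_0 u, lambda_1..n))``.
    """
    if u <= 0:
        raise ValueError("steady state requires u > 0")
    lam = spec.rates

    def residual(R: float) -> float:
        e = _profile_for_rate(lam, u, R)
        if e is None:
            return -np.inf
        return lam[0] * u * (1.0 - e[0]) - R

    hi = min(lam[0] * u, float(lam[1:].min()))
    lo = 0.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= tol * max(hi, 1.0):
            break
    else:
        raise RuntimeError(f"steady-state bisection did not converge (bracket [{lo}, {hi}])")
    R = 0.5 * (lo + hi)
    e = _profile_for_rate(lam, u, lo)
    if e is None:
        raise RuntimeError("steady-state profile infeasible at converged flow")
    return e, float(lam[-1] * e[-1]), float(e.mean())


def steady_state_by_integration(
    spec: RFMIOSpec,
    u: float = 1.0,
    x0: Optional[np.ndarray] = None,
    t_max: float = 5_000.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> tuple[np.ndarray, float, float]:
    """Steady state by relaxing the ODE from ``x0`` (default: empty chain).

    Independent of :func:`steady_state_chain`; used as a cross-check and as a
    fallback oracle.  Integrates with a stiff-capable method until the
    right-hand side is small.
    """
    n = spec.n
    x0 = np.full(n, 0.0) if x0 is None else np.asarray(x0, dtype=float)

    def rhs(t, x):
        return rfm_rhs(x, spec, u)

    t = 0.0
    x = x0
    span = 50.0
    for _ in range(int(np.ceil(t_max / span))):
        sol = solve_ivp(rhs, (t, t + span), x, method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"ODE relaxation failed: {sol.message}")
        x = sol.y[:, -1]
        t = sol.t[-1]
        if np.max(np.abs(rfm_rhs(x, spec, u))) < 1e-11:
            break
    lam = spec.rates
    return x, float(lam[-1] * x[-1]), float(x.mean())
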