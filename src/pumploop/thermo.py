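"""Continuous-time kinetic cycle: master equation, NESS flux, entropy production.

The Post-Albers cycle is modelled as a closed unicycle of ``n`` states
with forward rates ``k_i+`` on edge i -> i+1 (mod n) and backward rates
``k_i-`` on the reverse edge.  The probability density p_i(t) obeys the
master equation

    dp_i/dt = sum_{j != i} [ k(j->i) p_j - k(i->j) p_i ].

At the nonequilibrium steady state (NESS) the cycle carries an
edge-independent net probability current

    J_NESS = pi_i k_i+  -  pi_{i+1} k_i-          (any edge i),

the number of net forward reactions per unit time, and dissipates heat
at the rate

    e_p = J_NESS * ln( prod_i k_i+ / prod_i k_i- ),

the cycle flux times the cycle affinity (dimensionless, natural-log
units; no k_B T factor is applied).  Detailed balance
(prod k+ = prod k-) is equivalent to J_NESS = 0 and e_p = 0.

J_NESS is computed from the exact stationary distribution of the
continuous-time generator, which is well defined for any connected
unicycle; the closed-form product expression is recovered on small
cycles and used as an independent check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .markov import MarkovError, StateSpace

#: Illustrative driven Post-Albers rate set (forward-biased cycle,
#: arbitrary inverse-time units); not fitted to measured turnover.
DEFAULT_CYCLE_KPLUS = (5.0, 4.0, 6.0, 3.0)
DEFAULT_CYCLE_KMINUS = (1.0, 0.8, 1.2, 0.6)


class ThermoError(ValueError):
    """Structural or numerical problem in the kinetic-cycle model."""


@dataclass(frozen=True)
class RateSet:
    """Forward/backward rate constants on the edges of a closed unicycle.

    Edge ``i`` connects state ``i`` to state ``(i+1) % n``:
    ``k_plus[i]`` is the forward rate, ``k_minus[i]`` the backward rate.
    """

    states: StateSpace
    k_plus: np.ndarray
    k_minus: np.ndarray

    def __post_init__(self):
        kp = np.asarray(self.k_plus, dtype=float)
        km = np.asarray(self.k_minus, dtype=float)
        n = self.states.n
        if kp.shape != (n,) or km.shape != (n,):
            raise ThermoError(
                f"need one forward and one backward rate per edge ({n} edges)"
            )
        if np.any(kp < 0) or np.any(km < 0):
            raise ThermoError("rates must be non-negative")
        object.__setattr__(self, "k_plus", kp)
        object.__setattr__(self, "k_minus", km)

    @property
    def n(self) -> int:
        return self.states.n

    def rate_matrix(self) -> np.ndarray:
        """W[i, j] = rate of the transition i -> j."""
        n = self.n
        W = np.zeros((n, n))
        for i in range(n):
            j = (i + 1) % n
            W[i, j] += self.k_plus[i]
            W[j, i] += self.k_minus[i]
        return W

    def generator(self) -> np.ndarray:
        """Generator G with dp/dt = G p for the column vector p."""
        W = self.rate_matrix()
        return W.T - np.diag(W.sum(axis=1))


def default_post_albers_rates() -> RateSet:
    return RateSet(StateSpace(), np.array(DEFAULT_CYCLE_KPLUS), np.array(DEFAULT_CYCLE_KMINUS))


@dataclass(frozen=True)
class ProbabilityDensity:
    """State probabilities p_i(t) at one instant."""

    states: StateSpace
    p: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.shape != (self.states.n,):
            raise ThermoError("p length does not match state count")
        if np.any(p < -1e-10) or abs(p.sum() - 1.0) > 1e-10:
            raise ThermoError("p is not a probability vector")
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class ThermoSummary:
    """NESS flux, cycle affinity and entropy-production rate."""

    J_ness: float
    affinity: float
    e_p: float
    pi: np.ndarray = field(repr=False, default=None)


def drift(p: ProbabilityDensity, rates: RateSet) -> np.ndarray:
    """Right-hand side of the master equation, dp/dt.

    Components sum to zero (probability is conserved).
    """
    if p.states.labels != rates.states.labels:
        raise ThermoError("probability density and rates use different state spaces")
    return rates.generator() @ p.p


def _connected(rates: RateSet) -> bool:
    return bool(np.all((rates.k_plus > 0) | (rates.k_minus > 0)))


def stationary_density(rates: RateSet) -> np.ndarray:
    """Exact stationary probability vector of the generator (null space)."""
    if not _connected(rates):
        raise ThermoError(
            "cycle is disconnected (an edge has zero rate in both directions)"
        )
    G = rates.generator()
    n = rates.n
    A = np.vstack([G, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def edge_currents(rates: RateSet, pi: np.ndarray | None = None) -> np.ndarray:
    """Net probability current pi_i k_i+ - pi_{i+1} k_i- on every edge.

    At the stationary density these agree on all edges of a unicycle.
    """
    if pi is None:
        pi = stationary_density(rates)
    n = rates.n
    nxt = np.roll(np.arange(n), -1)
    return pi * rates.k_plus - pi[nxt] * rates.k_minus


def ness_flux(rates: RateSet) -> float:
    """Steady-state cycle flux J_NESS (net reactions per unit time).

    Positive when the forward rate product exceeds the backward one.
    """
    return float(edge_currents(rates).mean())


def cycle_affinity(rates: RateSet) -> float:
    """ln(prod k+ / prod k-); requires strictly positive rates."""
    if np.any(rates.k_plus <= 0) or np.any(rates.k_minus <= 0):
        raise ThermoError("affinity undefined: all rates must be strictly positive")
    return float(np.sum(np.log(rates.k_plus)) - np.sum(np.log(rates.k_minus)))


def entropy_production(rates: RateSet) -> ThermoSummary:
    """Heat dissipation rate e_p = J_NESS * cycle affinity (dimensionless).

    Non-negative for every strictly positive rate set; zero exactly at
    detailed balance.
    """
    A = cycle_affinity(rates)
    pi = stationary_density(rates)
    J = float(edge_currents(rates, pi).mean())
    return ThermoSummary(J_ness=J, affinity=A, e_p=J * A, pi=pi)


def integrate_master(
    p0: ProbabilityDensity,
    rates,
    t_grid: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> pd.DataFrame:
    """Integrate the master equation on ``t_grid``.

    ``rates`` is either a constant :class:`RateSet` or a callable
    ``t -> RateSet`` for time-dependent transition rates.  Returns a
    tidy frame with columns ``t`` plus one probability column per state;
    each row is renormalization-checked to 1e-10.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ThermoError("t_grid must be strictly increasing")
    if callable(rates):
        probe = rates(float(t_grid[0]))
    else:
        probe = rates
    if p0.states.labels != probe.states.labels:
        raise ThermoError("p0 and rates use different state spaces")

    if callable(rates):
        def rhs(t, y):
            return rates(t).generator() @ y
    else:
        G = rates.generator()

        def rhs(t, y):
            return G @ y

    sol = solve_ivp(
        rhs,
        (float(t_grid[0]), float(t_grid[-1])),
        p0.p,
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise ThermoError(f"master-equation solver failed: {sol.message}")
    Y = sol.y.T
    sums = Y.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-8):
        raise ThermoError("probability not conserved during integration")
    Y = Y / sums[:, None]
    df = pd.DataFrame(Y, columns=list(p0.states.labels))
    df.insert(0, "t", sol.t)
    return df
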