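"""Discrete-time Markov chain over Na/K-ATPase conformations.

The sodium pump cycles through the four principal Post-Albers
conformations E1 -> E1P -> E2P -> E2 -> E1.  Treating the conformation
of a single pump unit as memoryless, its turnover is a discrete-time
Markov chain: a row-stochastic one-step matrix ``P`` over the state
labels, a nominal time interval ``dt`` between steps, and a stationary
distribution ``pi`` describing the long-run superposition of states.

The chain may be refined with any number of "hidden" intermediate
states (e.g. sub-states binding different numbers of Na or K ions)
inserted on individual edges without changing path probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

POST_ALBERS_LABELS = ("E1", "E1P", "E2P", "E2")

#: Illustrative strongly-cyclic one-step matrix for the four Post-Albers
#: states (forward bias E1->E1P->E2P->E2 with small reverse/dwell
#: probabilities).  Not fitted to any measured turnover data.
DEFAULT_POST_ALBERS_P = np.array(
    [
        [0.10, 0.80, 0.05, 0.05],
        [0.05, 0.10, 0.80, 0.05],
        [0.05, 0.05, 0.15, 0.75],
        [0.70, 0.10, 0.05, 0.15],
    ]
)

ROW_SUM_TOL = 1e-9


class MarkovError(ValueError):
    """Structural problem with a chain definition."""


class StationaryError(RuntimeError):
    """No unique stationary distribution, or the solver did not converge."""


@dataclass(frozen=True)
class StateSpace:
    """Ordered conformational state labels.

    ``hidden`` marks the subset of ``labels`` that are hidden
    intermediate states (interleaved among the visible ones).
    """

    labels: tuple[str, ...] = POST_ALBERS_LABELS
    hidden: tuple[str, ...] = ()

    def __post_init__(self):
        labels = tuple(self.labels)
        hidden = tuple(self.hidden)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "hidden", hidden)
        if not labels:
            raise MarkovError("state space must have at least one state")
        if len(set(labels)) != len(labels):
            raise MarkovError("state labels must be unique")
        if not set(hidden) <= set(labels):
            raise MarkovError("hidden states must be a subset of labels")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    @property
    def visible(self) -> tuple[str, ...]:
        return tuple(s for s in self.labels if s not in set(self.hidden))


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic one-step probability matrix p_ij over a StateSpace.

    ``dt`` is the nominal time interval between steps, carried as
    metadata in arbitrary units (no physical calibration is attempted).
    """

    states: StateSpace
    P: np.ndarray
    dt: float = 1.0

    def __post_init__(self):
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise MarkovError(f"transition matrix must be square, got shape {P.shape}")
        if P.shape[0] != self.states.n:
            raise MarkovError(
                f"matrix dimension {P.shape[0]} does not match "
                f"{self.states.n} states"
            )
        object.__setattr__(self, "P", P)

    @property
    def n(self) -> int:
        return self.states.n


@dataclass(frozen=True)
class StationaryDistribution:
    """Stationary probability vector pi over a StateSpace."""

    states: StateSpace
    pi: np.ndarray

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (self.states.n,):
            raise MarkovError("pi length does not match state count")
        if np.any(pi < -1e-12) or abs(pi.sum() - 1.0) > 1e-12:
            raise MarkovError("pi is not a probability vector")
        object.__setattr__(self, "pi", pi)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.states.labels, self.pi.tolist()))


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    row_sums: np.ndarray
    row_deviation: np.ndarray
    bad_rows: tuple[int, ...]
    negative_rows: tuple[int, ...]

    @property
    def message(self) -> str:
        if self.ok:
            return "valid row-stochastic matrix"
        parts = []
        if self.negative_rows:
            parts.append(f"negative entries in rows {list(self.negative_rows)}")
        if self.bad_rows:
            devs = {i: float(self.row_deviation[i]) for i in self.bad_rows}
            parts.append(f"row sums deviate from 1: {devs}")
        return "; ".join(parts)


def default_post_albers_chain(dt: float = 1.0) -> TransitionMatrix:
    """The illustrative 4-state Post-Albers chain shipped with the package."""
    return TransitionMatrix(StateSpace(), DEFAULT_POST_ALBERS_P.copy(), dt=dt)


def validate_transition_matrix(tm: TransitionMatrix) -> ValidationReport:
    """Check row-stochasticity of a transition matrix.

    Non-square input is a structural error raised at construction; here
    a negative entry or a row-sum deviation above ``ROW_SUM_TOL`` yields
    a failing report listing the offending rows.
    """
    P = tm.P
    row_sums = P.sum(axis=1)
    dev = np.abs(row_sums - 1.0)
    neg = tuple(int(i) for i in np.where((P < 0).any(axis=1))[0])
    bad = tuple(int(i) for i in np.where(dev > ROW_SUM_TOL)[0])
    ok = not neg and not bad
    return ValidationReport(ok, row_sums, dev, bad, neg)


def _require_valid(tm: TransitionMatrix) -> None:
    rep = validate_transition_matrix(tm)
    if not rep.ok:
        raise MarkovError(f"invalid transition matrix: {rep.message}")


def step_distribution(dist: np.ndarray, tm: TransitionMatrix) -> np.ndarray:
    """One-step evolution of a probability row vector: dist -> dist @ P."""
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (tm.n,):
        raise MarkovError(
            f"distribution length {dist.shape} does not match {tm.n} states"
        )
    if abs(dist.sum() - 1.0) > 1e-9 or np.any(dist < -1e-12):
        raise MarkovError("input is not a probability distribution")
    out = dist @ tm.P
    return out / out.sum()


def is_irreducible(tm: TransitionMatrix) -> bool:
    """Single strongly-connected component on the positive-entry graph."""
    adj = csr_matrix((tm.P > 0).astype(int))
    ncomp, _ = connected_components(adj, directed=True, connection="strong")
    return ncomp == 1


def stationary_distribution(
    tm: TransitionMatrix, tol: float = 1e-10, max_iter: int = 10**6
) -> StationaryDistribution:
    """Stationary distribution pi with pi = pi P, sum(pi) = 1.

    Solved by power iteration on the lazy chain (P + I)/2, which has the
    same stationary vector but is aperiodic, so the iteration converges
    for every irreducible chain.  The residual reported and tested is
    ``max|pi P - pi|`` on the *original* matrix.
    """
    _require_valid(tm)
    if not is_irreducible(tm):
        raise StationaryError(
            "chain is reducible (more than one recurrent class): "
            "no unique stationary distribution"
        )
    n = tm.n
    P_lazy = 0.5 * (tm.P + np.eye(n))
    pi = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = pi @ P_lazy
        nxt /= nxt.sum()
        if np.max(np.abs(nxt - pi)) < 0.1 * tol:
            pi = nxt
            break
        pi = nxt
    residual = float(np.max(np.abs(pi @ tm.P - pi)))
    if residual >= tol:
        raise StationaryError(
            f"power iteration did not converge: residual {residual:.3e} >= tol {tol:.1e}"
        )
    return StationaryDistribution(tm.states, pi / pi.sum())


def stationary_distribution_exact(tm: TransitionMatrix) -> StationaryDistribution:
    """Direct linear solve of (pi P = pi, sum pi = 1).

    Independent of the power-iteration path; used as a cross-check.
    """
    _require_valid(tm)
    if not is_irreducible(tm):
        raise StationaryError("chain is reducible: no unique stationary distribution")
    n = tm.n
    A = np.vstack([tm.P.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return StationaryDistribution(tm.states, pi / pi.sum())


@dataclass(frozen=True)
class EdgeSplit:
    """Insert a hidden state on one edge, conserving path probability.

    The original one-step probability p(src -> dst) is rerouted through
    ``hidden``: p(src -> hidden) = p(src -> dst), p(hidden -> dst) =
    1 - dwell, p(hidden -> hidden) = dwell.  The total probability of
    eventually reaching ``dst`` through the hidden state is unchanged
    for any dwell in [0, 1); dwell -> 0 is the fast-hidden limit.
    """

    src: str
    dst: str
    hidden: str
    dwell: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.dwell < 1.0:
            raise MarkovError("dwell must be in [0, 1)")


def expand_hidden_states(
    tm: TransitionMatrix, plan: list[EdgeSplit]
) -> TransitionMatrix:
    """Refine a chain by threading edges through hidden intermediate states.

    An empty plan returns the input unchanged.  Each split conserves the
    path probability of its edge, so the expanded matrix is
    row-stochastic whenever the input is.
    """
    if not plan:
        return tm
    _require_valid(tm)
    labels = list(tm.states.labels)
    hidden = list(tm.states.hidden)
    P = tm.P.copy()
    for split in plan:
        if split.hidden in labels:
            raise MarkovError(f"hidden state name {split.hidden!r} already in use")
        i, j = labels.index(split.src), labels.index(split.dst)
        p_edge = P[i, j]
        if p_edge <= 0:
            raise MarkovError(
                f"edge {split.src}->{split.dst} has zero probability; nothing to split"
            )
        n = len(labels)
        newP = np.zeros((n + 1, n + 1))
        newP[:n, :n] = P
        h = n
        newP[i, j] = 0.0
        newP[i, h] = p_edge
        newP[h, h] = split.dwell
        newP[h, j] = 1.0 - split.dwell
        # interleave: hidden label placed right after its source state
        order = list(range(n))
        order.insert(i + 1, h)
        newP = newP[np.ix_(order, order)]
        labels.insert(i + 1, split.hidden)
        hidden.append(split.hidden)
        P = newP
    out = TransitionMatrix(
        StateSpace(tuple(labels), tuple(hidden)), P, dt=tm.dt
    )
    rep = validate_transition_matrix(out)
    if not rep.ok:
        raise MarkovError(f"expansion broke probability conservation: {rep.message}")
    return out


def marginal_visible_stationary(tm: TransitionMatrix) -> StationaryDistribution:
    """Stationary occupancy of visible states, renormalized over them."""
    full = stationary_distribution_exact(tm)
    hidden = set(tm.states.hidden)
    keep = [i for i, s in enumerate(tm.states.labels) if s not in hidden]
    vis_labels = tuple(tm.states.labels[i] for i in keep)
    pi = full.pi[keep]
    return StationaryDistribution(StateSpace(vis_labels), pi / pi.sum())


def simulate_chain(
    tm: TransitionMatrix,
    n_steps: int,
    seed: int | np.random.Generator,
    start: str | int = 0,
) -> np.ndarray:
    """Sample a state path of length ``n_steps + 1`` (indices into labels).

    Bit-reproducible for a given integer seed.  ``start`` is a state
    label or index (default: first state).
    """
    if n_steps < 1:
        raise MarkovError("n_steps must be >= 1")
    _require_valid(tm)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cum = np.cumsum(tm.P, axis=1)
    cum[:, -1] = 1.0  # guard against rounding in searchsorted
    path = np.empty(n_steps + 1, dtype=np.int64)
    state = tm.states.index(start) if isinstance(start, str) else int(start)
    path[0] = state
    u = rng.random(n_steps)
    for k in range(n_steps):
        state = int(np.searchsorted(cum[state], u[k], side="right"))
        path[k + 1] = state
    return path


def occupancy(path: np.ndarray, n_states: int) -> np.ndarray:
    """Empirical state occupancy frequencies of a sampled path."""
    counts = np.bincount(np.asarray(path), minlength=n_states)
    return counts / counts.sum()
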