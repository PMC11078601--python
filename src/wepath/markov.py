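"""Discrete-state Markov oracles with exactly solvable first-passage quantities.

A :class:`MarkovOracle` is a row-stochastic transition matrix over labelled
states (by convention including an unassociated state ``U`` and a bound
product state ``B``).  Mean first-passage times and commitment probabilities
are obtained by linear solves, giving exact ground truth against which the
weighted-ensemble estimators are validated.  An oracle can be hand-specified
or estimated as the "twin" of the continuous surrogate from brute-force
recycled propagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csgraph, csr_matrix

from . import surrogate as sg

__all__ = [
    "MarkovOracle",
    "exact_mfpt",
    "exact_commitment",
    "build_markov_twin",
    "simulate_chain",
    "first_passage_times",
]

_ROW_TOL = 1e-12


@dataclass(frozen=True)
class MarkovOracle:
    """Row-stochastic transition model at a fixed lag time.

    No reversibility is required: recycled steady states are in general
    nonequilibrium, so detailed-balance-violating matrices are accepted.
    """

    states: tuple[str, ...]
    transition_matrix: np.ndarray
    target: str = "B"

    def __post_init__(self) -> None:
        P = np.asarray(self.transition_matrix, dtype=float)
        object.__setattr__(self, "transition_matrix", P)
        n = len(self.states)
        if P.shape != (n, n):
            raise ValueError("transition matrix shape must match the state list")
        if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > _ROW_TOL):
            raise ValueError("rows must be non-negative and sum to 1 within 1e-12")
        if len(set(self.states)) != n:
            raise ValueError("state labels must be unique")
        if self.target in self.states:
            # product state must be reachable from every state
            order = csgraph.breadth_first_order(
                csr_matrix(P.T > 0), self.index(self.target),
                directed=True, return_predecessors=False)
            if len(order) != n:
                raise ValueError(f"target state {self.target!r} not reachable "
                                 "from every state")

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise KeyError(f"unknown state {state!r}") from None

    @property
    def n_states(self) -> int:
        return len(self.states)


def exact_mfpt(oracle: MarkovOracle, source: str, target: str) -> float:
    """Mean first-passage time source -> target, in lag units.

    Solves ``(I - Q) m = 1`` on the target-deleted submatrix Q.  By
    convention MFPT(target -> target) = 0.
    """
    i, j = oracle.index(source), oracle.index(target)
    if i == j:
        return 0.0
    keep = [k for k in range(oracle.n_states) if k != j]
    Q = oracle.transition_matrix[np.ix_(keep, keep)]
    try:
        m = np.linalg.solve(np.eye(len(keep)) - Q, np.ones(len(keep)))
    except np.linalg.LinAlgError:
        raise ValueError(f"{target!r} unreachable from {source!r}") from None
    if np.any(m < 0) or not np.all(np.isfinite(m)):
        raise ValueError(f"{target!r} unreachable from {source!r}")
    return float(m[keep.index(i)])


def exact_commitment(oracle: MarkovOracle, start: str, absorb_a: str,
                     absorb_b: str) -> float:
    """P(reach ``absorb_a`` before ``absorb_b`` | start), by linear solve."""
    ia, ib = oracle.index(absorb_a), oracle.index(absorb_b)
    i0 = oracle.index(start)
    if i0 == ia:
        return 1.0
    if i0 == ib:
        return 0.0
    keep = [k for k in range(oracle.n_states) if k not in (ia, ib)]
    P = oracle.transition_matrix
    Q = P[np.ix_(keep, keep)]
    b = P[keep, ia]
    try:
        h = np.linalg.solve(np.eye(len(keep)) - Q, b)
    except np.linalg.LinAlgError:
        raise ValueError("neither absorbing state reachable") from None
    return float(h[keep.index(i0)])


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary row vector of a row-stochastic matrix (unit eigenvector)."""
    w, v = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_chain(oracle: MarkovOracle, start: str, n_steps: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Sample a single trajectory of state indices, length n_steps + 1."""
    P = oracle.transition_matrix
    cum = np.cumsum(P, axis=1)
    path = np.empty(n_steps + 1, dtype=np.int64)
    path[0] = oracle.index(start)
    u = rng.random(n_steps)
    for t in range(n_steps):
        path[t + 1] = np.searchsorted(cum[path[t]], u[t], side="right")
    return path


def first_passage_times(oracle: MarkovOracle, source: str, target: str,
                        n_samples: int, seed: int,
                        max_steps: int = 1_000_000) -> np.ndarray:
    """Monte-Carlo first-passage times source -> target (vectorized sampling)."""
    rng = np.random.default_rng(seed)
    P = oracle.transition_matrix
    cum = np.cumsum(P, axis=1)
    j = oracle.index(target)
    cur = np.full(n_samples, oracle.index(source), dtype=np.int64)
    t_hit = np.zeros(n_samples, dtype=np.int64)
    alive = np.ones(n_samples, dtype=bool)
    for step in range(1, max_steps + 1):
        u = rng.random(int(alive.sum()))
        nxt = (cum[cur[alive]] > u[:, None]).argmax(axis=1)
        cur[alive] = nxt
        hit = alive.copy()
        hit[alive] = nxt == j
        t_hit[hit] = step
        alive &= ~hit
        if not alive.any():
            return t_hit
    raise RuntimeError("first-passage sampling did not terminate")


def write_transition_matrix(path: str, oracle: MarkovOracle) -> None:
    """CSV fixture: row/column labels are the oracle's state names."""
    import pandas as pd
    pd.DataFrame(oracle.transition_matrix, index=list(oracle.states),
                 columns=list(oracle.states)).to_csv(path)


def read_transition_matrix(path: str, target: str = "B") -> MarkovOracle:
    import pandas as pd
    df = pd.read_csv(path, index_col=0)
    return MarkovOracle(tuple(df.index), df.to_numpy(dtype=float),
                        target=target)


def build_markov_twin(params: "sg.SurrogateParams | None" = None,
                      lag: int = 250, n_samples: int = 200_000, seed: int = 0,
                      matrix: "np.ndarray | None" = None,
                      states: "tuple[str, ...] | None" = None) -> MarkovOracle:
    """Discrete twin of the surrogate, or a pass-through of a hand matrix.

    With a matrix given, wraps it unchanged.  Otherwise discretizes a long
    recycled brute-force trajectory at ``lag`` steps into macrostate x site
    labels (``U``, ``I<site>``, ``B``) and estimates the row-stochastic
    transition matrix by counting.  Entries into the product reset the walker
    to the unassociated shell, so the twin describes the recycled
    (nonequilibrium steady state) dynamics, with row B -> U.
    """
    if matrix is not None:
        if states is None:
            raise ValueError("states must accompany an explicit matrix")
        return MarkovOracle(tuple(states), np.asarray(matrix, dtype=float))
    if params is None:
        raise ValueError("either surrogate params or an explicit matrix is required")

    rng = np.random.default_rng(seed)
    labels = ["U"] + [f"I{lab}" for lab in
                      dict.fromkeys(("T",) + tuple(params.site_labels))] + ["B"]
    index = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    counts = np.zeros((n, n), dtype=float)

    n_walk = 64
    xy = sg.initial_pool(params, n_walk, rng, r_init=20.0)
    pool = sg.initial_pool(params, 50, rng, r_init=20.0)

    def observe(xy: np.ndarray) -> np.ndarray:
        r = np.hypot(xy[:, 0], xy[:, 1])
        site = sg.site_labels_xy(params, xy)
        out = np.empty(len(xy), dtype=np.int64)
        for k in range(len(xy)):
            if r[k] > sg.R_UNASSOCIATED:
                out[k] = index["U"]
            elif r[k] < sg.R_PRODUCT:
                out[k] = index["B"]
            else:
                out[k] = index[f"I{site[k]}"]
        return out

    prev = observe(xy)
    n_lags = max(1, n_samples // n_walk)
    for _ in range(n_lags):
        xy = sg.propagate_batch(params, xy, lag, rng)
        cur = observe(xy)
        np.add.at(counts, (prev, cur), 1.0)
        hit = cur == index["B"]
        if hit.any():
            xy[hit] = pool[rng.integers(0, len(pool), size=int(hit.sum()))]
            cur[hit] = observe(xy[hit])  # entry into B recorded; lineage restarts
        prev = cur

    counts[index["B"], :] = 0.0
    counts[index["B"], index["U"]] = 1.0  # recycling row
    row = counts.sum(axis=1)
    if np.any(row == 0):
        missing = [labels[k] for k in np.flatnonzero(row == 0)]
        raise RuntimeError(f"insufficient sampling: states never visited {missing}")
    return MarkovOracle(tuple(labels), counts / row[:, None])
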