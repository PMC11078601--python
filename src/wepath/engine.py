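"""Weighted-ensemble engine: binning, split/merge resampling, recycling, WESS.

The engine runs many weighted walkers in parallel.  After each resampling
interval tau it (1) logs conditional-flux events into labelled macrostates,
(2) recycles walkers that reached the target state (terminating them and
respawning their weight from the initial ensemble, which maintains a
nonequilibrium steady state), (3) bins walkers on a two-dimensional progress
coordinate, and (4) splits/merges within each bin to a target walker count,
conserving total weight exactly.  Everything is reproducible from the seed.

Flux attribution uses the standard last-in-state "color" scheme: a flux event
into state B is attributed to source A when the trajectory visited A more
recently than B.  Per-walker last-visit times for every labelled macrostate
are tracked, so conditional fluxes and source populations are available for
every ordered state pair simultaneously (overall reaction, activation and
dissociation steps from a single run).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.sparse import csgraph, csr_matrix

from . import surrogate as sg
from .markov import MarkovOracle

__all__ = [
    "BinMapper2D",
    "WalkerSet",
    "IterationRecord",
    "RunRecord",
    "LangevinSystem",
    "MarkovSystem",
    "assign_bins",
    "resample",
    "run_we",
    "continue_we",
    "wess_reweight",
    "default_mapper",
    "markov_mapper",
]

WEIGHT_TOL = 1e-12
_NEVER = np.iinfo(np.int64).min


# ---------------------------------------------------------------------------
# Binning

@dataclass(frozen=True)
class BinMapper2D:
    """Rectilinear bins over a 2-D progress coordinate.

    ``edges_dim1``/``edges_dim2`` are strictly increasing interior edges;
    the outermost bins are unbounded.  Boundary convention is left-closed,
    right-open: a coordinate exactly on an edge belongs to the higher bin.
    """

    edges_dim1: tuple[float, ...]
    edges_dim2: tuple[float, ...]

    def __post_init__(self) -> None:
        for edges in (self.edges_dim1, self.edges_dim2):
            e = np.asarray(edges, dtype=float)
            if e.size and np.any(np.diff(e) <= 0):
                raise ValueError("bin edges must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.edges_dim1) + 1, len(self.edges_dim2) + 1)

    @property
    def n_bins(self) -> int:
        return self.shape[0] * self.shape[1]

    def assign(self, pcoords: np.ndarray) -> np.ndarray:
        pcoords = np.asarray(pcoords, dtype=float)
        if not np.all(np.isfinite(pcoords)):
            raise ValueError("progress coordinates must be finite")
        i1 = np.searchsorted(self.edges_dim1, pcoords[:, 0], side="right")
        i2 = np.searchsorted(self.edges_dim2, pcoords[:, 1], side="right")
        return (i1 * self.shape[1] + i2).astype(np.int64)


def assign_bins(walker_pcoords: np.ndarray, mapper: BinMapper2D) -> np.ndarray:
    """Bin ids for an (n, 2) array of progress coordinates."""
    return mapper.assign(walker_pcoords)


def default_mapper() -> BinMapper2D:
    """Study bin layout: 0.25-wide bins below 6 on both distances (resolving
    the ion-pair and barrier regions), 2-wide bins above, unbounded edges."""
    fine = np.arange(1.0, 6.01, 0.25)
    coarse = np.arange(8.0, 20.1, 2.0)
    # outer shells stay resolved so unassociated weight is carried by many
    # light walkers (fine-grained collision flux) instead of a few heavy ones
    outer = np.arange(22.5, 58.0, 2.5)
    d1 = tuple(np.concatenate([fine, coarse, outer]))
    d2 = tuple(np.concatenate([np.arange(0.5, 6.01, 0.25), [8.0, 12.0, 20.0]]))
    return BinMapper2D(d1, d2)


def markov_mapper(n_states: int) -> BinMapper2D:
    """One bin per discrete state (pcoord dim 1 = state index)."""
    return BinMapper2D(tuple(np.arange(n_states - 1) + 0.5), ())


# ---------------------------------------------------------------------------
# Systems (propagator adapters)

class LangevinSystem:
    """Continuous surrogate propagator with tau = steps_per_iter * dt.

    The 2-D progress coordinate is (distance to the cation center, distance
    to the nearest site including the center) -- the surrogate analog of the
    minimum azide--carbon separations.  Frames are stored at tau/2 and tau;
    state evaluation and recycling happen at tau boundaries.
    """

    labels = sg.MACROSTATES

    def __init__(self, params: sg.SurrogateParams, pool: np.ndarray,
                 steps_per_iter: int = 250):
        self.params = params
        self.pool = np.asarray(pool, dtype=float)
        if self.pool.size == 0:
            raise ValueError("initial pool must be nonempty")
        self.steps_per_iter = int(steps_per_iter)
        self._sites = np.vstack([[0.0, 0.0], params.site_xy])

    @property
    def tau(self) -> float:
        """Resampling interval in reduced time units."""
        return self.steps_per_iter * self.params.dt

    def draw_pool(self, n: int, rng: np.random.Generator) -> np.ndarray:
        idx = rng.integers(0, len(self.pool), size=n)
        return self.pool[idx].copy()

    def sample_initial(self, n: int, rng: np.random.Generator) -> np.ndarray:
        k = min(n, len(self.pool))
        idx = rng.choice(len(self.pool), size=k, replace=False)
        return self.pool[idx].copy()

    def propagate(self, xy: np.ndarray, rng: np.random.Generator):
        half = self.steps_per_iter // 2
        mid = sg.propagate_batch(self.params, xy, max(half, 1), rng)
        end = sg.propagate_batch(self.params, mid,
                                 max(self.steps_per_iter - half, 1), rng)
        return mid, end

    def pcoord(self, xy: np.ndarray) -> np.ndarray:
        r = np.hypot(xy[:, 0], xy[:, 1])
        d2 = ((xy[:, None, :] - self._sites[None, :, :]) ** 2).sum(axis=2)
        return np.stack([r, np.sqrt(d2.min(axis=1))], axis=1)

    def macrostate_codes(self, xy: np.ndarray) -> np.ndarray:
        return sg.classify_r(np.hypot(xy[:, 0], xy[:, 1]))


class MarkovSystem:
    """Discrete-chain propagator for oracle-backed validation runs.

    ``state_map`` sends each oracle state label to a macrostate label (or
    None for unlabelled intermediates); ``source`` names the oracle state
    used as the initial/respawn pool.  One WE iteration is one lag step.
    """

    def __init__(self, oracle: MarkovOracle,
                 state_map: dict[str, "str | None"], source: str,
                 labels: tuple[str, ...] = sg.MACROSTATES):
        self.oracle = oracle
        self.labels = tuple(labels)
        self._cum = np.cumsum(oracle.transition_matrix, axis=1)
        codes = []
        for s in oracle.states:
            m = state_map.get(s)
            codes.append(self.labels.index(m) if m is not None else -1)
        self._codes = np.asarray(codes, dtype=np.int64)
        self._source = oracle.index(source)
        self.tau = 1.0

    def draw_pool(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.full((n, 1), float(self._source))

    sample_initial = draw_pool

    def propagate(self, states: np.ndarray, rng: np.random.Generator):
        idx = states[:, 0].astype(np.int64)
        u = rng.random(len(idx))
        nxt = (self._cum[idx] > u[:, None]).argmax(axis=1)
        out = nxt[:, None].astype(float)
        return out, out

    def pcoord(self, states: np.ndarray) -> np.ndarray:
        return np.stack([states[:, 0], np.zeros(len(states))], axis=1)

    def macrostate_codes(self, states: np.ndarray) -> np.ndarray:
        return self._codes[states[:, 0].astype(np.int64)]


# ---------------------------------------------------------------------------
# Records

@dataclass
class WalkerSet:
    """State of the live walker ensemble between iterations."""

    xy: np.ndarray          # (n, d) current configurations
    weights: np.ndarray     # (n,)
    last_visit: np.ndarray  # (n, S) iteration of last visit per macrostate
    prev_code: np.ndarray   # (n,) macrostate code of the current frame (-1 buffer)
    lineage: np.ndarray     # (n,) unique id per continuous trajectory
    parent: np.ndarray      # (n,) segment index in the previous iteration (-1 initial)
    spawn: np.ndarray       # (n,) walker was respawned from the pool last iteration

    def copy(self) -> "WalkerSet":
        return WalkerSet(*(a.copy() for a in (
            self.xy, self.weights, self.last_visit, self.prev_code,
            self.lineage, self.parent, self.spawn)))


@dataclass
class Walker:
    """Single-trajectory view used at API boundaries and in tests."""

    config: np.ndarray
    pcoord: np.ndarray
    weight: float
    lineage_id: int
    last_macrostate: "str | None"


@dataclass
class IterationRecord:
    """Everything logged for one WE iteration (arrays share walker order)."""

    parent: np.ndarray       # index into previous iteration's walkers (-1: initial set)
    spawn: np.ndarray        # segment began fresh from the pool
    x_mid: np.ndarray        # frame at tau/2 (contact analysis)
    x_end: np.ndarray        # frame at tau, before recycling
    weights: np.ndarray
    pcoords: np.ndarray      # after recycling (what binning saw)
    bin_ids: np.ndarray
    last_visit: np.ndarray   # (n, S), after recycling
    recycled: np.ndarray     # segment ended in the target and was respawned
    flux: np.ndarray         # (S, S) pairwise-conditional flux weight, [src, dst]
    pop_pair: np.ndarray     # (S, S) weight with src visited more recently than dst
    pop_label: np.ndarray    # (S,) last-labelled-state populations
    total_weight: float

    @property
    def n_walkers(self) -> int:
        return len(self.weights)


@dataclass
class RunRecord:
    """Complete per-iteration ledger of one WE simulation."""

    labels: tuple[str, ...]
    tau: float
    initial_xy: np.ndarray
    initial_weights: np.ndarray
    iterations: list[IterationRecord] = field(default_factory=list)
    final_state: "WalkerSet | None" = None
    meta: dict = field(default_factory=dict)

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    def state_index(self, label: str) -> int:
        return self.labels.index(label)

    def flux_series(self, source: str, target: str) -> np.ndarray:
        i, j = self.state_index(source), self.state_index(target)
        return np.array([it.flux[i, j] for it in self.iterations])

    def population_series(self, source: str, versus: "str | None" = None) -> np.ndarray:
        i = self.state_index(source)
        if versus is None:
            return np.array([it.pop_label[i] for it in self.iterations])
        j = self.state_index(versus)
        return np.array([it.pop_pair[i, j] for it in self.iterations])

    def recycled_weight_series(self) -> np.ndarray:
        return np.array([float(it.weights[it.recycled].sum())
                         for it in self.iterations])

    # -- persistence ------------------------------------------------------
    def to_hdf5(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["labels"] = json.dumps(list(self.labels))
            f.attrs["tau"] = self.tau
            f.attrs["meta"] = json.dumps(self.meta)
            f.create_dataset("initial_xy", data=self.initial_xy)
            f.create_dataset("initial_weights", data=self.initial_weights)
            for t, it in enumerate(self.iterations, start=1):
                g = f.create_group(f"iterations/{t:06d}")
                for name in ("parent", "spawn", "x_mid", "x_end", "weights",
                             "pcoords", "bin_ids", "last_visit", "recycled",
                             "flux", "pop_pair", "pop_label"):
                    g.create_dataset(name, data=getattr(it, name))
                g.attrs["total_weight"] = it.total_weight
            if self.final_state is not None:
                g = f.create_group("final_state")
                fs = self.final_state
                for name in ("xy", "weights", "last_visit", "prev_code",
                             "lineage", "parent", "spawn"):
                    g.create_dataset(name, data=getattr(fs, name))

    @classmethod
    def from_hdf5(cls, path: str) -> "RunRecord":
        with h5py.File(path, "r") as f:
            rec = cls(
                labels=tuple(json.loads(f.attrs["labels"])),
                tau=float(f.attrs["tau"]),
                initial_xy=f["initial_xy"][...],
                initial_weights=f["initial_weights"][...],
                meta=json.loads(f.attrs["meta"]),
            )
            if "iterations" in f:
                for key in sorted(f["iterations"]):
                    g = f["iterations"][key]
                    rec.iterations.append(IterationRecord(
                        parent=g["parent"][...], spawn=g["spawn"][...].astype(bool),
                        x_mid=g["x_mid"][...], x_end=g["x_end"][...],
                        weights=g["weights"][...], pcoords=g["pcoords"][...],
                        bin_ids=g["bin_ids"][...], last_visit=g["last_visit"][...],
                        recycled=g["recycled"][...].astype(bool),
                        flux=g["flux"][...], pop_pair=g["pop_pair"][...],
                        pop_label=g["pop_label"][...],
                        total_weight=float(g.attrs["total_weight"])))
            if "final_state" in f:
                g = f["final_state"]
                rec.final_state = WalkerSet(
                    xy=g["xy"][...], weights=g["weights"][...],
                    last_visit=g["last_visit"][...],
                    prev_code=g["prev_code"][...],
                    lineage=g["lineage"][...], parent=g["parent"][...],
                    spawn=g["spawn"][...].astype(bool))
        return rec


# ---------------------------------------------------------------------------
# Resampling

def resample(weights: np.ndarray, bin_ids: np.ndarray, target: int,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Split/merge every occupied bin to exactly ``target`` walkers.

    Returns ``(parent_index, new_weights)``.  Splitting apportions the
    target count among a bin's walkers by weight (largest remainder, at
    least one copy each) and divides each walker's weight equally among its
    copies.  Merging repeatedly combines the two lowest-weight walkers; the
    survivor is chosen with probability proportional to weight and absorbs
    both weights.  Per-bin weight is conserved exactly; empty bins stay
    empty.  Expected post-resampling weight of any walker equals its
    pre-resampling weight, so no bias is introduced.
    """
    if target < 1:
        raise ValueError("target walker count must be >= 1")
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("walker weights must be positive")
    out_parent: list[int] = []
    out_weight: list[float] = []
    for b in np.unique(bin_ids):
        idx = np.flatnonzero(bin_ids == b)
        w = weights[idx]
        n = len(idx)
        if n == target:
            out_parent.extend(idx)
            out_weight.extend(w)
        elif n < target:
            frac = target * w / w.sum()
            copies = np.maximum(np.floor(frac).astype(int), 1)
            while copies.sum() < target:  # largest remainders, stable order
                rem = frac - copies
                copies[int(np.argmax(rem))] += 1
            while copies.sum() > target:
                adjustable = np.flatnonzero(copies > 1)
                rem = frac[adjustable] - copies[adjustable]
                copies[adjustable[int(np.argmin(rem))]] -= 1
            for i, c in zip(idx, copies):
                out_parent.extend([i] * c)
                out_weight.extend([weights[i] / c] * c)
        else:
            order = list(np.argsort(w, kind="stable"))
            pool_idx = [idx[k] for k in order]
            pool_w = [w[k] for k in order]
            while len(pool_idx) > target:
                w0, w1 = pool_w[0], pool_w[1]
                keep = 0 if rng.random() < w0 / (w0 + w1) else 1
                survivor = pool_idx[keep]
                merged = w0 + w1
                del pool_idx[:2], pool_w[:2]
                # re-insert survivor keeping the pool sorted by weight
                pos = int(np.searchsorted(pool_w, merged))
                pool_idx.insert(pos, survivor)
                pool_w.insert(pos, merged)
            out_parent.extend(pool_idx)
            out_weight.extend(pool_w)
    return np.asarray(out_parent, dtype=np.int64), np.asarray(out_weight, dtype=float)


# ---------------------------------------------------------------------------
# Main loop

def run_we(system, mapper: BinMapper2D, n_iterations: int,
           n_init_walkers: int = 5, seed: int = 0, target_per_bin: int = 5,
           target_state: str = "product",
           init_state: "WalkerSet | None" = None,
           lineage_offset: int = 0) -> RunRecord:
    """Run a weighted-ensemble simulation and return its complete record.

    Each iteration: propagate tau -> log conditional-flux entries at the tau
    frame -> recycle walkers in ``target_state`` (respawn from the pool with
    unchanged weight) -> bin on the progress coordinate -> split/merge to
    ``target_per_bin`` per occupied bin.  Total weight is 1 at every
    iteration boundary to within 1e-12 by construction.
    """
    rng = np.random.default_rng(seed)
    labels = tuple(system.labels)
    S = len(labels)
    target_code = labels.index(target_state)

    if init_state is None:
        xy0 = system.sample_initial(n_init_walkers, rng)
        n0 = len(xy0)
        codes0 = system.macrostate_codes(xy0)
        lv0 = np.full((n0, S), _NEVER, dtype=np.int64)
        for k in range(n0):
            if codes0[k] >= 0:
                lv0[k, codes0[k]] = 0
        live = WalkerSet(
            xy=xy0, weights=np.full(n0, 1.0 / n0),
            last_visit=lv0, prev_code=codes0,
            lineage=np.arange(n0, dtype=np.int64) + lineage_offset,
            parent=np.arange(n0, dtype=np.int64),
            spawn=np.zeros(n0, dtype=bool))
        next_lineage = n0 + lineage_offset
    else:
        live = init_state.copy()
        live.parent = np.arange(len(live.weights), dtype=np.int64)
        next_lineage = int(live.lineage.max()) + 1

    record = RunRecord(labels=labels, tau=float(system.tau),
                       initial_xy=live.xy.copy(),
                       initial_weights=live.weights.copy(),
                       meta={"seed": int(seed), "target_state": target_state,
                             "target_per_bin": int(target_per_bin)})

    for t in range(1, n_iterations + 1):
        x_mid, x_end = system.propagate(live.xy, rng)
        codes = system.macrostate_codes(x_end)

        flux = np.zeros((S, S))
        entered = (codes >= 0) & (codes != live.prev_code)
        for k in np.flatnonzero(entered):
            s = codes[k]
            newer = live.last_visit[k] > live.last_visit[k, s]
            for a in np.flatnonzero(newer):
                flux[a, s] += live.weights[k]
            live.last_visit[k, s] = t
        live.prev_code = codes.copy()

        # recycling: terminate target-state walkers, respawn from the pool
        recycled = codes == target_code
        spawn_next = np.zeros(len(codes), dtype=bool)
        live.xy = x_end.copy()
        if recycled.any():
            nr = int(recycled.sum())
            respawn = system.draw_pool(nr, rng)
            live.xy[recycled] = respawn
            spawn_codes = system.macrostate_codes(respawn)
            lv = np.full((nr, S), _NEVER, dtype=np.int64)
            for k in range(nr):
                if spawn_codes[k] >= 0:
                    lv[k, spawn_codes[k]] = t
            live.last_visit[recycled] = lv
            live.prev_code[recycled] = spawn_codes
            live.lineage[recycled] = np.arange(nr) + next_lineage
            next_lineage += nr
            spawn_next[recycled] = True

        pop_pair = np.zeros((S, S))
        for a in range(S):
            for b in range(S):
                if a != b:
                    mask = live.last_visit[:, a] > live.last_visit[:, b]
                    pop_pair[a, b] = live.weights[mask].sum()
        cur_label = np.argmax(live.last_visit, axis=1)
        has_label = live.last_visit.max(axis=1) > _NEVER
        pop_label = np.zeros(S)
        for a in range(S):
            pop_label[a] = live.weights[has_label & (cur_label == a)].sum()

        pcoords = system.pcoord(live.xy)
        bin_ids = mapper.assign(pcoords)

        total = float(live.weights.sum())
        record.iterations.append(IterationRecord(
            parent=live.parent.copy(), spawn=live.spawn.copy(),
            x_mid=x_mid, x_end=x_end, weights=live.weights.copy(),
            pcoords=pcoords, bin_ids=bin_ids,
            last_visit=live.last_visit.copy(), recycled=recycled,
            flux=flux, pop_pair=pop_pair, pop_label=pop_label,
            total_weight=total))

        parent_idx, new_w = resample(live.weights, bin_ids, target_per_bin, rng)
        live = WalkerSet(
            xy=live.xy[parent_idx].copy(), weights=new_w,
            last_visit=live.last_visit[parent_idx].copy(),
            prev_code=live.prev_code[parent_idx].copy(),
            lineage=live.lineage[parent_idx].copy(),
            parent=parent_idx, spawn=spawn_next[parent_idx])

    record.final_state = live
    return record


def continue_we(record: RunRecord, system, mapper: BinMapper2D,
                n_iterations: int, seed: int,
                target_per_bin: "int | None" = None) -> RunRecord:
    """Extend a run from its final walker state (e.g. after WESS reweighting).

    Returns a new RunRecord containing only the continuation iterations.
    """
    if record.final_state is None:
        raise ValueError("record has no final walker state to continue from")
    return run_we(system, mapper, n_iterations,
                  seed=seed,
                  target_per_bin=target_per_bin or record.meta.get("target_per_bin", 5),
                  target_state=record.meta.get("target_state", "product"),
                  init_state=record.final_state,
                  lineage_offset=int(record.final_state.lineage.max()) + 1)


# ---------------------------------------------------------------------------
# WESS steady-state reweighting

def wess_reweight(record: RunRecord, window_fraction: float = 0.75
                  ) -> tuple["WalkerSet", dict]:
    """Reweight the final walkers toward the steady-state bin occupancies.

    Builds the bin-to-bin transition-probability matrix from the trailing
    ``window_fraction`` of iterations (weight flowing from each walker's
    parent bin to its own bin, recycling jumps included), solves for the
    stationary occupancy vector, and rescales each bin's walkers so bin
    weights match it, preserving relative weights within a bin.  Returns the
    reweighted walker set and a diagnostics dict with the occupied bins,
    their transition matrix and the stationary solution.
    """
    if not 0.0 < window_fraction < 1.0:
        raise ValueError("window_fraction must lie in (0, 1)")
    N = record.n_iterations
    if N < 1.0 / (1.0 - window_fraction):
        raise ValueError("record too short for the requested window")
    if record.final_state is None:
        raise ValueError("record has no final walker state")
    t0 = int(np.ceil((1.0 - window_fraction) * N))  # 1-based first window iter

    nb = max(int(it.bin_ids.max()) for it in record.iterations) + 1
    flow = np.zeros((nb, nb))
    for t in range(max(t0, 1), N):  # transitions t -> t+1 (0-based t-1 -> t)
        prev_bins = record.iterations[t - 1].bin_ids
        it = record.iterations[t]
        src = prev_bins[it.parent]
        np.add.at(flow, (src, it.bin_ids), it.weights)
    occupied = np.flatnonzero(flow.sum(axis=1) + flow.sum(axis=0) > 0)
    if occupied.size == 0:
        raise ValueError("no transitions in the reweighting window")
    sub = flow[np.ix_(occupied, occupied)]
    rowsum = sub.sum(axis=1)
    if np.any(rowsum == 0):
        occupied = occupied[rowsum > 0]
        sub = flow[np.ix_(occupied, occupied)]
        rowsum = sub.sum(axis=1)
    T = sub / rowsum[:, None]
    n_comp, _ = csgraph.connected_components(csr_matrix(T > 0),
                                             directed=True, connection="strong")
    if n_comp != 1:
        raise ValueError("bin transition matrix is reducible: sampling is "
                         "disconnected over the reweighting window")
    w_eig, v = np.linalg.eig(T.T)
    k = int(np.argmin(np.abs(w_eig - 1.0)))
    pi = np.abs(np.real(v[:, k]))
    pi = pi / pi.sum()

    fs = record.final_state.copy()
    final_bins = record.iterations[-1].bin_ids[fs.parent]
    bin_of = {int(b): p for b, p in zip(occupied, pi)}
    new_w = fs.weights.copy()
    for b in np.unique(final_bins):
        mask = final_bins == b
        cur = fs.weights[mask].sum()
        tgt = bin_of.get(int(b))
        if tgt is not None and cur > 0:
            new_w[mask] *= tgt / cur
    new_w /= new_w.sum()  # bins absent from the window keep relative weight
    fs.weights = new_w
    info = {"occupied_bins": occupied, "transition_matrix": T,
            "stationary": pi, "window_start_iteration": max(t0, 1) + 1}
    return fs, info
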