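"""Shared fixtures: Markov oracle chains, replicated WE runs, hand-built records."""

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from wepath import surrogate as sg
from wepath.engine import (IterationRecord, LangevinSystem, MarkovSystem,
                           RunRecord, WalkerSet, default_mapper, markov_mapper,
                           run_we)
from wepath.markov import MarkovOracle

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

#: oracle-state -> macrostate mapping shared by all Markov-backed runs
SMAP = {"U": "unassociated", "I": "ion_pair", "B": "product"}

# Fast chain: U <-> I -> B with recycling row B -> U hand-specified.
CHAIN3_P = np.array([[0.9, 0.1, 0.0],
                     [0.3, 0.5, 0.2],
                     [1.0, 0.0, 0.0]])
# ~150x slower chain (MFPT U->B = 4750 lags vs 30).
SLOW_P = np.array([[0.98, 0.02, 0.0],
                   [0.45, 0.545, 0.005],
                   [1.0, 0.0, 0.0]])


@pytest.fixture(scope="session")
def chain3() -> MarkovOracle:
    return MarkovOracle(("U", "I", "B"), CHAIN3_P)


@pytest.fixture(scope="session")
def slow_chain() -> MarkovOracle:
    return MarkovOracle(("U", "I", "B"), SLOW_P)


def markov_replicates(chain, n_replicates=5, n_iterations=600, seed0=100,
                      source="U", target_state="product", target_per_bin=20):
    recs = []
    for k in range(n_replicates):
        system = MarkovSystem(chain, SMAP, source=source)
        recs.append(run_we(system, markov_mapper(chain.n_states), n_iterations,
                           seed=seed0 + k, target_per_bin=target_per_bin,
                           target_state=target_state))
    return recs


@pytest.fixture(scope="session")
def chain3_runs(chain3):
    """Product-recycled WE replicates on the fast chain (overall and
    activation rates, percent-productive checks)."""
    return markov_replicates(chain3)


@pytest.fixture(scope="session")
def chain3_runs_to_u(chain3):
    """U-recycled WE replicates started in I (dissociation rate k_minus1)."""
    return markov_replicates(chain3, source="I", target_state="unassociated",
                             seed0=200)


@pytest.fixture(scope="session")
def slow_runs(slow_chain):
    return markov_replicates(slow_chain, n_iterations=900, seed0=300)


@pytest.fixture(scope="session")
def slow_runs_to_u(slow_chain):
    return markov_replicates(slow_chain, source="I",
                             target_state="unassociated", seed0=400)


@pytest.fixture(scope="session")
def h_params():
    return sg.make_surrogate("H")


@pytest.fixture(scope="session")
def h_record(h_params):
    """One modest surrogate WE run of the unsubstituted preset."""
    pool = sg.initial_pool(h_params, 50, seed=5)
    system = LangevinSystem(h_params, pool)
    return run_we(system, default_mapper(), 80, seed=17)


# ---------------------------------------------------------------------------
# Hand-built records for kinetics/WESS unit tests

LABELS = ("unassociated", "ion_pair", "product")


def make_record(n_iterations: int, tau: float = 1.0, flux: dict = None,
                pop_pair: dict = None, pop_label: dict = None) -> RunRecord:
    """Minimal RunRecord with prescribed per-iteration fluxes and populations.

    ``flux``/``pop_pair`` map (source, target) label pairs to scalars or
    per-iteration arrays; geometry fields are placeholders.
    """
    S = len(LABELS)
    idx = {lab: k for k, lab in enumerate(LABELS)}
    rec = RunRecord(labels=LABELS, tau=tau,
                    initial_xy=np.zeros((1, 2)), initial_weights=np.ones(1))

    def at(table, t):
        if table is None:
            return {}
        return {k: (np.asarray(v)[t] if np.ndim(v) else v)
                for k, v in table.items()}

    for t in range(n_iterations):
        F = np.zeros((S, S))
        for (a, b), v in at(flux, t).items():
            F[idx[a], idx[b]] = v
        PP = np.zeros((S, S))
        for (a, b), v in at(pop_pair, t).items():
            PP[idx[a], idx[b]] = v
        PL = np.zeros(S)
        for a, v in at(pop_label, t).items():
            PL[idx[a]] = v
        rec.iterations.append(IterationRecord(
            parent=np.zeros(1, dtype=np.int64), spawn=np.zeros(1, dtype=bool),
            x_mid=np.zeros((1, 2)), x_end=np.zeros((1, 2)),
            weights=np.ones(1), pcoords=np.zeros((1, 2)),
            bin_ids=np.zeros(1, dtype=np.int64),
            last_visit=np.zeros((1, S), dtype=np.int64),
            recycled=np.zeros(1, dtype=bool), flux=F, pop_pair=PP,
            pop_label=PL, total_weight=1.0))
    return rec


def make_two_bin_record(T: np.ndarray, bin_weights: np.ndarray,
                        n_iterations: int = 8) -> RunRecord:
    """Record whose bin-to-bin weight flow follows the 2x2 matrix ``T``
    exactly, with per-bin weights ``bin_weights`` at every iteration.

    Four walkers per iteration: two per bin, encoding the four flows
    w_i * T_ij; parents are wired so flow (i -> j) leaves from bin i.
    """
    w = np.array([bin_weights[0] * T[0, 0], bin_weights[1] * T[1, 0],
                  bin_weights[0] * T[0, 1], bin_weights[1] * T[1, 1]])
    bins = np.array([0, 0, 1, 1], dtype=np.int64)
    # child k draws from a parent that sat in the source bin of its flow
    parent = np.array([0, 2, 0, 2], dtype=np.int64)
    S = len(LABELS)
    rec = RunRecord(labels=LABELS, tau=1.0,
                    initial_xy=np.zeros((4, 2)), initial_weights=w.copy())
    for _ in range(n_iterations):
        rec.iterations.append(IterationRecord(
            parent=parent.copy(), spawn=np.zeros(4, dtype=bool),
            x_mid=np.zeros((4, 2)), x_end=np.zeros((4, 2)),
            weights=w.copy(), pcoords=np.zeros((4, 2)), bin_ids=bins.copy(),
            last_visit=np.zeros((4, S), dtype=np.int64),
            recycled=np.zeros(4, dtype=bool), flux=np.zeros((S, S)),
            pop_pair=np.zeros((S, S)), pop_label=np.zeros(S),
            total_weight=float(w.sum())))
    rec.final_state = WalkerSet(
        xy=np.zeros((4, 2)), weights=w.copy(),
        last_visit=np.zeros((4, S), dtype=np.int64),
        prev_code=np.zeros(4, dtype=np.int64),
        lineage=np.arange(4, dtype=np.int64),
        parent=np.arange(4, dtype=np.int64),  # final walkers are the segments
        spawn=np.zeros(4, dtype=bool))
    return rec
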