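"""Hill-relation kinetics from weighted-ensemble run records.

Rate constants follow from the Hill relation: at a nonequilibrium steady
state maintained by recycling, the conditional flux into a target state B
for trajectories most recently in source state A, normalized by the
steady-state population of A-tagged trajectories, equals 1/MFPT(A -> B).
Both flux and population are accumulated as running averages over the run.

Bimolecular constants (overall association and collision rates) are the
unimolecular Hill rates divided by the effective reactant concentration
``C0 = 1/(N_A V)`` of one reactant pair in the simulation volume.

Uncertainties over independent replicate simulations use the Bayesian
bootstrap: Dirichlet(1, ..., 1) weights over replicates, with the 95%
credibility region given by the 2.5th/97.5th percentiles of the weighted
means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import RunRecord

__all__ = [
    "AVOGADRO",
    "RateEstimate",
    "conditional_flux",
    "steady_state_population",
    "hill_rate",
    "rate_series",
    "bimolecular_rate",
    "effective_concentration",
    "volume_from_concentration",
    "percent_productive",
    "bayesian_bootstrap",
    "estimate_rates",
    "addition_site_ratios",
    "convergence_series",
]

AVOGADRO = 6.02214076e23

#: transitions reported by estimate_rates: name -> (source, target, bimolecular)
RATE_DEFINITIONS = {
    "k_rxn": ("unassociated", "product", True),
    "k_1": ("unassociated", "ion_pair", True),
    "k_minus1": ("ion_pair", "unassociated", False),
    "k_2": ("ion_pair", "product", False),
}


@dataclass
class RateEstimate:
    """A rate constant with replicate values and 95% credibility region."""

    name: str
    replicates: np.ndarray
    mean: float
    cr95: tuple[float, float]
    bimolecular: bool = False

    @property
    def cr_offsets(self) -> tuple[float, float]:
        """Asymmetric offsets (below, above) the mean, reporting style
        ``mean ± [lower, upper]``."""
        return (self.mean - self.cr95[0], self.cr95[1] - self.mean)


def conditional_flux(record: RunRecord, source: str, target: str,
                     return_series: bool = False):
    """Running-average conditional flux source -> target, per unit time.

    Cumulative weight entering ``target`` attributed to ``source`` (last-in
    state tagging), divided by elapsed time.  Returns the final value, or
    the full per-iteration series when ``return_series`` is set.
    """
    events = record.flux_series(source, target)
    t = np.arange(1, len(events) + 1) * record.tau
    series = np.cumsum(events) / t
    return series if return_series else float(series[-1]) if len(series) else 0.0


def steady_state_population(record: RunRecord, state: str,
                            versus: "str | None" = None,
                            return_series: bool = False):
    """Running-average steady-state population of ``state``.

    With ``versus`` given, uses pairwise last-in-state tagging (weight of
    trajectories that visited ``state`` more recently than ``versus``) --
    the normalization the Hill relation requires for the pair.  Without it,
    populations by last-visited labelled macrostate are returned.
    """
    p = record.population_series(state, versus)
    series = np.cumsum(p) / np.arange(1, len(p) + 1)
    return series if return_series else float(series[-1]) if len(series) else 0.0


def hill_rate(flux: float, p_source: float) -> float:
    """Unimolecular rate flux / p_source = 1/MFPT(A -> B) at steady state."""
    if p_source <= 0:
        raise ZeroDivisionError("source-state population is zero")
    return flux / p_source


def rate_series(record: RunRecord, source: str, target: str) -> np.ndarray:
    """Per-iteration running-average Hill rate for source -> target."""
    f = conditional_flux(record, source, target, return_series=True)
    p = steady_state_population(record, source, versus=target, return_series=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(p > 0, f / np.where(p > 0, p, 1.0), 0.0)
    return out


def bimolecular_rate(rate: float, c0: float) -> float:
    """Convert a Hill rate to a bimolecular constant (per concentration-time)."""
    if c0 <= 0:
        raise ZeroDivisionError("effective concentration must be positive")
    return rate / c0


def effective_concentration(volume_A3: float) -> float:
    """Effective molar concentration C0 = 1/(N_A V) of one pair in a box.

    ``volume_A3`` is the simulation-cell volume in cubic Angstrom; the
    result is in mol/L (1 A^3 = 1e-27 L).
    """
    if volume_A3 <= 0:
        raise ValueError("volume must be positive")
    return 1.0 / (AVOGADRO * volume_A3 * 1e-27)


def volume_from_concentration(c0_molar: float) -> float:
    """Inverse of :func:`effective_concentration`; volume in cubic Angstrom."""
    if c0_molar <= 0:
        raise ValueError("concentration must be positive")
    return 1.0 / (AVOGADRO * c0_molar * 1e-27)


def percent_productive(record: RunRecord, return_series: bool = False):
    """Percent productive collisions: 100 x Flux(U -> B) / Flux(U -> I).

    The denominator counts every entry of an unassociated-tagged trajectory
    into the ion-pair shell (each re-collision counts); at steady state the
    ratio equals the commitment probability of a fresh collision to reach
    the product before re-separating.
    """
    num = np.cumsum(record.flux_series("unassociated", "product"))
    den = np.cumsum(record.flux_series("unassociated", "ion_pair"))
    if den.size == 0 or den[-1] <= 0:
        raise ZeroDivisionError("no reactant collisions recorded")
    with np.errstate(divide="ignore", invalid="ignore"):
        series = 100.0 * np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return series if return_series else float(series[-1])


def bayesian_bootstrap(replicate_values, n_boot: int = 10_000, seed: int = 0
                       ) -> tuple[float, tuple[float, float]]:
    """Mean and 95% Bayesian-bootstrap credibility region over replicates.

    Draws Dirichlet(1, ..., 1) weights over the replicates ``n_boot`` times;
    the region is the [2.5, 97.5] percentile band of the weighted means.
    Scale-equivariant by construction.
    """
    values = np.asarray(replicate_values, dtype=float)
    if values.size < 2:
        raise ValueError("at least two replicates are required")
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.ones(values.size), size=n_boot)
    means = w @ values
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(values.mean()), (float(lo), float(hi))


def bootstrap_se(replicate_values, n_boot: int = 10_000, seed: int = 0) -> float:
    """Posterior standard deviation of the Bayesian-bootstrap mean."""
    values = np.asarray(replicate_values, dtype=float)
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.ones(values.size), size=n_boot)
    return float(np.std(w @ values))


def estimate_rates(records: list[RunRecord], c0: float = 1.0,
                   n_boot: int = 10_000, seed: int = 0
                   ) -> dict[str, RateEstimate]:
    """All four rate constants with credibility regions from replicate runs.

    k_rxn and k_1 are bimolecular (normalized by ``c0``); k_minus1 and k_2
    are unimolecular.  Credibility regions require >= 2 replicates and are
    reported as NaN bounds otherwise.
    """
    out: dict[str, RateEstimate] = {}
    for name, (src, dst, bimol) in RATE_DEFINITIONS.items():
        vals = []
        for rec in records:
            f = conditional_flux(rec, src, dst)
            p = steady_state_population(rec, src, versus=dst)
            r = hill_rate(f, p) if p > 0 else 0.0
            vals.append(bimolecular_rate(r, c0) if bimol else r)
        vals = np.asarray(vals)
        if len(vals) >= 2:
            mean, cr = bayesian_bootstrap(vals, n_boot=n_boot, seed=seed)
        else:
            mean, cr = float(vals.mean()), (float("nan"), float("nan"))
        out[name] = RateEstimate(name, vals, mean, cr, bimolecular=bimol)
    return out


def rates_to_dataframe(estimates: dict[str, RateEstimate]):
    """Tabular (CSV-ready) form of a set of rate estimates."""
    import pandas as pd
    rows = []
    for name, est in estimates.items():
        below, above = est.cr_offsets
        rows.append({"rate": name, "mean": est.mean,
                     "cr95_lower": est.cr95[0], "cr95_upper": est.cr95[1],
                     "cr_below": below, "cr_above": above,
                     "bimolecular": est.bimolecular,
                     **{f"replicate_{k + 1}": v
                        for k, v in enumerate(est.replicates)}})
    return pd.DataFrame(rows).set_index("rate")


def addition_site_ratios(site_labels, weights,
                         symmetry_groups: list[tuple[str, ...]]
                         ) -> dict[str, float]:
    """Relative azide-addition flux per symmetry-equivalent site group.

    Sums pathway weights per site label, averages the totals within each
    symmetry-equivalence group (symmetric sites share the flux), and
    normalizes so the highest-flux group reports 1.0.
    """
    site_labels = list(site_labels)
    weights = np.asarray(weights, dtype=float)
    if len(site_labels) == 0:
        raise ValueError("empty pathway ensemble")
    per_site: dict[str, float] = {}
    for lab, w in zip(site_labels, weights):
        per_site[lab] = per_site.get(lab, 0.0) + float(w)
    group_flux = {
        "/".join(group): float(np.mean([per_site.get(g, 0.0) for g in group]))
        for group in symmetry_groups
    }
    top = max(group_flux.values())
    if top <= 0:
        raise ValueError("no addition flux recorded at any site")
    return {k: v / top for k, v in group_flux.items()}


def convergence_series(records: "RunRecord | list[RunRecord]",
                       source: str = "unassociated", target: str = "product",
                       tail_fraction: float = 0.25, rel_tol: float = 0.10
                       ) -> tuple[np.ndarray, bool]:
    """Replicate-averaged running k_rxn versus iteration, with plateau flag.

    The flag is true when, over the trailing ``tail_fraction`` of the
    series, the spread (max - min) is below ``rel_tol`` of the final value.
    """
    if isinstance(records, RunRecord):
        records = [records]
    if min(r.n_iterations for r in records) < 50:
        raise ValueError("convergence assessment needs >= 50 iterations")
    n = min(r.n_iterations for r in records)
    series = np.mean([rate_series(r, source, target)[:n] for r in records], axis=0)
    tail = series[int(np.floor(n * (1.0 - tail_fraction))):]
    final = series[-1]
    plateau = bool(final > 0 and (tail.max() - tail.min()) < rel_tol * abs(final))
    return series, plateau
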