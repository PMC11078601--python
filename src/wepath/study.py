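"""End-to-end study orchestration: replicated WE runs, WESS, rates, clustering.

Mirrors the full study design: for each cation preset, generate a 50-member
unassociated starting ensemble, run five independent weighted-ensemble
simulations, reweight each with WESS after the main run, continue for extra
iterations to confirm steadiness, then compute rate constants with
credibility regions, percent productive collisions, pathway classes and
contact distributions, consolidated into one report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import kinetics, pathways as pw, surrogate as sg
from .engine import (LangevinSystem, RunRecord, continue_we, default_mapper,
                     run_we, wess_reweight)

log = logging.getLogger("wepath")

__all__ = ["StudyConfig", "run_study", "run_replicate", "report", "load_config"]


@dataclass
class StudyConfig:
    """Study design parameters (defaults follow the reference protocol)."""

    presets: tuple[str, ...] = ("OCH3", "H", "CF3")
    n_replicates: int = 5
    n_iterations: int = 500
    post_wess_iterations: int = 100
    walkers_per_bin: int = 5
    steps_per_iteration: int = 250   # tau = 0.5 reduced ps at dt = 0.002
    n_init_walkers: int = 5
    pool_size: int = 50
    wess_window: float = 0.75
    c0: float = 1.0                  # effective concentration, reduced units
    max_cluster_paths: int = 150     # subsample cap for the O(n^2) distances
    seed: int = 1
    out_dir: "str | None" = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.n_iterations < 1:
            raise ValueError("replicates and iterations must be positive")

    def replicate_seeds(self, preset_index: int) -> list[int]:
        base = (self.seed * 100_003 + preset_index * 1009) % (2 ** 31 - 1)
        return [(base + 7919 * k) % (2 ** 31 - 1) for k in range(self.n_replicates)]


def load_config(path: str) -> StudyConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if "presets" in raw:
        raw["presets"] = tuple(raw["presets"])
    return StudyConfig(**raw)


def run_replicate(params: sg.SurrogateParams, pool: np.ndarray,
                  config: StudyConfig, seed: int
                  ) -> tuple[RunRecord, "RunRecord | None"]:
    """One WE simulation: main run, WESS reweight, post-reweight extension."""
    system = LangevinSystem(params, pool, steps_per_iter=config.steps_per_iteration)
    mapper = default_mapper()
    rec = run_we(system, mapper, config.n_iterations,
                 n_init_walkers=config.n_init_walkers, seed=seed,
                 target_per_bin=config.walkers_per_bin)
    post = None
    if config.post_wess_iterations > 0:
        try:
            reweighted, _ = wess_reweight(rec, config.wess_window)
            rec_w = RunRecord(rec.labels, rec.tau, rec.initial_xy,
                              rec.initial_weights, rec.iterations, reweighted,
                              dict(rec.meta))
            post = continue_we(rec_w, system, mapper,
                               config.post_wess_iterations, seed=seed + 1)
        except ValueError as exc:  # disconnected sampling: keep the main run
            log.warning("WESS reweighting skipped: %s", exc)
    return rec, post


def _preset_study(preset: str, config: StudyConfig, preset_index: int) -> dict:
    params = sg.make_surrogate(preset)
    pool_seed = (config.seed * 613 + preset_index) % (2 ** 31 - 1)
    pool = sg.initial_pool(params, config.pool_size, seed=pool_seed)
    records: list[RunRecord] = []
    post_records: list[RunRecord] = []
    for seed in config.replicate_seeds(preset_index):
        log.info("preset %s: replicate seed %d", preset, seed)
        rec, post = run_replicate(params, pool, config, seed)
        records.append(rec)
        if post is not None:
            post_records.append(post)

    rates = kinetics.estimate_rates(records, c0=config.c0, seed=config.seed)
    out: dict = {
        "preset": preset,
        "rates": {
            name: {"mean": est.mean, "cr95": list(est.cr95),
                   "replicates": est.replicates.tolist(),
                   "bimolecular": est.bimolecular}
            for name, est in rates.items()},
    }
    if post_records:
        post_rates = kinetics.estimate_rates(post_records, c0=config.c0,
                                             seed=config.seed)
        out["rates_post_wess"] = {
            name: {"mean": est.mean, "cr95": list(est.cr95)}
            for name, est in post_rates.items()}

    pp_vals = []
    for rec in records:
        try:
            pp_vals.append(kinetics.percent_productive(rec))
        except ZeroDivisionError:
            pass
    if len(pp_vals) >= 2:
        mean, cr = kinetics.bayesian_bootstrap(pp_vals, seed=config.seed)
        out["percent_productive"] = {"mean": mean, "cr95": list(cr),
                                     "replicates": pp_vals}
    elif pp_vals:
        out["percent_productive"] = {"mean": pp_vals[0], "cr95": None,
                                     "replicates": pp_vals}

    try:
        series, plateau = kinetics.convergence_series(records)
        out["convergence"] = {"k_rxn_running": series.tolist(),
                              "plateau": plateau}
    except ValueError:
        pass

    # pathway ensemble over all replicates
    per_replicate_paths = [pw.trace_pathways(rec) for rec in records]
    paths: list[pw.Pathway] = [p for rp in per_replicate_paths for p in rp]
    out["n_pathways"] = len(paths)
    if len(paths) >= 2:
        rng = np.random.default_rng(config.seed + preset_index)
        sample = paths
        if len(paths) > config.max_cluster_paths:
            # weight-proportional subsample keeps the probable classes
            probs = np.array([p.weight for p in paths])
            idx = rng.choice(len(paths), size=config.max_cluster_paths,
                             replace=False, p=probs / probs.sum())
            sample = [paths[i] for i in sorted(idx)]
        strings = [pw.discretize(p, params) for p in sample]
        dm = pw.distance_matrix(strings)
        tree = pw.cluster(dm)
        labels, n_classes, degenerate = pw.cut_tree(tree)
        for p, lab in zip(sample, labels):
            p.class_id = int(lab)
        out["pathway_classes"] = {
            "n_classes": n_classes,
            "degenerate": degenerate,
            "probabilities": {str(k): v for k, v in
                              pw.class_probabilities(sample).items()},
        }
        # contact statistics: per-replicate distributions averaged with equal
        # replicate weight (replicates are i.i.d.; this caps the influence of
        # any single heavy pathway), while the O(n^2) clustering runs on the
        # weight-proportional subsample
        rep_dists = [pw.contact_distribution(rp, params)
                     for rp in per_replicate_paths if rp]
        labels_all = params.label_alphabet
        dist = {lab: float(np.mean([d.get(lab, 0.0) for d in rep_dists]))
                for lab in labels_all}
        out["contact_distribution"] = dist
        out["contact_entropy"] = pw.label_entropy(dist)
        sites = [pw.addition_site(p, params) for p in paths]
        weights = [p.weight for p in paths]
        groups = [(lab,) for lab in dict.fromkeys(params.site_labels)]
        out["addition_site_ratios"] = kinetics.addition_site_ratios(
            sites, weights, groups)
    else:
        out["pathway_classes"] = {"note": "no productive pathways"}
    return out


def run_study(config: StudyConfig) -> dict:
    """Run the full multi-preset study and return the consolidated report.

    With ``out_dir`` set, a failure mid-study preserves the completed
    presets in ``study.partial.json`` plus a ``resume.marker`` naming the
    preset to restart from, then re-raises.
    """
    results = {"config": asdict(config), "presets": {}}
    outdir = Path(config.out_dir) if config.out_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    for i, preset in enumerate(config.presets):
        log.info("=== preset %s ===", preset)
        try:
            results["presets"][preset] = _preset_study(preset, config, i)
        except Exception:
            if outdir:
                with open(outdir / "study.partial.json", "w") as f:
                    json.dump(results, f, indent=2, default=str)
                (outdir / "resume.marker").write_text(preset + "\n")
            raise
    if outdir:
        with open(outdir / "study.json", "w") as f:
            json.dump(results, f, indent=2, default=str)
        marker = outdir / "resume.marker"
        if marker.exists():
            marker.unlink()
    return results


def _fmt_rate(entry: dict) -> str:
    mean = entry["mean"]
    cr = entry.get("cr95")
    if cr and all(np.isfinite(cr)):
        return f"{mean:.3g} ± [{mean - cr[0]:.2g}, {cr[1] - mean:.2g}]"
    return f"{mean:.3g}"


def report(study: dict) -> str:
    """Human-readable study summary, mirroring the reference reporting style."""
    lines: list[str] = []
    for preset, res in study["presets"].items():
        lines.append(f"== {preset} ==")
        rates = res.get("rates", {})
        for name in ("k_rxn", "k_1", "k_minus1", "k_2"):
            if name in rates:
                lines.append(f"  {name:9s} {_fmt_rate(rates[name])}")
        if "k_minus1" in rates and "k_2" in rates and rates["k_2"]["mean"] > 0:
            ratio = rates["k_minus1"]["mean"] / rates["k_2"]["mean"]
            regime = "activation-limited" if ratio > 10 else (
                "activation-leaning" if ratio > 1 else "diffusion-limited")
            lines.append(f"  k_minus1/k_2 = {ratio:.3g} ({regime})")
        pp = res.get("percent_productive")
        if pp:
            if pp.get("cr95"):
                lines.append(f"  productive collisions: {_fmt_rate(pp)}%")
            else:
                lines.append(f"  productive collisions: {pp['mean']:.3g}% "
                             "(credibility region needs >= 2 replicates)")
        pc = res.get("pathway_classes", {})
        if "note" in pc:
            lines.append(f"  pathway classes: {pc['note']}")
        elif pc:
            probs = ", ".join(f"{k}: {v:.2f}"
                              for k, v in sorted(pc["probabilities"].items()))
            lines.append(f"  pathway classes: {pc['n_classes']} ({probs})")
        if "contact_entropy" in res:
            lines.append(f"  contact-label entropy: {res['contact_entropy']:.3f} nats")
        if "n_pathways" in res:
            lines.append(f"  pathways traced: {res['n_pathways']}")
        conv = res.get("convergence")
        if conv:
            lines.append(f"  k_rxn plateau: {conv['plateau']}")
    return "\n".join(lines)
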