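"""End-to-end orchestration: cohort in, landscape + transition artifacts out.

``run_full_analysis`` chains diagnosis, obesity grouping, filtering, feature
selection, binarization, model fitting, basin/disconnectivity construction,
transition counting, pathway-preference testing, and the pre-transition
feature table, writing every artifact (plus a manifest with a config hash)
to an output directory. The run is deterministic for fixed seeds.

Scope "diabetes_only" re-runs the landscape on the sub-cohort of individuals
who were ever diagnosed, using that subset's own binarization thresholds
(the filtered records are all pre-onset by construction).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .cohort import (apply_filters, classify_all_obesity, diagnose_all,
                     rank_features)
from .ela import (ELA_FEATURES, N_PATTERNS, build_basin_graph,
                  compute_thresholds, disconnectivity, fit_pairwise_maxent,
                  landscape, pattern_bits)
from .pretransition import pretransition_table
from .transitions import (assign_states, count_transitions,
                          count_transitions_by_group, preference_test)

log = logging.getLogger("checkup_ela")


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    input_path: str | None = None
    features: tuple = ELA_FEATURES
    scope: str = "all"  # "all" or "diabetes_only"
    seed: int = 0
    coding: str = "01"
    rank_features_first: bool = False
    output_dir: str = "results"

    def validate(self) -> None:
        if len(self.features) != 6:
            raise ValueError("exactly 6 landscape features are required")
        if self.scope not in ("all", "diabetes_only"):
            raise ValueError("scope must be 'all' or 'diabetes_only'")


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunArtifacts:
    """In-memory results of a full run (also serialized to output_dir)."""

    config: RunConfig
    filter_report: object
    thresholds: object
    model: object
    landscape: object
    basins: object
    barriers: object
    state_sequences: list
    transition_counts: np.ndarray
    group_counts: dict
    preference: object | None
    pretransition: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _plot_basin_graph(scape, basins, path: Path) -> None:
    g = nx.DiGraph()
    for p in range(N_PATTERNS):
        g.add_node(p, energy=scape.energies[p], state=int(basins.state_of[p]))
    for p, q in enumerate(basins.descent_edge):
        if q >= 0:
            g.add_edge(p, int(q))
    pos = nx.spring_layout(g, seed=0)
    colors = [scape.energies[p] for p in g.nodes]
    fig, ax = plt.subplots(figsize=(8, 8))
    nx.draw_networkx(g, pos, node_color=colors, cmap="viridis",
                     node_size=220, font_size=6, ax=ax, arrowsize=8)
    ax.set_axis_off()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_disconnectivity(barriers, path: Path) -> None:
    """Bar-style sketch: each minimum's energy with pairwise barrier levels."""
    fig, ax = plt.subplots(figsize=(6, 4))
    E = barriers.energies
    for i, m in enumerate(barriers.minima):
        ax.plot([i, i], [E[m], np.nanmax(np.where(np.isfinite(barriers.barrier), barriers.barrier, np.nan))],
                color="0.7", lw=1)
        ax.scatter([i], [E[m]], zorder=3)
        ax.annotate(f"min {m}\nE={E[m]:.2f}", (i, E[m]),
                    textcoords="offset points", xytext=(4, -12), fontsize=8)
    k = len(barriers.minima)
    for i in range(k):
        for j in range(i + 1, k):
            b = barriers.barrier[i, j]
            if np.isfinite(b):
                ax.plot([i, j], [b, b], color="C1", lw=1.5)
    ax.set_xticks(range(k))
    ax.set_xticklabels([f"state {i + 1}" for i in range(k)])
    ax.set_ylabel("energy")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_full_analysis(config: RunConfig, records: pd.DataFrame | None = None) -> RunArtifacts:
    """Run the whole pipeline and write artifacts under ``config.output_dir``."""
    config.validate()
    if records is None:
        if config.input_path is None:
            raise ValueError("either records or config.input_path is required")
        records = pd.read_csv(config.input_path)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("input: %d records, %d individuals",
             len(records), records["individual_id"].nunique())
    onset_map = diagnose_all(records)
    obesity = classify_all_obesity(records)
    filtered, report = apply_filters(records, onset_map)
    log.info("filtered: %d records, %d individuals",
             report.final_records, report.final_individuals)

    if config.rank_features_first:
        ranking, selected = rank_features(filtered, onset_map, seed=config.seed)
        features = tuple(f for f in ELA_FEATURES if f in selected) \
            if set(selected) == set(ELA_FEATURES) else tuple(selected)
    else:
        features = tuple(config.features)

    if config.scope == "diabetes_only":
        keep = {i for i, y in onset_map.items() if y is not None}
        analysis = filtered[filtered["individual_id"].isin(keep)].reset_index(drop=True)
        log.info("diabetes-only scope: %d records from %d individuals",
                 len(analysis), analysis["individual_id"].nunique())
    else:
        analysis = filtered

    thresholds = compute_thresholds(analysis, features)
    from .ela import binarize_frame
    bits = binarize_frame(analysis, thresholds)
    model = fit_pairwise_maxent(bits, coding=config.coding, feature_order=features)
    scape = landscape(model)
    basins = build_basin_graph(scape)
    barriers = disconnectivity(scape, basins)
    log.info("landscape: %d states, minima %s", basins.n_states, basins.local_minima)

    sequences = assign_states(analysis, thresholds, basins)
    counts = count_transitions(sequences, basins.n_states)
    group_counts = count_transitions_by_group(sequences, basins.n_states, obesity)

    preference = None
    if basins.n_states >= 3 and {"obese", "non_obese"} <= set(group_counts):
        tbl = np.array([
            [group_counts["obese"][0, 1], group_counts["obese"][0, 2]],
            [group_counts["non_obese"][0, 1], group_counts["non_obese"][0, 2]],
        ])
        if (tbl.sum(axis=0) > 0).all() and (tbl.sum(axis=1) > 0).all():
            preference = preference_test(tbl)
            log.info("pathway preference test: p = %.4g", preference.p_value)

    types = [(a, b) for a in range(1, basins.n_states + 1)
             for b in range(1, basins.n_states + 1) if counts[a - 1, b - 1] > 0]
    comparisons = [(ta, tb) for i, ta in enumerate(types) for tb in types[i + 1:]
                   if ta != tb][:6]
    pre_tbl = pretransition_table(analysis, sequences, types,
                                  report.retained_features or list(features), comparisons)

    # ---- artifacts
    (out / "thresholds.json").write_text(json.dumps(
        {"feature_order": list(thresholds.feature_order),
         "values": thresholds.values,
         "reversed": sorted(thresholds.reversed_features)}, indent=2))
    (out / "model.json").write_text(json.dumps(
        {"feature_order": list(model.feature_order), "coding": model.coding,
         "h": model.h.tolist(), "J": model.J.tolist()}, indent=2))
    land_df = pd.DataFrame({
        "pattern": range(N_PATTERNS),
        "bits": ["".join(map(str, pattern_bits(p))) for p in range(N_PATTERNS)],
        "energy": scape.energies,
        "probability": scape.probabilities,
        "state": basins.state_of,
    })
    land_df.to_csv(out / "landscape.csv", index=False)
    pd.DataFrame(barriers.barrier,
                 index=[f"min_{m}" for m in barriers.minima],
                 columns=[f"min_{m}" for m in barriers.minima]).to_csv(out / "barriers.csv")
    pd.DataFrame(counts).to_csv(out / "transitions.csv")
    for gname, mat in group_counts.items():
        pd.DataFrame(mat).to_csv(out / f"transitions_{gname}.csv")
    if preference is not None:
        (out / "preference_test.json").write_text(json.dumps(
            {"table": preference.table.tolist(), "statistic": preference.statistic,
             "dof": preference.dof, "p_value": preference.p_value}, indent=2))
    pre_tbl.to_csv(out / "pretransition_table.csv", index=False)
    (out / "filter_report.json").write_text(json.dumps(asdict(report), indent=2))
    _plot_basin_graph(scape, basins, out / "basin_graph.png")
    _plot_disconnectivity(barriers, out / "disconnectivity.png")

    manifest = {
        "version": __version__,
        "config": asdict(cfg := config),
        "config_hash": _config_hash(cfg),
        "n_input_records": int(len(records)),
        "n_analysis_records": int(len(analysis)),
        "n_states": int(basins.n_states),
        "artifacts": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return RunArtifacts(config, report, thresholds, model, scape, basins, barriers,
                        sequences, counts, group_counts, preference, pre_tbl, manifest)
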