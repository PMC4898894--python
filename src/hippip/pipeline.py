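"""End-to-end pipeline: synth -> split -> train -> evaluate -> scan -> stats.

Every stage writes machine-readable TSV/SIF artifacts; a run manifest
(YAML) records the configuration snapshot, every seed, input checksums and
output paths, so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .annot_io import PPIEdgeList, write_network
from .evaluate import hub_ranked_eval, identify_hubs, pr_sweep
from .interactome import (
    assemble_interactome,
    full_scan,
    genome_scan,
    interactome_overlap,
    summarize_interactome,
)
from .model import train
from .netstats import (
    distance_drop_test,
    distance_report,
    drug_target_summary,
    hypergeom_overlap,
    shortest_path_histogram,
    term_enrichment,
)
from .synth import SynthConfig, generate_drug_targets, generate_universe, make_seed_panel, write_universe
from .trainset import build_test_set, build_training_set, split_known_edges

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    command: str
    config: dict
    seeds: dict = field(default_factory=dict)
    input_checksums: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    started: str = ""
    finished: str = ""
    package_version: str = __version__

    def record_output(self, path) -> None:
        self.outputs.append(str(path))

    def checksum_input(self, path) -> None:
        p = Path(path)
        self.input_checksums[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run; all sizes are desk scale."""

    synth: SynthConfig = field(default_factory=lambda: SynthConfig(seed=0))
    seed: int = 0
    train_positive_fraction: float = 0.8  # known edges used for training positives
    negative_ratio: int = 4
    test_total: int = 30_000
    test_prevalence: float = 0.003
    scan_threshold: float = 0.5
    hub_min_degree: int = 8               # desk-scale analog of degree > 50
    permutation_trials: int = 200
    k_gwas: int = 77
    k_historic: int = 25
    k_shared: int = 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth_raw = raw.pop("synth", {})
        cfg = cls(**raw)
        if synth_raw:
            cfg.synth = SynthConfig(**synth_raw)
        return cfg


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the whole workflow on a synthetic universe; return headline numbers.

    Artifacts written under *outdir*: the universe directory, the PR curve,
    the interactome (SIF + attributes), distance/permutation reports,
    interactome-overlap and enrichment tables, drug summaries, and
    ``manifest.yaml``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    seeds = {
        "master": config.seed,
        "synth": config.synth.seed,
        "split": int(rng.integers(2**31)),
        "train_set": int(rng.integers(2**31)),
        "test_set": int(rng.integers(2**31)),
        "model": int(rng.integers(2**31)),
        "seed_panel": int(rng.integers(2**31)),
        "drugs": int(rng.integers(2**31)),
        "permutation": int(rng.integers(2**31)),
    }
    manifest = RunManifest(
        command="run",
        config={
            **{k: v for k, v in dataclasses.asdict(config).items() if k != "synth"},
            "synth": dataclasses.asdict(config.synth),
        },
        seeds=seeds,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    results: dict = {}

    # --- synth
    universe, truth = generate_universe(config.synth)
    drugs = generate_drug_targets(truth, n_drugs=config.synth.n_drugs, seed=seeds["drugs"])
    panel = make_seed_panel(
        truth, config.k_gwas, config.k_historic, config.k_shared, seed=seeds["seed_panel"]
    )
    unidir = write_universe(universe, out / "universe", drugs=drugs, seeds=panel)
    manifest.record_output(unidir)
    results["n_genes"] = len(universe.catalog)
    results["n_truth_edges"] = len(truth.truth)
    results["n_known_edges"] = len(universe.known_ppis)
    results["seed_panel_union"] = len(panel.union)

    # --- split / train / test
    train_edges, heldout_edges = split_known_edges(
        universe.known_ppis, 1.0 - config.train_positive_fraction, seed=seeds["split"]
    )
    train_known = PPIEdgeList({e: "known" for e in train_edges})
    train_set = build_training_set(
        train_known,
        universe.catalog,
        positives_n=len(train_edges),
        ratio=config.negative_ratio,
        seed=seeds["train_set"],
        exclude=universe.known_ppis.pairs(),
    )
    test_set = build_test_set(
        heldout_edges,
        universe.catalog,
        total_n=config.test_total,
        positive_fraction=config.test_prevalence,
        seed=seeds["test_set"],
        known=universe.known_ppis,
        train_set=train_set,
    )
    results["train_positives"] = len(train_set.positives)
    results["train_negatives"] = len(train_set.negatives)
    results["test_total"] = len(test_set)
    results["test_positives"] = len(test_set.positives)

    # --- model
    model = train(train_set, universe, seed=seeds["model"])
    model_path = out / "model.joblib"
    model.save(model_path)
    manifest.record_output(model_path)

    # --- evaluation
    scores = model.decision_scores(test_set.pairs)
    curve = pr_sweep(scores, test_set.labels)
    curve.table.to_csv(out / "pr_curve.tsv", sep="\t", index=False)
    manifest.record_output(out / "pr_curve.tsv")
    at_half = curve.at_threshold(0.5)
    results["precision_at_0.5"] = float(at_half["precision"])
    results["recall_at_0.5"] = float(at_half["recall"])

    hubs = sorted(identify_hubs(universe.known_ppis, min_degree=config.hub_min_degree))
    if hubs:
        ranked = hub_ranked_eval(
            model, hubs[:5], universe, heldout_edges, threshold_floor=config.scan_threshold
        )
        ranked.average.to_csv(out / "hub_average_curve.tsv", sep="\t", index=False)
        manifest.record_output(out / "hub_average_curve.tsv")
    results["n_hubs"] = len(hubs)

    # --- genome scan + interactome
    scan = genome_scan(panel, universe, model, threshold=config.scan_threshold)
    graph = assemble_interactome(
        panel, universe.known_ppis, scan.predicted, catalog_symbols=universe.catalog.symbols
    )
    summary = summarize_interactome(graph, panel, universe.known_ppis)
    results["novel_ppis"] = summary.n_novel_edges
    results["known_ppis_of_seeds"] = summary.n_known_edges
    results["newly_connected_seeds"] = len(summary.newly_connected_seeds)
    net_files = write_network(graph, out / "interactome", overwrite=True)
    for p in net_files.values():
        manifest.record_output(p)

    # --- distance statistics with permutation null
    background = nx_known_graph(universe.known_ppis)
    predicted_all = full_scan(universe, model, threshold=config.scan_threshold)
    report = distance_report(background, predicted_all, panel.union, label="seed panel")
    results["avg_distance_with"] = report.with_predicted.mean
    results["avg_distance_without"] = report.without_predicted.mean
    results["distance_drop"] = report.drop
    perm = distance_drop_test(
        background,
        predicted_all,
        panel.union,
        universe.catalog,
        n_trials=config.permutation_trials,
        seed=seeds["permutation"],
    )
    results["distance_drop_p"] = perm.p_value

    # --- per-list interactomes, overlap, nearest-distance histogram
    sub_graphs = {}
    for label, genes in panel.lists.items():
        sub_scan = genome_scan(genes, universe, model, threshold=config.scan_threshold)
        sub_graphs[label] = assemble_interactome(
            genes, universe.known_ppis, sub_scan.predicted,
            catalog_symbols=universe.catalog.symbols,
        )
    labels = list(sub_graphs)
    if len(labels) == 2:
        shared = interactome_overlap(sub_graphs[labels[0]], sub_graphs[labels[1]])
        row = hypergeom_overlap(
            set(sub_graphs[labels[0]].nodes),
            set(sub_graphs[labels[1]].nodes),
            len(universe.catalog),
        )
        results["interactome_overlap_genes"] = len(shared)
        results["interactome_overlap_p"] = row.p_value
        hist = shortest_path_histogram(
            nx_known_graph(universe.known_ppis, extra=predicted_all),
            panel.lists[labels[0]],
            panel.lists[labels[1]],
        )
        hist.to_csv(out / "nearest_distance.tsv", sep="\t", index=False)
        manifest.record_output(out / "nearest_distance.tsv")

    # --- GO-term enrichment of the interactors
    interactors = {n for n, r in graph.nodes(data="role") if r != "seed"}
    term_table = {
        g: universe.go.annotated_closure(g, "BP") for g in universe.catalog.symbols
    }
    enrich = term_enrichment(interactors, term_table, universe.catalog.symbols)
    enrich.to_csv(out / "enrichment_bp.tsv", sep="\t", index=False)
    manifest.record_output(out / "enrichment_bp.tsv")
    results["n_enriched_terms_bh05"] = int((enrich["p_adjusted"] < 0.05).sum())

    # --- drugs
    dsum = drug_target_summary(graph, drugs)
    dsum.by_category.to_csv(out / "drug_categories.tsv", sep="\t", index=False)
    manifest.record_output(out / "drug_categories.tsv")
    results["n_drugs_targeting_interactome"] = len(dsum.drug_roles)
    results["n_targeted_genes"] = sum(len(v) for v in dsum.targeted_genes.values())

    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, default=float)
    manifest.record_output(out / "results.json")
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out / "manifest.yaml")
    return results


def nx_known_graph(known: PPIEdgeList, extra: PPIEdgeList | None = None):
    """Background network: all known PPIs, optionally plus predicted edges."""
    import networkx as nx

    g = nx.Graph()
    g.add_edges_from(known.pairs())
    if extra is not None:
        g.add_edges_from(extra.pairs())
    return g
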