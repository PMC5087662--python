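"""End-to-end orchestration: simulate/load -> DE -> signatures -> score ->
entropy -> enrichment, from a single config, with a reproducibility manifest.

The run config either names input files (expression, metadata, network, GMT)
or describes a synthetic experiment; one global seed is fanned out to the
stages through a fixed counter scheme so any stage can be re-run in
isolation.  All intermediate tables are plain TSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .io import (
    CONSTRUCTS,
    GeneSet,
    GeneSetCollection,
    ValidationError,
    read_expression,
    read_gmt,
    read_metadata,
    read_network,
    write_expression,
    write_gmt,
    write_metadata,
    write_network,
)
from .biomarker import dux4_score
from .diffexp import de_all_constructs
from .entropy import entropy_per_sample
from .enrichment import enrich
from .signatures import (
    derive_dux4_signature,
    derive_dux4c_signature,
    pairwise_correlations,
    partition_joint,
)
from .simulate import SimulationConfig, simulate_experiment, simulate_network

logger = logging.getLogger("duxent")

# fixed offsets fanning the global seed out to stages
_SEED_OFFSETS = {"simulate": 0, "network": 10007, "annotation": 20011}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    seed: int = 0
    alpha: float = 0.05
    correlation_method: str = "pearson"
    score_statistic: str = "mean_diff"
    expression: str | None = None
    metadata: str | None = None
    network: str | None = None
    gene_sets: str | None = None
    simulation: dict = field(default_factory=dict)
    network_simulation: dict = field(default_factory=lambda: {"n_nodes": 400, "mean_degree": 6})
    entropy: dict = field(default_factory=dict)
    run_entropy: bool = True
    run_enrichment: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if (self.expression is None) != (self.metadata is None):
            raise ValidationError("expression and metadata must be given together")
        for key in ("expression", "metadata", "network", "gene_sets"):
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                raise ValidationError(f"{key} file not found: {path}")
        if self.run_entropy and self.network is None and not self.network_simulation:
            raise ValidationError("entropy stage enabled but no network given or simulated")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _truth_annotation(truth: pd.DataFrame, seed: int) -> GeneSetCollection:
    """Annotation sets for a synthetic run: planted groups plus random decoys."""
    import numpy as np

    rng = np.random.default_rng(seed)
    sets = []
    for group in sorted(truth["group"].unique()):
        if group == "none":
            continue
        members = tuple(truth.index[truth["group"] == group])
        if members:
            sets.append(GeneSet(f"planted_{group}", "planted synthetic gene group", members))
    genes = list(truth.index)
    for i in range(10):
        members = tuple(rng.choice(genes, size=50, replace=False))
        sets.append(GeneSet(f"decoy_{i:02d}", "random synthetic decoy set", members))
    return GeneSetCollection(sets)


def run_all(config: RunConfig, outdir) -> dict:
    """Run the full pipeline and return the manifest (also written as JSON)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    notes: dict = {}

    def emit(path: Path):
        artifacts.append(path)

    def stage(name):
        logger.info("pipeline stage: %s", name)

    truth = None
    try:
        stage("data")
        if config.expression is not None:
            matrix = read_expression(config.expression)
            metadata = read_metadata(config.metadata)
        else:
            sim_cfg = SimulationConfig(**{**config.simulation, "seed": config.seed + _SEED_OFFSETS["simulate"]})
            matrix, metadata, truth = simulate_experiment(sim_cfg)
            write_expression(matrix, outdir / "expression.tsv")
            write_metadata(metadata, outdir / "metadata.tsv")
            truth.to_csv(outdir / "truth.tsv", sep="\t")
            emit(outdir / "expression.tsv")
            emit(outdir / "metadata.tsv")
            emit(outdir / "truth.tsv")
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise StageError("data", exc) from exc

    try:
        stage("diffexp")
        de = de_all_constructs(matrix, metadata)
        for cond, table in de.items():
            path = outdir / f"de_{cond}.tsv"
            table.to_csv(path, sep="\t", index_label="gene")
            emit(path)
    except Exception as exc:
        raise StageError("diffexp", exc) from exc

    try:
        stage("correlations")
        corr = pairwise_correlations(de, method=config.correlation_method)
        corr.to_csv(outdir / "corr.tsv", sep="\t", index_label="construct")
        emit(outdir / "corr.tsv")
    except Exception as exc:
        raise StageError("correlations", exc) from exc

    try:
        stage("signatures")
        sig_dux4 = derive_dux4_signature(
            de["DUX4"], de["tMALDUX4-VP16"], de["tMALDUX4-ERD"], alpha=config.alpha
        )
        sig_dux4c = derive_dux4c_signature(de["tMALDUX4"], de["DUX4c"], alpha=config.alpha)
        combined = GeneSetCollection(
            list(sig_dux4.to_collection()) + list(sig_dux4c.to_collection())
        )
        write_gmt(combined, outdir / "sig.gmt")
        emit(outdir / "sig.gmt")
        universe = de["DUX4"].index
        partition = partition_joint(sig_dux4, sig_dux4c, universe)
        for name, genes in partition.as_dict().items():
            path = outdir / f"partition_{name}.txt"
            path.write_text("".join(g + "\n" for g in genes))
            emit(path)
        notes["n_dux4_up"] = len(sig_dux4.up_genes)
        notes["n_dux4_down"] = len(sig_dux4.down_genes)
        notes["n_dux4c_up"] = len(sig_dux4c.up_genes)
        notes["n_dux4c_down"] = len(sig_dux4c.down_genes)
    except Exception as exc:
        raise StageError("signatures", exc) from exc

    try:
        stage("biomarker")
        if sig_dux4.up_genes and sig_dux4.down_genes:
            scores = dux4_score(matrix, sig_dux4, statistic=config.score_statistic)
        else:
            scores = pd.DataFrame(columns=["score", "n_up_used", "n_down_used"])
            notes["biomarker"] = "skipped: empty DUX4 signature"
        scores.to_csv(outdir / "scores.tsv", sep="\t", index_label="sample_id")
        emit(outdir / "scores.tsv")
    except Exception as exc:
        raise StageError("biomarker", exc) from exc

    if config.run_entropy:
        try:
            stage("entropy")
            if config.network is not None:
                network = read_network(config.network)
            else:
                net_cfg = dict(config.network_simulation)
                n_nodes = min(net_cfg.pop("n_nodes", 400), matrix.shape[0])
                network = simulate_network(
                    n_nodes,
                    seed=config.seed + _SEED_OFFSETS["network"],
                    gene_ids=matrix.gene_ids,
                    **net_cfg,
                )
                write_network(network, outdir / "network.tsv")
                emit(outdir / "network.tsv")
            summary, _ = entropy_per_sample(matrix, network, **config.entropy)
            summary.to_csv(outdir / "entropy.tsv", sep="\t")
            emit(outdir / "entropy.tsv")
        except Exception as exc:
            raise StageError("entropy", exc) from exc

    if config.run_enrichment:
        try:
            stage("enrichment")
            if config.gene_sets is not None:
                collection = read_gmt(config.gene_sets)
            elif truth is not None:
                collection = _truth_annotation(truth, config.seed + _SEED_OFFSETS["annotation"])
                write_gmt(collection, outdir / "annotation.gmt")
                emit(outdir / "annotation.gmt")
            else:
                collection = None
                notes["enrichment"] = "skipped: no gene sets supplied"
            if collection is not None:
                universe = list(de["DUX4"].index)
                for name, genes in partition.as_dict().items():
                    path = outdir / f"enrich_{name}.tsv"
                    if genes:
                        table = enrich(genes, collection, universe, alpha_bh=config.alpha)
                    else:
                        table = pd.DataFrame(
                            columns=["set_name", "a", "b", "c", "d", "odds_ratio", "p", "p_bh", "enriched"]
                        )
                    table.to_csv(path, sep="\t", index=False)
                    emit(path)
        except Exception as exc:
            raise StageError("enrichment", exc) from exc

    manifest = {
        "duxent_version": __version__,
        "seed": config.seed,
        "config_digest": hashlib.sha256(
            json.dumps(config.__dict__, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "notes": notes,
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
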