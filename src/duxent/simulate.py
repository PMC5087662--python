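"""Synthetic expression experiments with planted construct-specific targets.

The generator emulates the design of the retroviral construct panel: six
conditions (control plus five DUX4/DUX4c constructs) with three biological
replicates each, gene-level Gaussian noise on a log scale, and planted
target-gene groups whose signed effects follow the construct biology:

* ``dux4_up`` / ``dux4_down`` — activation-domain-dependent DUX4 targets:
  moved concordantly by DUX4 and the constitutively active tMALDUX4-VP16
  fusion and inverted by the dominant-negative tMALDUX4-ERD fusion.
* ``dux4c_up`` / ``dux4c_down`` — DUX4c targets, moved concordantly by DUX4c
  and the truncated tMALDUX4 (which lacks the DUX4 C-terminus, like DUX4c).
* ``shared_up`` / ``shared_down`` — homeodomain-dependent targets moved by
  DUX4 independently of its transactivation domain.  The ERD fusion moves
  them in the SAME direction as DUX4 (it carries the same DNA-binding
  domains), and tMALDUX4/DUX4c move them at half magnitude.  Balancing these
  repression-concordant targets against the activation-inverted groups is
  what reproduces the observed global picture: DUX4 strongly correlated with
  VP16 but essentially uncorrelated with ERD, because DUX4 both activates
  and suppresses targets.

A companion generator draws connected, non-bipartite interaction networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .io import CONDITIONS, CONSTRUCTS, ExpressionMatrix, ValidationError

#: Planted gene-group labels ("none" marks unaffected background genes).
GROUPS = ("dux4_up", "dux4_down", "dux4c_up", "dux4c_down", "shared_up", "shared_down")

DEFAULT_GROUP_SIZES = {
    "dux4_up": 300,
    "dux4_down": 350,
    "dux4c_up": 200,
    "dux4c_down": 200,
    "shared_up": 325,
    "shared_down": 325,
}


def default_effect_matrix() -> pd.DataFrame:
    """Signed effect multipliers (rows: gene groups, columns: constructs).

    Entries multiply ``effect_size * noise_sd`` to give the planted log-scale
    shift of each group under each construct.  Control is always 0.
    """
    rows = {
        #              DUX4  tMAL  VP16  ERD   DUX4c
        "dux4_up":    [+1.0, 0.0, +1.0, -1.0, 0.0],
        "dux4_down":  [-1.0, 0.0, -1.0, +1.0, 0.0],
        "dux4c_up":   [0.0, +1.0, 0.0, 0.0, +1.0],
        "dux4c_down": [0.0, -1.0, 0.0, 0.0, -1.0],
        "shared_up":  [+1.0, +0.5, +1.0, +1.0, +0.5],
        "shared_down": [-1.0, -0.5, -1.0, -1.0, -0.5],
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(CONSTRUCTS))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    effect_size is the planted mean log-scale shift in units of noise_sd.
    """

    n_genes: int = 5000
    n_replicates: int = 3
    baseline_mean: float = 6.0
    baseline_sd: float = 1.0
    effect_size: float = 3.0
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    effect_matrix: pd.DataFrame | None = None
    noise_sd: float = 1.0
    min_expression: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        unknown = set(self.group_sizes) - set(GROUPS)
        if unknown:
            raise ValidationError(f"unknown planted groups {sorted(unknown)}")
        if sum(self.group_sizes.values()) > self.n_genes:
            raise ValidationError("planted group sizes exceed n_genes")
        if self.effect_matrix is None:
            self.effect_matrix = default_effect_matrix()

    def null(self) -> "SimulationConfig":
        """A copy of this configuration with every planted effect removed."""
        return replace(self, effect_size=0.0, effect_matrix=self.effect_matrix.copy())


def simulate_experiment(config: SimulationConfig):
    """Draw one synthetic experiment.

    Returns ``(matrix, metadata, truth)`` where truth carries the per-gene
    group label and the signed planted effect under each condition.  The same
    config (same seed) reproduces the matrix bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"g{i:05d}" for i in range(1, n + 1)]

    # assign planted groups to random gene positions
    group = np.array(["none"] * n, dtype=object)
    planted_total = sum(config.group_sizes.get(g, 0) for g in GROUPS)
    positions = rng.permutation(n)[:planted_total]
    cursor = 0
    for g in GROUPS:
        size = config.group_sizes.get(g, 0)
        group[positions[cursor:cursor + size]] = g
        cursor += size

    # per-(gene, condition) planted shift
    shift = pd.DataFrame(0.0, index=genes, columns=list(CONDITIONS))
    magnitude = config.effect_size * config.noise_sd
    for g in GROUPS:
        mask = group == g
        if not mask.any() or g not in config.effect_matrix.index:
            continue
        for cond in CONSTRUCTS:
            shift.loc[mask, cond] = config.effect_matrix.loc[g, cond] * magnitude

    samples, conditions, replicates = [], [], []
    for cond in CONDITIONS:
        for r in range(1, config.n_replicates + 1):
            samples.append(f"{cond}_r{r}")
            conditions.append(cond)
            replicates.append(r)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    values = np.empty((n, len(samples)))
    for j, cond in enumerate(conditions):
        noise = rng.normal(0.0, config.noise_sd, size=n)
        values[:, j] = baseline + shift[cond].to_numpy() + noise
    values = np.maximum(values, config.min_expression)

    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
    metadata = pd.DataFrame(
        {"sample_id": samples, "condition": conditions, "replicate": replicates}
    )
    truth = shift.copy()
    truth.insert(0, "group", group)
    truth.index.name = "gene"
    return matrix, metadata, truth


def true_signature(truth: pd.DataFrame, regulator: str = "DUX4"):
    """Ground-truth up/down target lists for one regulator from a truth table."""
    from .io import SignatureSet

    key = {"DUX4": ("dux4_up", "dux4_down"), "DUX4c": ("dux4c_up", "dux4c_down")}[regulator]
    up = tuple(truth.index[truth["group"] == key[0]])
    down = tuple(truth.index[truth["group"] == key[1]])
    return SignatureSet(regulator, up, down)


def simulate_network(
    n_nodes: int,
    mean_degree: float = 4,
    model: str = "small_world",
    seed: int | None = None,
    gene_ids=None,
) -> nx.Graph:
    """Draw a connected, non-bipartite simple graph standing in for a PIN.

    Disconnected draws are bridged with minimal extra edges; bipartite draws
    get one triangle-closing edge.  Node ids come from ``gene_ids`` when
    given, else ``n0001``-style labels.
    """
    if n_nodes < 3:
        raise ValidationError("network needs at least 3 nodes")
    if mean_degree < 2:
        raise ValidationError("mean_degree must be >= 2")
    rng = np.random.default_rng(seed)
    nx_seed = int(rng.integers(0, 2**31 - 1))
    if model == "small_world":
        k = max(2, int(round(mean_degree / 2)) * 2)  # watts-strogatz needs even k
        graph = nx.watts_strogatz_graph(n_nodes, min(k, n_nodes - 1), 0.1, seed=nx_seed)
    elif model == "scale_free":
        m = max(1, int(round(mean_degree / 2)))
        graph = nx.barabasi_albert_graph(n_nodes, min(m, n_nodes - 1), seed=nx_seed)
    else:
        raise ValueError(f"unknown network model {model!r}")
    graph.remove_edges_from(nx.selfloop_edges(graph))

    # bridge components deterministically: connect smallest node of each
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    for a, b in zip(components, components[1:]):
        graph.add_edge(min(a), min(b))

    if nx.is_bipartite(graph):
        # close a triangle at the first node with two neighbours
        for node in sorted(graph.nodes()):
            nbrs = sorted(graph.neighbors(node))
            if len(nbrs) >= 2:
                graph.add_edge(nbrs[0], nbrs[1])
                break

    if gene_ids is not None:
        gene_ids = list(gene_ids)
        if len(gene_ids) < n_nodes:
            raise ValidationError("not enough gene_ids for requested n_nodes")
        mapping = {i: gene_ids[i] for i in graph.nodes()}
        graph = nx.relabel_nodes(graph, mapping)
    else:
        graph = nx.relabel_nodes(graph, {i: f"n{i + 1:04d}" for i in graph.nodes()})
    return graph
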