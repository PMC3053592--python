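"""Synthetic input bundles with the statistical structure the analysis assumes.

A bundle holds: a random gene annotation; per-cell-type Poisson contact
matrices with power-law distance decay and compartment-block boosts; an
expression matrix whose within-block correlation is tunable (the contact ->
co-expression coupling); mutual ranks derived from that matrix; a sparse
bipartite TF network; and a small ontology DAG whose annotation sharing can
be coupled to spatial blocks.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .core_io import (
    ChromSizes,
    CoexpressionTable,
    ContactMatrix,
    Gene,
    GeneAnnotation,
    GeneGoAnnotation,
    GoDAG,
    RegulatoryNetwork,
    n_bins_for,
    write_chrom_sizes,
    write_contact_matrix,
    write_gene_annotation,
    write_gene_go,
    write_mutual_ranks,
    write_obo_subset,
    write_tf_targets,
)
from .errors import ConfigError, ValidationError

GENE_LENGTH_RANGE = (5_000, 200_000)  # log-uniform gene-length support, bp


@dataclass
class SimulationConfig:
    """All knobs of the generator; ``beta == 0`` and ``gamma == 0`` is the null."""

    n_chromosomes: int = 2
    chrom_length: int = 30_000_000
    resolution: int = 1_000_000
    n_genes: int = 300
    n_tfs: int = 40
    tf_mean_out_degree: float = 20.0
    tf_block_coupling: float = 0.0
    n_conditions: int = 60
    decay_exponent: float = 1.0
    n_blocks: int = 6
    kappa: float = 3.0
    beta: float = 0.0
    shared_block_fraction: float = 1.0
    go_depth: int = 3
    go_branching: int = 3
    part_of_fraction: float = 0.2
    gamma: float = 0.0
    noise_scale: float = 1.0
    base_contacts: float = 100.0
    cell_types: Tuple[str, ...] = ("cellA", "cellB")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_length", "resolution", "n_tfs",
                     "n_conditions", "n_blocks", "go_depth", "go_branching"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_genes < 0:
            raise ConfigError("n_genes must be >= 0")
        if self.resolution > self.chrom_length:
            raise ConfigError("resolution must not exceed chrom_length")
        if not (0.0 <= self.beta <= 1.0):
            raise ConfigError(f"beta must lie in [0, 1], got {self.beta}")
        if self.kappa < 1.0:
            raise ConfigError("kappa must be >= 1")
        if self.decay_exponent <= 0:
            raise ConfigError("decay_exponent must be > 0")
        if self.gamma < 0 or self.shared_block_fraction < 0:
            raise ConfigError("gamma and shared_block_fraction must be >= 0")
        self.cell_types = tuple(self.cell_types)

    @property
    def chroms(self) -> List[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def n_bins(self) -> int:
        return n_bins_for(self.chrom_length, self.resolution)


def null_config(**overrides) -> SimulationConfig:
    """Default preset with no contact->expression or ontology coupling."""
    return SimulationConfig(beta=0.0, gamma=0.0, **overrides)


def strong_config(**overrides) -> SimulationConfig:
    """Strong-coupling preset: shared compartments, beta=0.9, ontology coupling."""
    params = dict(beta=0.9, gamma=0.6, kappa=3.0, shared_block_fraction=1.0)
    params.update(overrides)
    return SimulationConfig(**params)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_genome(cfg: SimulationConfig, rng: np.random.Generator) -> GeneAnnotation:
    """Genes placed uniformly at random without overlap, log-uniform lengths."""
    sizes = ChromSizes({c: cfg.chrom_length for c in cfg.chroms})
    lo, hi = np.log(GENE_LENGTH_RANGE[0]), np.log(GENE_LENGTH_RANGE[1])
    genes: List[Gene] = []
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_genes // cfg.n_chromosomes)
    per_chrom[: cfg.n_genes % cfg.n_chromosomes] += 1
    gi = 0
    for chrom, count in zip(cfg.chroms, per_chrom):
        placed: List[Tuple[int, int]] = []
        for _ in range(count):
            length = int(np.exp(rng.uniform(lo, hi)))
            for _attempt in range(1000):
                start = int(rng.integers(0, cfg.chrom_length - length))
                end = start + length
                if all(end <= s or start >= e for s, e in placed):
                    placed.append((start, end))
                    gi += 1
                    genes.append(Gene(f"g{gi:05d}", chrom, start, end,
                                      "+" if rng.random() < 0.5 else "-"))
                    break
            else:
                raise ConfigError(
                    f"could not place {count} non-overlapping genes on {chrom}; "
                    "gene density too high"
                )
    return GeneAnnotation(genes, sizes)


@dataclass
class BlockAssignment:
    """Per-bin compartment labels: a base assignment plus one per cell type."""

    base: Dict[str, np.ndarray]
    per_cell: Dict[str, Dict[str, np.ndarray]]


def simulate_blocks(cfg: SimulationConfig, rng: np.random.Generator) -> BlockAssignment:
    """Contiguous segments per chromosome, each labeled open/closed (0/1).

    The first cell type uses the base labels; later cell types keep each
    segment's label with probability ``shared_block_fraction`` and redraw it
    otherwise.
    """
    n = cfg.n_bins
    bounds = np.linspace(0, n, cfg.n_blocks + 1).astype(int)
    base: Dict[str, np.ndarray] = {}
    seg_labels: Dict[str, np.ndarray] = {}
    for chrom in cfg.chroms:
        labels = rng.integers(0, 2, size=cfg.n_blocks)
        seg_labels[chrom] = labels
        per_bin = np.zeros(n, dtype=int)
        for s in range(cfg.n_blocks):
            per_bin[bounds[s]: bounds[s + 1]] = labels[s]
        base[chrom] = per_bin
    per_cell: Dict[str, Dict[str, np.ndarray]] = {}
    for idx, ct in enumerate(cfg.cell_types):
        per_cell[ct] = {}
        for chrom in cfg.chroms:
            if idx == 0:
                per_cell[ct][chrom] = base[chrom].copy()
                continue
            labels = seg_labels[chrom].copy()
            redraw = rng.random(cfg.n_blocks) >= cfg.shared_block_fraction
            labels[redraw] = rng.integers(0, 2, size=int(redraw.sum()))
            per_bin = np.zeros(n, dtype=int)
            for s in range(cfg.n_blocks):
                per_bin[bounds[s]: bounds[s + 1]] = labels[s]
            per_cell[ct][chrom] = per_bin
    return BlockAssignment(base, per_cell)


def contact_mean_matrix(
    cfg: SimulationConfig, labels: np.ndarray
) -> np.ndarray:
    """Expected contact count: base * (1+|i-j|)^-alpha * kappa^[same block]."""
    n = cfg.n_bins
    idx = np.arange(n)
    dist = np.abs(np.subtract.outer(idx, idx))
    same = (labels[:, None] == labels[None, :]).astype(float)
    return cfg.base_contacts * (1.0 + dist) ** (-cfg.decay_exponent) * cfg.kappa ** same


def simulate_contacts(
    cfg: SimulationConfig,
    blocks: BlockAssignment,
    cell_type: str,
    rng: np.random.Generator,
) -> Dict[str, ContactMatrix]:
    """Per-chromosome Poisson contact matrices for one cell type."""
    out: Dict[str, ContactMatrix] = {}
    for chrom in cfg.chroms:
        mu = contact_mean_matrix(cfg, blocks.per_cell[cell_type][chrom])
        upper = rng.poisson(mu)
        counts = np.triu(upper) + np.triu(upper, 1).T  # mirror upper triangle
        out[chrom] = ContactMatrix(chrom, cell_type, cfg.resolution,
                                   counts.astype(float), cfg.n_bins)
    return out


def gene_block_labels(
    cfg: SimulationConfig, ann: GeneAnnotation, blocks: BlockAssignment
) -> Dict[str, Tuple[str, int]]:
    """Block key (chrom, base label at the gene's midpoint bin) per gene."""
    out: Dict[str, Tuple[str, int]] = {}
    for g in ann:
        b = min(int(g.midpoint // cfg.resolution), cfg.n_bins - 1)
        out[g.id] = (g.chrom, int(blocks.base[g.chrom][b]))
    return out


def simulate_expression(
    cfg: SimulationConfig,
    ann: GeneAnnotation,
    blocks: BlockAssignment,
    rng: np.random.Generator,
) -> np.ndarray:
    """Factor-model expression (genes x conditions).

    Gene profile = sqrt(beta) * f_block + sqrt(1-beta) * sigma * noise, so
    same-block pairs have expected correlation beta/(beta+(1-beta)*sigma^2)
    (= beta at sigma=1) and cross-block pairs 0.
    """
    labels = gene_block_labels(cfg, ann, blocks)
    keys = sorted(set(labels.values()))
    factors = {k: rng.standard_normal(cfg.n_conditions) for k in keys}
    expr = np.empty((len(ann), cfg.n_conditions))
    for row, g in enumerate(ann):
        noise = rng.standard_normal(cfg.n_conditions)
        expr[row] = (
            np.sqrt(cfg.beta) * factors[labels[g.id]]
            + np.sqrt(1.0 - cfg.beta) * cfg.noise_scale * noise
        )
    return expr


def mutual_ranks_from_expression(
    expr: np.ndarray, gene_ids: List[str]
) -> CoexpressionTable:
    """Geometric mean of reciprocal correlation ranks, genome-wide.

    For each ordered pair, rank of corr(g, h) among g's partners (rank 1 =
    highest); MR(g, h) = sqrt(rank_g(h) * rank_h(g)). Genes with a constant
    profile have undefined correlations and contribute no pairs.
    """
    expr = np.asarray(expr, dtype=float)
    if expr.shape[1] < 3:
        raise ConfigError("need >= 3 conditions for mutual ranks")
    ok = expr.std(axis=1) > 0
    idx = np.flatnonzero(ok)
    table = CoexpressionTable()
    if len(idx) < 2:
        return table
    corr = np.corrcoef(expr[idx])
    from scipy.stats import rankdata

    n = len(idx)
    ranks = np.empty((n, n))
    for i in range(n):
        others = np.delete(np.arange(n), i)
        r = rankdata(-corr[i, others], method="average")
        ranks[i, others] = r
        ranks[i, i] = np.nan
    for i in range(n):
        for j in range(i + 1, n):
            mr = float(np.sqrt(ranks[i, j] * ranks[j, i]))
            table.add(gene_ids[idx[i]], gene_ids[idx[j]], mr)
    return table


def simulate_tf_network(
    cfg: SimulationConfig,
    ann: GeneAnnotation,
    blocks: Optional[BlockAssignment],
    rng: np.random.Generator,
) -> RegulatoryNetwork:
    """Per-TF target sets, degree ~ 1 + Poisson(mean - 1).

    With probability ``tf_block_coupling`` a TF draws all its targets from a
    single compartment block, biasing shared regulators toward same-block
    pairs; otherwise targets are uniform over all genes.
    """
    gene_ids = [g.id for g in ann]
    if not gene_ids:
        return RegulatoryNetwork([])
    pools: Dict[Tuple[str, int], List[str]] = {}
    if blocks is not None:
        for gid, key in gene_block_labels(cfg, ann, blocks).items():
            pools.setdefault(key, []).append(gid)
    pool_keys = sorted(pools)
    edges = []
    for t in range(cfg.n_tfs):
        tf = f"tf{t + 1:04d}"
        degree = 1 + int(rng.poisson(max(cfg.tf_mean_out_degree - 1.0, 0.0)))
        pool = gene_ids
        if pool_keys and rng.random() < cfg.tf_block_coupling:
            pool = pools[pool_keys[int(rng.integers(len(pool_keys)))]]
        degree = min(degree, len(pool))
        targets = rng.choice(len(pool), size=degree, replace=False)
        edges.extend((tf, pool[i]) for i in targets)
    return RegulatoryNetwork(edges)


def simulate_go(
    cfg: SimulationConfig,
    ann: GeneAnnotation,
    blocks: Optional[BlockAssignment],
    rng: np.random.Generator,
) -> Tuple[GoDAG, GeneGoAnnotation]:
    """Rooted ontology tree plus gene annotations to its leaves.

    The tree has ``go_branching`` children per node down to ``go_depth``;
    a ``part_of_fraction`` of edges are relabeled part_of. Each gene gets
    1-3 leaf terms; with probability ``gamma`` the first term is copied from
    a previously annotated same-block gene, coupling annotation sharing to
    spatial proximity.
    """
    terms = ["T:0000001"]
    edges: List[Tuple[str, str, str]] = []
    level = ["T:0000001"]
    counter = 1
    for _depth in range(cfg.go_depth):
        nxt = []
        for parent in level:
            for _ in range(cfg.go_branching):
                counter += 1
                child = f"T:{counter:07d}"
                rel = "part_of" if rng.random() < cfg.part_of_fraction else "is_a"
                terms.append(child)
                edges.append((child, parent, rel))
                nxt.append(child)
        level = nxt
    dag = GoDAG(terms, edges)
    leaves = sorted(level)

    labels = gene_block_labels(cfg, ann, blocks) if blocks is not None else {}
    by_block: Dict[Tuple[str, int], List[str]] = {}
    mapping: Dict[str, set] = {}
    for g in ann:
        k = int(rng.integers(1, 4))
        chosen: set = set()
        key = labels.get(g.id)
        neighbors = by_block.get(key, []) if key is not None else []
        if neighbors and rng.random() < cfg.gamma:
            donor = neighbors[int(rng.integers(len(neighbors)))]
            donor_terms = sorted(mapping[donor])
            chosen.add(donor_terms[int(rng.integers(len(donor_terms)))])
        while len(chosen) < k:
            chosen.add(leaves[int(rng.integers(len(leaves)))])
        mapping[g.id] = chosen
        if key is not None:
            by_block.setdefault(key, []).append(g.id)
    return dag, GeneGoAnnotation(mapping, dag)


# ---------------------------------------------------------------------------
# bundle assembly
# ---------------------------------------------------------------------------

@dataclass
class Bundle:
    """All simulated inputs, in memory."""

    cfg: SimulationConfig
    annotation: GeneAnnotation
    blocks: BlockAssignment
    contacts: Dict[str, Dict[str, ContactMatrix]]  # cell type -> chrom -> matrix
    expression: np.ndarray
    coexpression: CoexpressionTable
    network: RegulatoryNetwork
    dag: GoDAG
    go_annotation: GeneGoAnnotation


def simulate_bundle(cfg: SimulationConfig) -> Bundle:
    """Generate every input the pipeline consumes; fully seed-deterministic."""
    rng = np.random.default_rng(cfg.seed)
    ann = simulate_genome(cfg, rng)
    blocks = simulate_blocks(cfg, rng)
    contacts = {
        ct: simulate_contacts(cfg, blocks, ct, rng) for ct in cfg.cell_types
    }
    expr = simulate_expression(cfg, ann, blocks, rng)
    coexpr = mutual_ranks_from_expression(expr, [g.id for g in ann])
    net = simulate_tf_network(cfg, ann, blocks, rng)
    dag, goann = simulate_go(cfg, ann, blocks, rng)
    return Bundle(cfg, ann, blocks, contacts, expr, coexpr, net, dag, goann)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_bundle(bundle: Bundle, out_dir: str) -> dict:
    """Write the bundle in core_io formats plus a manifest and analysis config.

    Returns the manifest dict (simulation config, seed, per-file sha256).
    The directory is directly consumable by ``chromex run --config
    <out_dir>/config.yaml``.
    """
    cfg = bundle.cfg
    os.makedirs(out_dir, exist_ok=True)
    contacts_dir = os.path.join(out_dir, "contacts")
    os.makedirs(contacts_dir, exist_ok=True)

    paths = {
        "genes": os.path.join(out_dir, "genes.bed"),
        "chrom_sizes": os.path.join(out_dir, "chrom.sizes"),
        "tf_targets": os.path.join(out_dir, "tf_targets.tsv"),
        "mutual_ranks": os.path.join(out_dir, "mutual_ranks.tsv"),
        "obo": os.path.join(out_dir, "ontology.obo"),
        "gene_go": os.path.join(out_dir, "gene_go.tsv"),
    }
    write_gene_annotation(bundle.annotation, paths["genes"])
    write_chrom_sizes(bundle.annotation.sizes, paths["chrom_sizes"])
    write_tf_targets(bundle.network, paths["tf_targets"])
    write_mutual_ranks(bundle.coexpression, paths["mutual_ranks"])
    write_obo_subset(bundle.dag, paths["obo"])
    write_gene_go(bundle.go_annotation, paths["gene_go"])

    contact_paths: Dict[str, Dict[str, str]] = {}
    for ct, per_chrom in bundle.contacts.items():
        contact_paths[ct] = {}
        for chrom, mat in per_chrom.items():
            p = os.path.join(contacts_dir, f"{ct}_{chrom}.tsv")
            write_contact_matrix(mat, p, dialect="dense")
            contact_paths[ct][chrom] = p

    # config paths are relative to the bundle directory so a bundle is
    # relocatable and byte-identical across runs with the same seed
    rel = lambda p: os.path.relpath(p, out_dir)
    analysis_config = {
        "inputs": {
            "genes": rel(paths["genes"]),
            "chrom_sizes": rel(paths["chrom_sizes"]),
            "contacts": {
                ct: {chrom: rel(p) for chrom, p in per.items()}
                for ct, per in contact_paths.items()
            },
            "contact_dialect": "dense",
            "resolution": cfg.resolution,
            "tf_targets": rel(paths["tf_targets"]),
            "mutual_ranks": rel(paths["mutual_ranks"]),
            "obo": rel(paths["obo"]),
            "gene_go": rel(paths["gene_go"]),
        },
        "thresholds": {
            "rank_match": 0.05,
            "distant": 0.2,
            "coexpressed_mr": 50,
            "n_groups": 20,
            "alpha": 0.05,
        },
        "panels": {
            "measures": ["oh", "pc"],
            "rank_measure": "oh",
            "correlation": "pearson",
            "go": True,
        },
        "seed": cfg.seed,
    }
    config_path = os.path.join(out_dir, "config.yaml")
    with open(config_path, "w") as fh:
        yaml.safe_dump(analysis_config, fh, sort_keys=True)

    files = sorted(
        list(paths.values())
        + [config_path]
        + [p for per in contact_paths.values() for p in per.values()]
    )
    cfg_dict = asdict(cfg)
    cfg_dict["cell_types"] = list(cfg_dict["cell_types"])
    manifest = {
        "simulation_config": cfg_dict,
        "seed": cfg.seed,
        "files": {os.path.relpath(p, out_dir): _sha256(p) for p in files},
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return manifest
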