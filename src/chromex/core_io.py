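"""Domain types and readers/writers for every external format the pipeline touches.

Formats
-------
* gene annotation: BED6 (tab-separated ``chrom start end name score strand``),
  0-based half-open coordinates
* chromosome sizes: 2-column TSV ``chrom<TAB>length``
* contact matrices: dense TSV (first row/column carry bin start coordinates)
  or COO TSV (``bin_i bin_j count``)
* TF->target edges: 2-column TSV
* mutual ranks: 3-column TSV ``gene_a gene_b mutual_rank``
* ontology: OBO subset ([Term] stanzas with id / is_a / relationship: part_of)
* gene->GO annotations: 2-column TSV
* pair table: headered TSV with ``#meta`` comment lines
* analysis results: JSON
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger("chromex")

STRANDS = ("+", "-", ".")

#: default semantic-contribution edge weights for the ontology DAG
DEFAULT_EDGE_WEIGHTS: Dict[str, float] = {"is_a": 0.8, "part_of": 0.6}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    """A gene interval in BED convention (0-based, half-open)."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("gene id must be a non-empty string")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.id}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"gene {self.id}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


class ChromSizes(dict):
    """Mapping chromosome name -> length in bp; all lengths positive."""

    def __init__(self, sizes: Mapping[str, int]):
        super().__init__()
        for name, length in sizes.items():
            if not name:
                raise ValidationError("chromosome name must be non-empty")
            if int(length) <= 0:
                raise ValidationError(f"chromosome {name}: non-positive length {length}")
            self[name] = int(length)


@dataclass
class GeneAnnotation:
    """Ordered gene collection plus the chromosome sizes they live on."""

    genes: List[Gene]
    sizes: ChromSizes

    def __post_init__(self) -> None:
        seen = set()
        for g in self.genes:
            if g.id in seen:
                raise ValidationError(f"duplicate gene id {g.id!r}")
            seen.add(g.id)
            if g.chrom not in self.sizes:
                raise ValidationError(f"gene {g.id}: unknown chromosome {g.chrom!r}")
            if g.end > self.sizes[g.chrom]:
                raise ValidationError(
                    f"gene {g.id}: interval end {g.end} exceeds {g.chrom} "
                    f"length {self.sizes[g.chrom]}"
                )
        self.genes = sorted(self.genes, key=lambda g: (g.chrom, g.start, g.id))
        self._by_id = {g.id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def get(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def by_chrom(self) -> Dict[str, List[Gene]]:
        out: Dict[str, List[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        return out

    def subset(self, gene_ids: Iterable[str]) -> "GeneAnnotation":
        keep = set(gene_ids)
        return GeneAnnotation([g for g in self.genes if g.id in keep], self.sizes)


def n_bins_for(chrom_length: int, resolution: int) -> int:
    """Number of fixed-width bins covering a chromosome; bin k is [k*res, (k+1)*res)."""
    return int(math.ceil(chrom_length / resolution))


@dataclass
class ContactMatrix:
    """Square symmetric matrix of observed contact counts for one chromosome."""

    chrom: str
    cell_type: str
    resolution: int
    counts: np.ndarray
    n_bins: int = field(default=0)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValidationError("contact matrix must be square")
        if self.n_bins == 0:
            self.n_bins = self.counts.shape[0]
        if self.counts.shape[0] != self.n_bins:
            raise ValidationError(
                f"{self.chrom}: matrix is {self.counts.shape[0]}x{self.counts.shape[0]} "
                f"but n_bins={self.n_bins}"
            )
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError(f"{self.chrom}: non-finite contact count")
        if np.any(self.counts < 0):
            raise ValidationError(f"{self.chrom}: negative contact count")
        if not np.allclose(self.counts, self.counts.T, rtol=0, atol=1e-9):
            raise ValidationError(f"{self.chrom}: contact matrix is not symmetric")
        # exact symmetry after the tolerance check so the invariant is crisp
        self.counts = 0.5 * (self.counts + self.counts.T)


@dataclass
class CorrelationMatrix:
    """Bin-by-bin Pearson correlation matrix; NaN marks undefined entries."""

    chrom: str
    cell_type: str
    resolution: int
    values: np.ndarray
    n_bins: int = field(default=0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError("correlation matrix must be square")
        if self.n_bins == 0:
            self.n_bins = self.values.shape[0]
        defined = np.isfinite(self.values)
        if np.any(np.abs(self.values[defined]) > 1 + 1e-9):
            raise ValidationError("correlation entries must lie in [-1, 1]")
        if not np.array_equal(defined, defined.T) or not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T), atol=1e-9
        ):
            raise ValidationError("correlation matrix is not symmetric")


class RegulatoryNetwork:
    """Bipartite TF -> target edge set with a per-gene TF-set accessor."""

    def __init__(self, edges: Iterable[Tuple[str, str]]):
        self.edges: set = set()
        for tf, target in edges:
            if not tf or not target:
                raise ValidationError("TF and target ids must be non-empty strings")
            self.edges.add((tf, target))
        self._tf_sets: Dict[str, set] = {}
        for tf, target in self.edges:
            self._tf_sets.setdefault(target, set()).add(tf)

    def tf_set(self, gene_id: str) -> FrozenSet[str]:
        return frozenset(self._tf_sets.get(gene_id, ()))

    @property
    def targets(self) -> FrozenSet[str]:
        return frozenset(self._tf_sets)

    @property
    def tfs(self) -> FrozenSet[str]:
        return frozenset(tf for tf, _ in self.edges)

    def __len__(self) -> int:
        return len(self.edges)


class CoexpressionTable:
    """Unordered gene-pair -> mutual rank (>= 1) mapping."""

    def __init__(self, entries: Optional[Mapping[Tuple[str, str], float]] = None):
        self._data: Dict[Tuple[str, str], float] = {}
        self._genes: set = set()
        if entries:
            for (a, b), mr in entries.items():
                self.add(a, b, mr)

    @staticmethod
    def _key(a: str, b: str) -> Tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, mr: float) -> None:
        if a == b:
            raise ValidationError(f"self-pair ({a}, {b}) in mutual-rank table")
        mr = float(mr)
        if not (mr >= 1):
            raise ValidationError(f"mutual rank must be >= 1, got {mr} for ({a}, {b})")
        key = self._key(a, b)
        if key in self._data and self._data[key] != mr:
            raise ValidationError(
                f"conflicting mutual ranks for pair {key}: {self._data[key]} vs {mr}"
            )
        self._data[key] = mr
        self._genes.update(key)

    def get(self, a: str, b: str) -> float:
        """Symmetric lookup; NaN when the pair is absent."""
        return self._data.get(self._key(a, b), float("nan"))

    @property
    def genes(self) -> FrozenSet[str]:
        return frozenset(self._genes)

    def items(self):
        return self._data.items()

    def __len__(self) -> int:
        return len(self._data)


class GoDAG:
    """Ontology terms with typed child->parent edges and per-relation weights."""

    def __init__(
        self,
        terms: Iterable[str],
        edges: Iterable[Tuple[str, str, str]],
        edge_weights: Optional[Mapping[str, float]] = None,
    ):
        self.terms = set(terms)
        self.edge_weights = dict(edge_weights or DEFAULT_EDGE_WEIGHTS)
        for rel, w in self.edge_weights.items():
            if not (0.0 < w < 1.0):
                raise ValidationError(f"edge weight for {rel!r} must be in (0,1), got {w}")
        self.parents: Dict[str, List[Tuple[str, str]]] = {t: [] for t in self.terms}
        self.children: Dict[str, List[Tuple[str, str]]] = {t: [] for t in self.terms}
        self.edges: List[Tuple[str, str, str]] = []
        for child, parent, rel in edges:
            if child not in self.terms or parent not in self.terms:
                raise ValidationError(f"edge ({child}, {parent}) references unknown term")
            if rel not in self.edge_weights:
                raise ValidationError(f"unknown relation {rel!r}")
            self.parents[child].append((parent, rel))
            self.children[parent].append((child, rel))
            self.edges.append((child, parent, rel))
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from((c, p) for c, p, _ in self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError("ontology graph contains a cycle")

    @property
    def roots(self) -> FrozenSet[str]:
        return frozenset(t for t in self.terms if not self.parents[t])

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)


class GeneGoAnnotation(dict):
    """Mapping gene id -> frozenset of ontology term ids."""

    def __init__(self, mapping: Mapping[str, Iterable[str]], dag: GoDAG):
        super().__init__()
        for gene, terms in mapping.items():
            terms = frozenset(terms)
            for t in terms:
                if t not in dag:
                    raise ValidationError(
                        f"gene {gene}: annotation to unknown term {t!r}"
                    )
            self[gene] = terms


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str) -> ChromSizes:
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            name, length = fields
            try:
                length_i = int(length)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad length {length!r}") from exc
            if name in sizes:
                raise ValidationError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            sizes[name] = length_i
    return ChromSizes(sizes)


def read_gene_annotation(path: str, sizes_path: str) -> GeneAnnotation:
    """Read a BED6 file plus a chrom.sizes file into a validated annotation."""
    sizes = read_chrom_sizes(sizes_path)
    genes: List[Gene] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 BED fields, got {len(fields)}"
                )
            chrom, start, end, name, _score, strand = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            try:
                genes.append(Gene(name, chrom, start_i, end_i, strand))
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return GeneAnnotation(genes, sizes)


def read_contact_matrix(
    path: str,
    chrom: str,
    cell_type: str,
    resolution: int,
    chrom_length: int,
    dialect: str = "dense",
) -> ContactMatrix:
    """Read a contact matrix in either the dense or the COO TSV dialect."""
    n = n_bins_for(chrom_length, resolution)
    if dialect == "dense":
        raw = pd.read_csv(path, sep="\t", index_col=0)
        counts = raw.to_numpy(dtype=float)
        if counts.shape != (n, n):
            raise ValidationError(
                f"{path}: dense matrix is {counts.shape}, expected ({n}, {n})"
            )
        if not np.allclose(counts, counts.T, rtol=0, atol=1e-9):
            raise ValidationError(f"{path}: dense matrix asymmetric beyond 1e-9")
    elif dialect == "coo":
        counts = np.zeros((n, n), dtype=float)
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 3:
                    raise ParseError(
                        f"{path}:{lineno}: expected 3 fields, got {len(fields)}"
                    )
                try:
                    i, j, c = int(fields[0]), int(fields[1]), float(fields[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad COO record") from exc
                if i < 0 or j < 0 or i >= n or j >= n:
                    raise ValidationError(
                        f"{path}:{lineno}: bin index ({i},{j}) outside 0..{n - 1}"
                    )
                if c < 0:
                    raise ValidationError(f"{path}:{lineno}: negative count {c}")
                counts[i, j] = c
                counts[j, i] = c
    else:
        raise ValidationError(f"unknown contact-matrix dialect {dialect!r}")
    return ContactMatrix(chrom, cell_type, resolution, counts, n)


def read_tf_targets(path: str) -> RegulatoryNetwork:
    edges: List[Tuple[str, str]] = []
    seen = set()
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            edge = (fields[0], fields[1])
            if edge in seen:
                n_dup += 1
                continue
            seen.add(edge)
            edges.append(edge)
    if n_dup:
        logger.warning("%s: %d duplicate TF-target edge(s) collapsed", path, n_dup)
    return RegulatoryNetwork(edges)


def read_mutual_ranks(path: str) -> CoexpressionTable:
    table = CoexpressionTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
            try:
                mr = float(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad mutual rank") from exc
            try:
                table.add(fields[0], fields[1], mr)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return table


_OBO_ISA = re.compile(r"^is_a:\s*(\S+)")
_OBO_RELATION = re.compile(r"^relationship:\s*(\S+)\s+(\S+)")


def read_obo_subset(
    path: str, weights: Optional[Mapping[str, float]] = None
) -> GoDAG:
    """Parse an OBO subset: [Term] stanzas with id, is_a and part_of only.

    Terms carrying a ``namespace`` other than ``biological_process`` are
    rejected — the analysis is defined on that namespace alone.
    """
    terms: List[str] = []
    edges: List[Tuple[str, str, str]] = []
    current: Optional[str] = None
    in_term = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if line == "[Term]":
                in_term = True
                current = None
                continue
            if line.startswith("["):
                in_term = False
                continue
            if not in_term or not line:
                continue
            if line.startswith("id:"):
                current = line.split(":", 1)[1].strip()
                terms.append(current)
                continue
            if current is None:
                continue
            if line.startswith("namespace:"):
                ns = line.split(":", 1)[1].strip()
                if ns != "biological_process":
                    raise ValidationError(
                        f"{path}:{lineno}: term {current} has namespace {ns!r}; "
                        "only biological_process is supported"
                    )
                continue
            m = _OBO_ISA.match(line)
            if m:
                edges.append((current, m.group(1), "is_a"))
                continue
            m = _OBO_RELATION.match(line)
            if m:
                rel, parent = m.group(1), m.group(2)
                if rel == "part_of":
                    edges.append((current, parent, "part_of"))
    return GoDAG(terms, edges, weights)


def read_gene_go(path: str, dag: GoDAG) -> GeneGoAnnotation:
    mapping: Dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            mapping.setdefault(fields[0], set()).add(fields[1])
    return GeneGoAnnotation(mapping, dag)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_chrom_sizes(sizes: Mapping[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for name in sorted(sizes):
            fh.write(f"{name}\t{sizes[name]}\n")


def write_gene_annotation(ann: GeneAnnotation, path: str) -> None:
    with open(path, "w") as fh:
        for g in ann:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.id}\t0\t{g.strand}\n")


def write_contact_matrix(m: ContactMatrix, path: str, dialect: str = "dense") -> None:
    if dialect == "dense":
        coords = [i * m.resolution for i in range(m.n_bins)]
        df = pd.DataFrame(m.counts, index=coords, columns=coords)
        df.to_csv(path, sep="\t")
    elif dialect == "coo":
        with open(path, "w") as fh:
            for i in range(m.n_bins):
                for j in range(i, m.n_bins):
                    if m.counts[i, j] != 0:
                        fh.write(f"{i}\t{j}\t{m.counts[i, j]:.17g}\n")
    else:
        raise ValidationError(f"unknown contact-matrix dialect {dialect!r}")


def write_tf_targets(net: RegulatoryNetwork, path: str) -> None:
    with open(path, "w") as fh:
        for tf, target in sorted(net.edges):
            fh.write(f"{tf}\t{target}\n")


def write_mutual_ranks(table: CoexpressionTable, path: str) -> None:
    with open(path, "w") as fh:
        for (a, b), mr in sorted(table.items()):
            fh.write(f"{a}\t{b}\t{mr:.17g}\n")


def write_obo_subset(dag: GoDAG, path: str) -> None:
    by_child: Dict[str, List[Tuple[str, str]]] = {t: [] for t in dag.terms}
    for child, parent, rel in dag.edges:
        by_child[child].append((parent, rel))
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {term}\nnamespace: biological_process\n")
            for parent, rel in sorted(by_child[term]):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")


def write_gene_go(ann: Mapping[str, Iterable[str]], path: str) -> None:
    with open(path, "w") as fh:
        for gene in sorted(ann):
            for term in sorted(ann[gene]):
                fh.write(f"{gene}\t{term}\n")


def write_pair_table(table, path: str) -> None:
    """Write a GenePairTable as a headered TSV.

    Leading ``#meta`` lines carry the provenance metadata as JSON so the
    table round-trips exactly through :func:`read_pair_table`.
    """
    with open(path, "w") as fh:
        fh.write("#meta\t" + json.dumps(table.meta, sort_keys=True) + "\n")
        table.df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_pair_table(path: str):
    from .pair_metrics import GenePairTable

    meta: Dict = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#meta\t"):
                meta = json.loads(line.split("\t", 1)[1])
                skip += 1
            else:
                break
    df = pd.read_csv(
        path, sep="\t", skiprows=skip, na_values=["NA"], keep_default_na=False
    )
    return GenePairTable(df, meta)


def _json_safe(obj):
    """Convert numpy scalars and NaN/inf to JSON-representable values."""
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if math.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _json_safe(obj.tolist())
    return obj


def write_results(results, path: str) -> None:
    """Write analysis results as deterministic JSON (sorted keys, NaN -> null)."""
    payload = results.to_dict() if hasattr(results, "to_dict") else results
    with open(path, "w") as fh:
        json.dump(_json_safe(payload), fh, sort_keys=True, indent=2)
        fh.write("\n")
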