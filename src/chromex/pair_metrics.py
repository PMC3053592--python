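"""Per-pair scalar statistics: regulator-set similarity, normalized distance,
mutual-rank retrieval, and the central gene-pair table."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional

import numpy as np
import pandas as pd

from .core_io import ChromSizes, CoexpressionTable, Gene
from .errors import UndefinedSimilarityError, UsageError, ValidationError

#: fixed scalar columns of the pair table, in output order
BASE_COLUMNS = ["gene_a", "gene_b", "chrom", "norm_dist", "mutual_rank", "tcs", "go_sim"]
#: per-cell-type column templates, appended in cell-type order
CELLTYPE_COLUMNS = ["oh_{ct}", "pc_{ct}", "rank_pct_{ct}"]


def tcs(tfs_a: FrozenSet[str], tfs_b: FrozenSet[str]) -> float:
    """Regulator-set similarity of two genes.

    One minus the number of regulators binding exactly one of the genes,
    divided by the total number of regulator-target interactions of the pair.
    1 = identical regulator sets, 0 = disjoint (both nonempty).
    """
    total = len(tfs_a) + len(tfs_b)
    if total == 0:
        raise UndefinedSimilarityError(
            "TCS is undefined when both genes have empty TF sets"
        )
    return 1.0 - len(set(tfs_a) ^ set(tfs_b)) / total


def normalized_distance(ga: Gene, gb: Gene, sizes: ChromSizes) -> float:
    """Midpoint separation divided by chromosome length; in [0, 1)."""
    if ga.chrom != gb.chrom:
        raise UsageError(
            f"normalized distance needs same-chromosome genes, got "
            f"{ga.chrom} and {gb.chrom}"
        )
    return abs(ga.midpoint - gb.midpoint) / sizes[ga.chrom]


def lookup_mutual_rank(table: CoexpressionTable, a: str, b: str) -> float:
    """Symmetric mutual-rank lookup; NaN when the pair is absent."""
    if a == b:
        raise UsageError(f"mutual rank of a gene with itself ({a}) is undefined")
    return table.get(a, b)


@dataclass
class PairRecord:
    """One unordered intra-chromosomal gene pair with all per-pair statistics."""

    gene_a: str
    gene_b: str
    chrom: str
    oh: Dict[str, float] = field(default_factory=dict)
    pc: Dict[str, float] = field(default_factory=dict)
    rank_pct: Dict[str, float] = field(default_factory=dict)
    mutual_rank: float = float("nan")
    tcs: float = float("nan")
    norm_dist: float = float("nan")
    go_sim: float = float("nan")

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValidationError(
                f"pair key must be canonical: {self.gene_a!r} < {self.gene_b!r} fails"
            )


def pair_columns(cell_types) -> List[str]:
    cols = list(BASE_COLUMNS)
    for ct in cell_types:
        cols.extend(tpl.format(ct=ct) for tpl in CELLTYPE_COLUMNS)
    return cols


class GenePairTable:
    """Ordered collection of pair records with provenance metadata.

    Backed by a :class:`pandas.DataFrame` with the documented fixed column
    order (see :data:`BASE_COLUMNS` / :data:`CELLTYPE_COLUMNS`). ``meta``
    carries resolution, cell types and every filter applied so far.
    """

    def __init__(self, df: pd.DataFrame, meta: Optional[dict] = None):
        self.meta = dict(meta or {})
        cts = self.meta.get("cell_types")
        if cts is None:
            cts = sorted(
                c[len("oh_"):] for c in df.columns if c.startswith("oh_")
            )
            self.meta["cell_types"] = cts
        cols = pair_columns(cts)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValidationError(f"pair table missing columns: {missing}")
        keys = list(zip(df["gene_a"], df["gene_b"]))
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate gene pair in table")
        if (df["gene_a"] >= df["gene_b"]).any():
            raise ValidationError("pair keys must satisfy gene_a < gene_b")
        self.df = df[cols].reset_index(drop=True)

    @classmethod
    def from_records(
        cls, records: List[PairRecord], cell_types, meta: Optional[dict] = None
    ) -> "GenePairTable":
        rows = []
        for r in records:
            row = {
                "gene_a": r.gene_a,
                "gene_b": r.gene_b,
                "chrom": r.chrom,
                "norm_dist": r.norm_dist,
                "mutual_rank": r.mutual_rank,
                "tcs": r.tcs,
                "go_sim": r.go_sim,
            }
            for ct in cell_types:
                row[f"oh_{ct}"] = r.oh.get(ct, np.nan)
                row[f"pc_{ct}"] = r.pc.get(ct, np.nan)
                row[f"rank_pct_{ct}"] = r.rank_pct.get(ct, np.nan)
            rows.append(row)
        meta = dict(meta or {})
        meta["cell_types"] = list(cell_types)
        df = pd.DataFrame(rows, columns=pair_columns(cell_types))
        return cls(df, meta)

    @property
    def cell_types(self) -> List[str]:
        return list(self.meta["cell_types"])

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> List[PairRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            out.append(
                PairRecord(
                    gene_a=d["gene_a"],
                    gene_b=d["gene_b"],
                    chrom=d["chrom"],
                    oh={ct: d[f"oh_{ct}"] for ct in self.cell_types},
                    pc={ct: d[f"pc_{ct}"] for ct in self.cell_types},
                    rank_pct={ct: d[f"rank_pct_{ct}"] for ct in self.cell_types},
                    mutual_rank=d["mutual_rank"],
                    tcs=d["tcs"],
                    norm_dist=d["norm_dist"],
                    go_sim=d["go_sim"],
                )
            )
        return out

    def filtered(self, mask, filter_desc: dict) -> "GenePairTable":
        """New table keeping rows where ``mask`` is True; records the filter."""
        meta = dict(self.meta)
        filters = list(meta.get("filters", []))
        desc = dict(filter_desc)
        desc["n_before"] = int(len(self.df))
        desc["n_after"] = int(np.asarray(mask).sum())
        filters.append(desc)
        meta["filters"] = filters
        return GenePairTable(self.df[np.asarray(mask)].reset_index(drop=True), meta)
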