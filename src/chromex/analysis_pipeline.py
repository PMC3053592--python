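"""Pipeline orchestration.

Pair-table assembly, cross-cell-type rank matching, stratification,
equal-size binned correlation tests with Bonferroni correction, and the
co-expressed-vs-rest t-test — plus the end-to-end driver behind
``chromex run``.
"""

from __future__ import annotations

import contextlib
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

import yaml

from . import core_io, go_semsim, hic_metrics
from .core_io import (
    CoexpressionTable,
    ContactMatrix,
    GeneAnnotation,
    GeneGoAnnotation,
    GoDAG,
    RegulatoryNetwork,
)
from .errors import (
    ChromexError,
    ConfigError,
    InsufficientDataError,
    UsageError,
    ValidationError,
)
from .pair_metrics import GenePairTable, pair_columns

logger = logging.getLogger("chromex")

DEFAULT_THRESHOLDS = {
    "rank_match": 0.05,
    "distant": 0.2,
    "coexpressed_mr": 50.0,
    "n_groups": 20,
    "alpha": 0.05,
}

STRATUM_RULES = ("distant", "tcs_zero", "tcs_nonzero", "coexpressed")


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class BinnedSeries:
    """Per-group summaries from equal-size binning along x."""

    n_groups: int
    n: np.ndarray          # samples per group (0 = missing group)
    mean_x: np.ndarray     # NaN for missing groups
    mean_y: np.ndarray
    sem_y: np.ndarray
    x_min: np.ndarray      # group x-range (the group "definition")
    x_max: np.ndarray

    @property
    def nonempty(self) -> np.ndarray:
        return self.n > 0

    def to_dict(self) -> dict:
        return {
            "n_groups": int(self.n_groups),
            "n": self.n.tolist(),
            "mean_x": self.mean_x.tolist(),
            "mean_y": self.mean_y.tolist(),
            "sem_y": self.sem_y.tolist(),
            "x_min": self.x_min.tolist(),
            "x_max": self.x_max.tolist(),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": np.arange(self.n_groups),
                "n": self.n,
                "mean_x": self.mean_x,
                "mean_y": self.mean_y,
                "sem_y": self.sem_y,
                "x_min": self.x_min,
                "x_max": self.x_max,
            }
        )


@dataclass
class PanelResult:
    """Correlation over group means for one measure/cell-type panel."""

    label: str
    r: float
    p: float
    n_pairs: int
    n_groups_nonempty: int
    method: str = "pearson"
    series: Optional[BinnedSeries] = None
    threshold: Optional[float] = None
    significant: Optional[bool] = None

    def to_dict(self) -> dict:
        out = {
            "label": self.label,
            "r": self.r,
            "p": self.p,
            "n_pairs": int(self.n_pairs),
            "n_groups_nonempty": int(self.n_groups_nonempty),
            "method": self.method,
            "threshold": self.threshold,
            "significant": self.significant,
        }
        if self.series is not None:
            out["groups"] = self.series.to_dict()
        return out


@dataclass
class TTestResult:
    statistic: float
    p: float
    n_coexpressed: int
    n_rest: int
    mean_coexpressed: float
    mean_rest: float

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p": self.p,
            "n_coexpressed": int(self.n_coexpressed),
            "n_rest": int(self.n_rest),
            "mean_coexpressed": self.mean_coexpressed,
            "mean_rest": self.mean_rest,
        }


@dataclass
class AnalysisResults:
    meta: dict
    counts: dict
    panels: Dict[str, Dict[str, dict]] = field(default_factory=dict)
    ttests: Dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "meta": self.meta,
            "counts": self.counts,
            "panels": self.panels,
            "ttests": self.ttests,
        }


# ---------------------------------------------------------------------------
# pair-table assembly
# ---------------------------------------------------------------------------

def _popcount(x: int) -> int:
    return x.bit_count()


def build_pair_table(
    ann: GeneAnnotation,
    matrices: Dict[str, Dict[str, ContactMatrix]],
    coexpr: CoexpressionTable,
    net: RegulatoryNetwork,
    goann: Optional[GeneGoAnnotation] = None,
    dag: Optional[GoDAG] = None,
    *,
    rank_measure: str = "oh",
    compute_go: Optional[bool] = None,
) -> GenePairTable:
    """One record per unordered intra-chromosomal pair of retained genes.

    Retained genes are those appearing in the co-expression table and having
    at least one regulator in the network. Each record carries OH and PC per
    cell type (weighted bin average), mutual rank, TCS, normalized distance
    and — when an ontology is supplied — gene-level GO similarity. Percentile
    ranks of ``rank_measure`` across the whole table are populated per cell
    type for the downstream rank-match filter.
    """
    if compute_go is None:
        compute_go = goann is not None and dag is not None
    if compute_go and (goann is None or dag is None):
        raise UsageError("compute_go requires both an ontology and annotations")
    if rank_measure not in ("oh", "pc"):
        raise ConfigError(f"rank_measure must be 'oh' or 'pc', got {rank_measure!r}")

    coexpr_genes = coexpr.genes
    retained = [g for g in ann if g.id in coexpr_genes and net.tf_set(g.id)]
    if not retained:
        raise InsufficientDataError(
            "empty cohort: no gene has both co-expression and TF annotation"
        )
    cell_types = sorted(matrices)
    if not cell_types or not any(matrices[ct] for ct in cell_types):
        raise ConfigError("no contact matrices supplied")
    resolution = next(
        m.resolution for ct in cell_types for m in matrices[ct].values()
    )

    tf_bits: Dict[str, int] = {}
    masks: Dict[str, int] = {}
    for g in retained:
        m = 0
        for tf in net.tf_set(g.id):
            if tf not in tf_bits:
                tf_bits[tf] = len(tf_bits)
            m |= 1 << tf_bits[tf]
        masks[g.id] = m

    go_cache: Dict = {}
    by_chrom: Dict[str, List] = {}
    for g in retained:
        by_chrom.setdefault(g.chrom, []).append(g)

    frames = []
    for chrom in sorted(by_chrom):
        genes_c = by_chrom[chrom]
        if len(genes_c) < 2:
            continue
        for ct in cell_types:
            if chrom not in matrices[ct]:
                raise ValidationError(
                    f"cell type {ct}: no contact matrix for chromosome {chrom}"
                )
        n_bins = matrices[cell_types[0]][chrom].n_bins
        w = hic_metrics.gene_weight_matrix(genes_c, resolution, n_bins)
        iu, ju = np.triu_indices(len(genes_c), k=1)

        ids = np.array([g.id for g in genes_c])
        swap = ids[iu] > ids[ju]
        a_ids = np.where(swap, ids[ju], ids[iu])
        b_ids = np.where(swap, ids[iu], ids[ju])
        mid = np.array([g.midpoint for g in genes_c])
        nd = np.abs(mid[iu] - mid[ju]) / ann.sizes[chrom]
        mr = np.array(
            [coexpr.get(a, b) for a, b in zip(ids[iu], ids[ju])], dtype=float
        )
        mlist = [masks[i] for i in ids]
        tcs_vals = np.array(
            [
                1.0
                - _popcount(mlist[i] ^ mlist[j])
                / (_popcount(mlist[i]) + _popcount(mlist[j]))
                for i, j in zip(iu, ju)
            ]
        )
        data = {
            "gene_a": a_ids,
            "gene_b": b_ids,
            "chrom": chrom,
            "norm_dist": nd,
            "mutual_rank": mr,
            "tcs": tcs_vals,
            "go_sim": np.full(len(iu), np.nan),
        }
        if compute_go:
            data["go_sim"] = np.array(
                [
                    go_semsim.gene_similarity(dag, goann, a, b, _cache=go_cache)
                    for a, b in zip(ids[iu], ids[ju])
                ]
            )
        for ct in cell_types:
            mat = matrices[ct][chrom]
            oh_pairs = hic_metrics.pairwise_gene_interactions(w, mat.counts)
            pc = hic_metrics.correlation_matrix(
                hic_metrics.observed_over_expected(mat),
                chrom=chrom,
                cell_type=ct,
                resolution=resolution,
            )
            pc_pairs = hic_metrics.pairwise_gene_interactions(w, pc.values)
            data[f"oh_{ct}"] = oh_pairs[iu, ju]
            data[f"pc_{ct}"] = pc_pairs[iu, ju]
            data[f"rank_pct_{ct}"] = np.nan
        frames.append(pd.DataFrame(data))

    if not frames:
        raise InsufficientDataError(
            "empty cohort: no chromosome holds two retained genes"
        )
    df = pd.concat(frames, ignore_index=True)[pair_columns(cell_types)]
    for ct in cell_types:
        df[f"rank_pct_{ct}"] = hic_metrics.percentile_ranks(
            df[f"{rank_measure}_{ct}"].to_numpy()
        )
    meta = {
        "cell_types": cell_types,
        "resolution": int(resolution),
        "rank_measure": rank_measure,
        "go_computed": bool(compute_go),
        "n_genes_retained": len(retained),
        "filters": [],
    }
    logger.info(
        "pair table built: %d retained genes, %d intra-chromosomal pairs",
        len(retained),
        len(df),
    )
    return GenePairTable(df, meta)


# ---------------------------------------------------------------------------
# filters and strata
# ---------------------------------------------------------------------------

def rank_match_filter(
    table: GenePairTable, cell_a: str, cell_b: str, threshold: float
) -> GenePairTable:
    """Keep pairs whose percentile-rank difference across cell types is below
    ``threshold`` (strict inequality). Pairs with an undefined rank drop out."""
    if not (0.0 < threshold <= 1.0):
        raise ConfigError(f"rank-match threshold must be in (0, 1], got {threshold}")
    ra = table.df[f"rank_pct_{cell_a}"].to_numpy()
    rb = table.df[f"rank_pct_{cell_b}"].to_numpy()
    with np.errstate(invalid="ignore"):
        mask = np.abs(ra - rb) < threshold
    mask &= np.isfinite(ra) & np.isfinite(rb)
    out = table.filtered(
        mask,
        {
            "filter": "rank_match",
            "cell_types": [cell_a, cell_b],
            "threshold": float(threshold),
            "measure": table.meta.get("rank_measure", "oh"),
        },
    )
    logger.info("rank match (<%g): %d -> %d pairs", threshold, len(table), len(out))
    return out


def stratify(
    table: GenePairTable,
    rule: str,
    *,
    distant_threshold: float = 0.2,
    mr_threshold: float = 50.0,
) -> GenePairTable:
    """Filter the table to one of the named strata."""
    df = table.df
    if rule == "distant":
        mask = df["norm_dist"].to_numpy() > distant_threshold
        desc = {"filter": "distant", "threshold": float(distant_threshold)}
    elif rule == "tcs_zero":
        mask = df["tcs"].to_numpy() == 0.0
        desc = {"filter": "tcs_zero"}
    elif rule == "tcs_nonzero":
        mask = df["tcs"].to_numpy() > 0.0
        desc = {"filter": "tcs_nonzero"}
    elif rule == "coexpressed":
        with np.errstate(invalid="ignore"):
            mask = df["mutual_rank"].to_numpy() <= mr_threshold
        mask &= np.isfinite(df["mutual_rank"].to_numpy())
        desc = {"filter": "coexpressed", "mr_threshold": float(mr_threshold)}
    else:
        raise ConfigError(f"unknown stratification rule {rule!r}")
    out = table.filtered(mask, desc)
    logger.info("stratum %s: %d -> %d pairs", rule, len(table), len(out))
    return out


# ---------------------------------------------------------------------------
# binning and tests
# ---------------------------------------------------------------------------

def equal_size_binning(x, n_groups: int) -> np.ndarray:
    """Group index (0..n_groups-1) per sample, equal-size cuts along sorted x.

    All samples sharing an x value land in the group of the first sample of
    their tie run, so ties are never split; some group indices may end up
    with no members. With all-distinct x, group sizes differ by at most 1.
    """
    if n_groups < 2:
        raise ConfigError(f"n_groups must be >= 2, got {n_groups}")
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValidationError("x must be a non-empty 1-D vector")
    if not np.all(np.isfinite(x)):
        raise ValidationError("x must be finite")
    n = len(x)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    tentative = (np.arange(n) * n_groups) // n
    run_start = np.r_[True, xs[1:] != xs[:-1]]
    run_id = np.cumsum(run_start) - 1
    groups_sorted = tentative[np.flatnonzero(run_start)][run_id]
    assign = np.empty(n, dtype=int)
    assign[order] = groups_sorted
    return assign


def binned_series(x, y, n_groups: int) -> BinnedSeries:
    """Equal-size binning of x plus per-group means and standard errors of y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    assign = equal_size_binning(x, n_groups)
    n = np.zeros(n_groups, dtype=int)
    mean_x = np.full(n_groups, np.nan)
    mean_y = np.full(n_groups, np.nan)
    sem_y = np.full(n_groups, np.nan)
    x_min = np.full(n_groups, np.nan)
    x_max = np.full(n_groups, np.nan)
    for g in range(n_groups):
        sel = assign == g
        cnt = int(sel.sum())
        n[g] = cnt
        if cnt == 0:
            continue
        mean_x[g] = x[sel].mean()
        mean_y[g] = y[sel].mean()
        x_min[g] = x[sel].min()
        x_max[g] = x[sel].max()
        if cnt > 1:
            sem_y[g] = y[sel].std(ddof=1) / np.sqrt(cnt)
    return BinnedSeries(n_groups, n, mean_x, mean_y, sem_y, x_min, x_max)


def binned_correlation_test(
    x,
    y,
    n_groups: int,
    method: str = "pearson",
    label: str = "",
) -> PanelResult:
    """Correlation test on the (mean_x, mean_y) points of nonempty groups.

    Pairs with a missing x or y are excluded up front; they drop out of this
    panel only.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) == 0:
        raise InsufficientDataError(f"panel {label or '?'}: no complete pairs")
    series = binned_series(x, y, n_groups)
    sel = series.nonempty
    k = int(sel.sum())
    if k < 3:
        raise InsufficientDataError(
            f"panel {label or '?'}: only {k} nonempty group(s), need >= 3"
        )
    mx = series.mean_x[sel]
    my = series.mean_y[sel]
    if np.std(mx) == 0 or np.std(my) == 0:
        raise InsufficientDataError(
            f"panel {label or '?'}: zero variance across group means"
        )
    if method == "pearson":
        res = scipy.stats.pearsonr(mx, my)
    elif method == "spearman":
        res = scipy.stats.spearmanr(mx, my)
    else:
        raise ConfigError(f"unknown correlation method {method!r}")
    return PanelResult(
        label=label,
        r=float(res.statistic),
        p=float(res.pvalue),
        n_pairs=int(len(x)),
        n_groups_nonempty=k,
        method=method,
        series=series,
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if not (0.0 < alpha < 1.0):
        raise ConfigError(f"alpha must be in (0, 1), got {alpha}")
    if n_tests < 1:
        raise ConfigError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


def coexpressed_vs_all_ttest(
    table: GenePairTable,
    measure: str,
    cell_type: str,
    mr_threshold: float = 50.0,
) -> TTestResult:
    """Welch t-test: measure in the MR <= threshold stratum vs all other pairs."""
    col = f"{measure}_{cell_type}"
    if col not in table.df.columns:
        raise UsageError(f"no column {col!r} in pair table")
    vals = table.df[col].to_numpy(dtype=float)
    mr = table.df["mutual_rank"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        coex = np.isfinite(mr) & (mr <= mr_threshold)
    fin = np.isfinite(vals)
    a = vals[coex & fin]
    b = vals[~coex & fin]
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError(
            f"t-test {col}: need >= 2 values per group, got {len(a)} and {len(b)}"
        )
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        n_coexpressed=len(a),
        n_rest=len(b),
        mean_coexpressed=float(a.mean()),
        mean_rest=float(b.mean()),
    )


# ---------------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------------

@contextlib.contextmanager
def _stage(name: str):
    """Prefix any chromex error escaping this stage with the stage name."""
    try:
        yield
    except ChromexError as exc:
        raise type(exc)(f"[stage: {name}] {exc}") from exc


def load_config(path: str) -> dict:
    """Read a YAML config; relative input paths resolve against its directory."""
    import os

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "inputs" not in cfg:
        raise ConfigError(f"{path}: config must be a mapping with an 'inputs' section")
    base = os.path.dirname(os.path.abspath(path))
    inputs = cfg["inputs"]
    for key in ("genes", "chrom_sizes", "tf_targets", "mutual_ranks", "obo", "gene_go"):
        if inputs.get(key):
            inputs[key] = os.path.join(base, inputs[key])
    for per_chrom in (inputs.get("contacts") or {}).values():
        for chrom, p in per_chrom.items():
            per_chrom[chrom] = os.path.join(base, p)
    return cfg


def _read_inputs(cfg: dict):
    inputs = cfg["inputs"]
    ann = core_io.read_gene_annotation(inputs["genes"], inputs["chrom_sizes"])
    resolution = int(inputs["resolution"])
    dialect = inputs.get("contact_dialect", "dense")
    matrices: Dict[str, Dict[str, ContactMatrix]] = {}
    for ct, per_chrom in inputs["contacts"].items():
        matrices[ct] = {}
        for chrom, path in per_chrom.items():
            matrices[ct][chrom] = core_io.read_contact_matrix(
                path, chrom, ct, resolution, ann.sizes[chrom], dialect
            )
    net = core_io.read_tf_targets(inputs["tf_targets"])
    coexpr = core_io.read_mutual_ranks(inputs["mutual_ranks"])
    dag = goann = None
    if inputs.get("obo") and inputs.get("gene_go"):
        dag = core_io.read_obo_subset(inputs["obo"])
        goann = core_io.read_gene_go(inputs["gene_go"], dag)
    return ann, matrices, coexpr, net, dag, goann


def _panel_block(
    table: GenePairTable,
    x_col,
    y_cols: Sequence[str],
    n_groups: int,
    alpha: float,
    method: str,
) -> Dict[str, dict]:
    """Run one figure's family of panels; Bonferroni family = panel count."""
    thr = bonferroni_threshold(alpha, len(y_cols))
    out: Dict[str, dict] = {}
    for y_col in y_cols:
        label = y_col
        try:
            panel = binned_correlation_test(
                table.df[x_col].to_numpy(),
                table.df[y_col].to_numpy(),
                n_groups,
                method=method,
                label=label,
            )
            panel.threshold = thr
            panel.significant = bool(panel.p < thr)
            out[label] = panel.to_dict()
        except InsufficientDataError as exc:
            logger.warning("panel %s skipped: %s", label, exc)
            out[label] = {"label": label, "error": str(exc), "threshold": thr}
    return out


def run_full_analysis(
    config: dict,
    out_dir: Optional[str] = None,
    make_plots: bool = False,
) -> AnalysisResults:
    """Execute the whole inference chain and optionally write all outputs.

    Stages: read inputs -> build pair table -> rank-match filter ->
    strata -> binned correlation panels (measure x cell type, per stratum)
    -> GO panels -> co-expressed-vs-rest t-tests. Pair counts are logged at
    every stage and recorded in the results.
    """
    thresholds = dict(DEFAULT_THRESHOLDS)
    thresholds.update(config.get("thresholds", {}))
    panels_cfg = dict(config.get("panels", {}))
    measures = list(panels_cfg.get("measures", ["oh", "pc"]))
    rank_measure = panels_cfg.get("rank_measure", "oh")
    method = panels_cfg.get("correlation", "pearson")
    want_go = bool(panels_cfg.get("go", True))
    n_groups = int(thresholds["n_groups"])
    alpha = float(thresholds["alpha"])
    seed = config.get("seed")

    with _stage("read_inputs"):
        ann, matrices, coexpr, net, dag, goann = _read_inputs(config)
    cell_types = sorted(matrices)

    with _stage("build_pair_table"):
        table = build_pair_table(
            ann,
            matrices,
            coexpr,
            net,
            goann,
            dag,
            rank_measure=rank_measure,
            compute_go=want_go and dag is not None,
        )
    with _stage("rank_match"):
        if len(cell_types) >= 2:
            matched = rank_match_filter(
                table, cell_types[0], cell_types[1], float(thresholds["rank_match"])
            )
        else:
            matched = table

    strata: Dict[str, GenePairTable] = {"all": matched}
    with _stage("stratify"):
        for rule in STRATUM_RULES:
            strata[rule] = stratify(
                matched,
                rule,
                distant_threshold=float(thresholds["distant"]),
                mr_threshold=float(thresholds["coexpressed_mr"]),
            )

    measure_cols = [f"{m}_{ct}" for m in measures for ct in cell_types]
    panels: Dict[str, Dict[str, dict]] = {}
    with _stage("binned_correlation"):
        for name, stratum in strata.items():
            panels[name] = _panel_block(
                stratum, "mutual_rank", measure_cols, n_groups, alpha, method
            )
    go_available = matched.meta.get("go_computed", False)
    if go_available:
        with _stage("go_panels"):
            go_vs_interaction: Dict[str, dict] = {}
            thr4 = bonferroni_threshold(alpha, len(measure_cols))
            for col in measure_cols:
                label = f"go_sim~{col}"
                try:
                    panel = binned_correlation_test(
                        matched.df[col].to_numpy(),
                        matched.df["go_sim"].to_numpy(),
                        n_groups,
                        method=method,
                        label=label,
                    )
                    panel.threshold = thr4
                    panel.significant = bool(panel.p < thr4)
                    go_vs_interaction[label] = panel.to_dict()
                except InsufficientDataError as exc:
                    logger.warning("panel %s skipped: %s", label, exc)
                    go_vs_interaction[label] = {"label": label, "error": str(exc)}
            panels["go_vs_interaction"] = go_vs_interaction
            panels["go_vs_coexpression"] = _panel_block(
                matched, "mutual_rank", ["go_sim"], n_groups, alpha, method
            )

    ttests: Dict[str, dict] = {}
    with _stage("ttests"):
        for col in measure_cols:
            m, ct = col.split("_", 1)
            try:
                ttests[col] = coexpressed_vs_all_ttest(
                    matched, m, ct, float(thresholds["coexpressed_mr"])
                ).to_dict()
            except InsufficientDataError as exc:
                logger.warning("t-test %s skipped: %s", col, exc)
                ttests[col] = {"error": str(exc)}

    counts = {
        "genes_retained": int(matched.meta["n_genes_retained"]),
        "pairs_built": int(len(table)),
        "pairs_rank_matched": int(len(matched)),
        "strata": {name: int(len(s)) for name, s in strata.items()},
    }
    meta = {
        "thresholds": {k: float(v) if k != "n_groups" else int(v)
                       for k, v in thresholds.items()},
        "cell_types": cell_types,
        "measures": measures,
        "rank_measure": rank_measure,
        "correlation_method": method,
        "resolution": matched.meta["resolution"],
        "go_computed": bool(go_available),
        "ttest": "welch_unequal_variance_vs_complement",
        "seed": seed,
    }
    results = AnalysisResults(meta=meta, counts=counts, panels=panels, ttests=ttests)

    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        core_io.write_results(results, os.path.join(out_dir, "results.json"))
        core_io.write_pair_table(matched, os.path.join(out_dir, "pair_table.tsv"))
        groups_dir = os.path.join(out_dir, "panels")
        os.makedirs(groups_dir, exist_ok=True)
        for stratum_name, block in panels.items():
            for label, payload in block.items():
                if "groups" not in payload:
                    continue
                frame = pd.DataFrame(payload["groups"])
                fname = f"{stratum_name}__{label.replace('~', '_vs_')}.tsv"
                frame.to_csv(os.path.join(groups_dir, fname), sep="\t", index=False)
        with open(os.path.join(out_dir, "chromex.log"), "w") as fh:
            fh.write(f"genes_retained\t{counts['genes_retained']}\n")
            fh.write(f"pairs_built\t{counts['pairs_built']}\n")
            fh.write(f"pairs_rank_matched\t{counts['pairs_rank_matched']}\n")
            for name, cnt in counts["strata"].items():
                fh.write(f"stratum_{name}\t{cnt}\n")
        if make_plots:
            _plot_panels(panels, groups_dir)
    return results


def _plot_panels(panels: Dict[str, Dict[str, dict]], out_dir: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for stratum_name, block in panels.items():
        for label, payload in block.items():
            if "groups" not in payload:
                continue
            g = payload["groups"]
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.errorbar(g["mean_x"], g["mean_y"], yerr=g["sem_y"], fmt="o", ms=3)
            ax.set_title(f"{stratum_name}: {label} (r={payload['r']:.3f})", fontsize=8)
            fig.tight_layout()
            fname = f"{stratum_name}__{label.replace('~', '_vs_')}.png"
            fig.savefig(f"{out_dir}/{fname}", dpi=100)
            plt.close(fig)
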