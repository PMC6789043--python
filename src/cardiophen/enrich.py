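"""Differential-expression sets, pathway enrichment and scRNA-seq QC.

The maturation "net benefit" score asks whether a treatment shifts genes in
curated cardiac-maturation pathways up or down.  For each condition vs the
empty-vector control, up- (> 1.5-fold) and downregulated (< 1/1.5-fold) gene
sets are formed on mean normalized expression; each set is tested for
enrichment against each pathway with an upper-tail hypergeometric test; and
the score is -log10(p_up / p_down), so positive values mean maturation
pathways are preferentially upregulated.  Across m pathways and n conditions
this yields an m-by-n score matrix.

The single-cell utilities implement the QC filter (remove cells with > 40%
mitochondrial reads, < 200 detected genes or < 2000 UMIs; equality passes)
and per-gene z-score summaries by cluster for marker heat maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse
from scipy.stats import hypergeom

__all__ = [
    "FOLD_THRESHOLD",
    "QC_MAX_MITO_FRACTION",
    "QC_MIN_GENES",
    "QC_MIN_UMIS",
    "EnrichmentResult",
    "de_sets",
    "hypergeom_enrichment",
    "net_benefit_matrix",
    "qc_filter_cells",
    "cluster_zscores",
]

#: Fold-change threshold for the DE gene sets (strict inequality).
FOLD_THRESHOLD = 1.5
#: Expression floor: genes whose total across the compared samples is at or
#: below this are excluded.
EXPRESSION_FLOOR = 1.0

QC_MAX_MITO_FRACTION = 0.40
QC_MIN_GENES = 200
QC_MIN_UMIS = 2000


def _condition_samples(
    conditions: pd.Series, expr: pd.DataFrame, name: str
) -> list[str]:
    samples = [s for s in expr.columns if conditions.get(s) == name]
    if not samples:
        raise ValueError(f"condition {name!r} has no samples in the table")
    return samples


def de_sets(
    expr: pd.DataFrame,
    conditions: pd.Series | dict,
    condition: str,
    control: str = "EV",
    *,
    fold_threshold: float = FOLD_THRESHOLD,
    pseudocount: float = 1.0,
    expression_floor: float = EXPRESSION_FLOOR,
) -> tuple[set[str], set[str]]:
    """Up- and downregulated gene sets for one condition vs control.

    ``expr`` is genes x samples (normalized, non-negative); fold change is
    the ratio of condition to control mean expression with a pseudocount.
    Up = fold > threshold, down = fold < 1/threshold, both strict; genes whose
    total expression over the compared samples is not above the floor are
    excluded.
    """
    if (expr.values < 0).any():
        raise ValueError("expression table contains negative values")
    if not expr.index.is_unique:
        raise ValueError("gene ids must be unique")
    conditions = pd.Series(conditions)
    cond_samples = _condition_samples(conditions, expr, condition)
    ctrl_samples = _condition_samples(conditions, expr, control)

    sub = expr[cond_samples + ctrl_samples]
    kept = sub.index[sub.sum(axis=1) > expression_floor]
    fold = (expr.loc[kept, cond_samples].mean(axis=1) + pseudocount) / (
        expr.loc[kept, ctrl_samples].mean(axis=1) + pseudocount
    )
    up = set(fold.index[fold > fold_threshold])
    down = set(fold.index[fold < 1.0 / fold_threshold])
    return up, down


def hypergeom_enrichment(
    hits: set[str], pathway: set[str], universe: set[str]
) -> float:
    """Upper-tail hypergeometric enrichment p-value, P(X >= overlap).

    Population = universe, successes = pathway, draws = hits.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not hits <= universe:
        raise ValueError("hit set must be a subset of the universe")
    if not pathway <= universe:
        raise ValueError("pathway must be a subset of the universe")
    overlap = len(hits & pathway)
    return float(hypergeom.sf(overlap - 1, len(universe), len(pathway), len(hits)))


@dataclass
class EnrichmentResult:
    """Net-benefit matrix with the underlying per-cell p-values.

    All three frames are pathways (rows) x conditions (columns);
    ``net_benefit = log10(p_down) - log10(p_up)``.
    """

    net_benefit: pd.DataFrame
    p_up: pd.DataFrame
    p_down: pd.DataFrame


def net_benefit_matrix(
    expr: pd.DataFrame,
    conditions: pd.Series | dict,
    pathways: dict[str, set[str]],
    *,
    control: str = "EV",
    condition_names: list[str] | None = None,
    universe: set[str] | None = None,
    **de_kwargs,
) -> EnrichmentResult:
    """The m-pathways by n-conditions net-benefit score matrix.

    The universe defaults to all genes passing the expression floor across
    the whole table.  The control column is included (its DE sets are empty,
    so its scores are 0 by construction).
    """
    conditions = pd.Series(conditions)
    if condition_names is None:
        condition_names = list(dict.fromkeys(conditions[expr.columns]))
    if universe is None:
        floor = de_kwargs.get("expression_floor", EXPRESSION_FLOOR)
        universe = set(expr.index[expr.sum(axis=1) > floor])
    for name, genes in pathways.items():
        if not genes <= universe:
            raise ValueError(f"pathway {name!r} is not a subset of the universe")

    p_up = pd.DataFrame(index=list(pathways), columns=condition_names, dtype=float)
    p_down = p_up.copy()
    for cond in condition_names:
        if cond == control:
            up: set[str] = set()
            down: set[str] = set()
        else:
            up, down = de_sets(expr, conditions, cond, control, **de_kwargs)
        up &= universe
        down &= universe
        for name, genes in pathways.items():
            p_up.loc[name, cond] = hypergeom_enrichment(up, genes, universe)
            p_down.loc[name, cond] = hypergeom_enrichment(down, genes, universe)
    net = np.log10(p_down) - np.log10(p_up)
    return EnrichmentResult(net_benefit=net, p_up=p_up, p_down=p_down)


def _per_cell_stats(adata: AnnData, mito_mask: np.ndarray):
    x = adata.X
    if sparse.issparse(x):
        umis = np.asarray(x.sum(axis=1)).ravel()
        genes = np.asarray((x > 0).sum(axis=1)).ravel()
        mito = np.asarray(x[:, mito_mask].sum(axis=1)).ravel()
    else:
        x = np.asarray(x)
        umis = x.sum(axis=1)
        genes = (x > 0).sum(axis=1)
        mito = x[:, mito_mask].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(umis > 0, mito / umis, 0.0)
    return umis, genes, frac


def qc_filter_cells(
    adata: AnnData,
    *,
    mito_prefixes: tuple[str, ...] = ("MT-", "mt-"),
    max_mito_fraction: float = QC_MAX_MITO_FRACTION,
    min_genes: int = QC_MIN_GENES,
    min_umis: int = QC_MIN_UMIS,
) -> tuple[AnnData, dict[str, int]]:
    """Remove low-quality cells from a cells x genes UMI count matrix.

    A cell is kept iff mito fraction <= ``max_mito_fraction`` AND detected
    genes >= ``min_genes`` AND total UMIs >= ``min_umis`` ("more than" /
    "less than" thresholds are strict, so equality passes).  Mitochondrial
    genes are taken from a boolean ``adata.var["mito"]`` column when present,
    else by gene-name prefix.

    Returns the filtered view (copied) and removal counts keyed by reason
    (``mito``, ``genes``, ``umis`` — a cell can count toward several — plus
    ``total`` removed).  Per-cell stats and pass flags are written to
    ``adata.obs``.
    """
    if "mito" in adata.var:
        mito_mask = np.asarray(adata.var["mito"], dtype=bool)
    else:
        mito_mask = np.array(
            [str(g).startswith(mito_prefixes) for g in adata.var_names]
        )
    if not mito_mask.any():
        raise ValueError(
            "no mitochondrial gene annotation: provide var['mito'] or use "
            "gene names with an MT- prefix"
        )
    umis, genes, frac = _per_cell_stats(adata, mito_mask)
    fail_mito = frac > max_mito_fraction
    fail_genes = genes < min_genes
    fail_umis = umis < min_umis
    keep = ~(fail_mito | fail_genes | fail_umis)

    adata.obs["total_umis"] = umis
    adata.obs["n_genes"] = genes
    adata.obs["mito_fraction"] = frac
    adata.obs["qc_pass"] = keep
    counts = {
        "mito": int(fail_mito.sum()),
        "genes": int(fail_genes.sum()),
        "umis": int(fail_umis.sum()),
        "total": int((~keep).sum()),
    }
    return adata[keep].copy(), counts


def cluster_zscores(
    expr: pd.DataFrame,
    clusters: pd.Series | dict,
    markers: list[str],
) -> tuple[pd.DataFrame, list[str]]:
    """Marker x cluster matrix of cluster-averaged per-gene z-scores.

    ``expr`` is cells x genes.  Each marker is z-scored across all cells,
    then averaged within cluster.  Zero-variance markers cannot be z-scored:
    their rows are set to 0 and returned in the flagged list rather than
    propagating NaN.
    """
    clusters = pd.Series(clusters).loc[expr.index]
    missing = [m for m in markers if m not in expr.columns]
    if missing:
        raise ValueError(f"markers not in expression table: {missing}")
    cluster_names = list(dict.fromkeys(clusters))
    out = pd.DataFrame(0.0, index=markers, columns=cluster_names)
    flagged: list[str] = []
    for m in markers:
        x = expr[m].astype(float)
        sd = x.std(ddof=0)
        if sd == 0:
            flagged.append(m)
            continue
        z = (x - x.mean()) / sd
        out.loc[m] = z.groupby(clusters).mean().reindex(cluster_names)
    return out, flagged
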