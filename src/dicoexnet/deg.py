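"""Per-study differential expression and cross-study meta-analysis.

Each cohort is tested independently (Welch two-sample t per gene, BH-FDR
across genes, fold-change filter); the meta-analysis step is the
intersection of the per-study DEG lists, which trades sensitivity for
robustness to cohort-specific artefacts.  Over-representation of the common
DEGs in pathway collections is assessed with the one-sided hypergeometric
(Fisher) test.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionStudy, GeneSetCollection

logger = logging.getLogger(__name__)

DEG_COLUMNS = ["gene", "log2fc", "p_value", "adj_p", "direction"]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Order-preserving with the input; values capped at 1.  Raises if any
    input lies outside [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    study: ExpressionStudy,
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
    equal_var: bool = False,
    all_genes: bool = False,
) -> pd.DataFrame:
    """Welch t-test disease vs control per gene, BH-FDR, fold-change filter.

    Parameters
    ----------
    study : ExpressionStudy
        Cohort with log2-scale values (so the difference of group means is
        the log2 fold change).
    alpha : float
        BH-adjusted significance cut-off (default 0.05).
    fc_threshold : float
        Linear fold-change cut-off, applied as |log2fc| ≥ log2(fc_threshold)
        (default 2, i.e. |log2fc| ≥ 1).
    equal_var : bool
        Pooled-variance Student t instead of Welch (off by default).
    all_genes : bool
        Return the full per-gene table instead of only significant DEGs.

    Returns
    -------
    pandas.DataFrame
        Columns ``gene, log2fc, p_value, adj_p, direction``; when
        ``all_genes`` is false only records with ``adj_p < alpha`` and
        ``|log2fc| ≥ log2(fc_threshold)`` (and a non-zero log2fc) remain.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if fc_threshold < 1:
        raise ValueError("fc_threshold is a linear fold change and must be ≥ 1")
    disease = study.condition_values("disease").to_numpy(dtype=float)
    control = study.condition_values("control").to_numpy(dtype=float)
    if disease.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError(
            "each phenotype needs at least 2 samples for a variance estimate"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(disease, control, axis=1, equal_var=equal_var)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance ties: no evidence
    log2fc = disease.mean(axis=1) - control.mean(axis=1)
    table = pd.DataFrame(
        {
            "gene": study.genes,
            "log2fc": log2fc,
            "p_value": p,
            "adj_p": bh_adjust(p),
            "direction": np.where(log2fc > 0, "up", "down"),
        }
    )
    if all_genes:
        return table
    keep = (
        (table["adj_p"] < alpha)
        & (table["log2fc"].abs() >= np.log2(fc_threshold))
        & (table["log2fc"] != 0)
    )
    return table.loc[keep].reset_index(drop=True)


def intersect_common_degs(deg_tables: Sequence[pd.DataFrame]) -> set[str]:
    """Genes present (by symbol) in every per-study DEG table.

    Direction consistency across studies is reported via logging but not
    enforced.  Requires at least two tables.
    """
    if len(deg_tables) < 2:
        raise ValueError("need at least two DEG tables to intersect")
    common = set(deg_tables[0]["gene"])
    for table in deg_tables[1:]:
        common &= set(table["gene"])
    inconsistent = []
    for gene in common:
        directions = {
            table.loc[table["gene"] == gene, "direction"].iloc[0]
            for table in deg_tables
        }
        if len(directions) > 1:
            inconsistent.append(gene)
    if inconsistent:
        logger.warning(
            "%d of %d common DEGs have inconsistent direction across studies: %s",
            len(inconsistent),
            len(common),
            ", ".join(sorted(inconsistent)[:10]),
        )
    return common


def consensus_directions(
    deg_tables: Sequence[pd.DataFrame], genes: Iterable[str]
) -> pd.Series:
    """Majority up/down call per gene across studies (ties → 'up')."""
    genes = list(genes)
    votes = pd.DataFrame(index=genes)
    for i, table in enumerate(deg_tables):
        sub = table.set_index("gene")["direction"]
        votes[i] = sub.reindex(genes)
    n_up = (votes == "up").sum(axis=1)
    n_down = (votes == "down").sum(axis=1)
    return pd.Series(
        np.where(n_up >= n_down, "up", "down"), index=genes, name="direction"
    )


def ora_fisher(
    query: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of a query gene set in each collection set.

    One-sided hypergeometric tail P(X ≥ overlap) with the collection set
    first intersected with the universe; BH adjustment across sets; rows
    sorted by adjusted p.  The query must be contained in the universe.
    """
    query = set(query)
    universe = set(universe)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for name, genes in collection.sets.items():
        in_universe = set(genes) & universe
        K = len(in_universe)
        k = len(query & in_universe)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, k, K, N, n, min(p, 1.0)))
    result = pd.DataFrame(
        rows,
        columns=["set_name", "overlap", "set_size", "universe_size",
                 "query_size", "p_value"],
    )
    result["adj_p"] = bh_adjust(result["p_value"]) if len(result) else []
    result["significant"] = result["adj_p"] < alpha
    return result.sort_values(
        ["adj_p", "p_value", "set_name"], kind="mergesort"
    ).reset_index(drop=True)


def write_deg_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_deg_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(DEG_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"DEG table {path} lacks columns: {sorted(missing)}")
    return table
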