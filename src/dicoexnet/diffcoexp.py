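"""Differential co-expression networks from condition-wise Spearman correlation.

The analysis asks not whether a gene's *mean* expression changes between
phenotypes, but whether the *correlation structure* among genes changes.
For every unordered pair of common DEGs, a Spearman correlation coefficient
is computed separately in the pooled disease samples (SCCd) and the pooled
control samples (SCCh).  Two thresholds define the differential network:

* **p-critic** — an adaptive significance cut-off for correlations in one
  condition,

      pcritic = mean(SCC) + 1.96 · std(SCC)

  computed over all off-diagonal pair values of that condition (sample
  standard deviation).  A pair is significantly linked in a condition when
  |SCC| exceeds that condition's p-critic.

* **ε (epsilon)** — the differential-correlation statistic
  ε = |SCCd − SCCh|, thresholded at 0.5 by default.  Large ε means a pair
  is strongly rewired between phenotypes: co-expressed in disease but not
  in health, or flipping correlation sign.

A pair enters the network when it is significantly linked in disease
(|SCCd| > pcritic_d) *and* ε exceeds its threshold.  Densely connected
communities of the resulting graph are the differential co-expression
modules; a module's density is 2E/(N(N−1)).

The :class:`DifferentialCoexpressionModel` /
:class:`DifferentialCoexpressionResults` pair wraps the whole stage in a
fit-style API over a list of cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    ExpressionStudy,
    collapse_duplicate_genes,
    write_graphml,
    write_sif,
    zscore_normalize,
)

logger = logging.getLogger(__name__)

#: multiplier on the SCC standard deviation in the p-critic cut-off
PCRITIC_MULTIPLIER = 1.96

PAIR_COLUMNS = [
    "gene_a", "gene_b", "scc_d", "scc_h", "epsilon",
    "significant_d", "significant_h",
]


@dataclass
class ConditionCorrelation:
    """Symmetric Spearman correlation matrix of one condition."""

    genes: list[str]
    scc: np.ndarray
    condition: str
    n_samples: int

    def __post_init__(self) -> None:
        self.scc = np.asarray(self.scc, dtype=float)
        if self.scc.shape != (len(self.genes), len(self.genes)):
            raise ValueError("correlation matrix shape does not match gene list")

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle pair values (each unordered pair once)."""
        iu = np.triu_indices(len(self.genes), k=1)
        return self.scc[iu]

    def lookup(self, gene_a: str, gene_b: str) -> float:
        i, j = self.genes.index(gene_a), self.genes.index(gene_b)
        return float(self.scc[i, j])


@dataclass
class PCritic:
    """Adaptive correlation-significance cut-off of one condition."""

    condition: str
    mean_scc: float
    std_scc: float

    @property
    def value(self) -> float:
        return self.mean_scc + PCRITIC_MULTIPLIER * self.std_scc


@dataclass
class CoexpressionModule:
    """A dense community of the differential co-expression network."""

    module_id: str
    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    density: float
    pattern_counts: dict | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def pairwise_scc(values: pd.DataFrame, condition: str) -> ConditionCorrelation:
    """Spearman correlation for every unordered gene pair of one condition.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes × pooled samples of a single condition (z-scored per study
        before pooling).  Needs ≥ 3 samples.  Ties receive average ranks.
    condition : str
        ``"disease"`` or ``"control"``; carried through for bookkeeping.
    """
    if values.shape[1] < 3:
        raise ValueError(
            f"need at least 3 pooled samples for correlation, got {values.shape[1]}"
        )
    if values.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    arr = values.to_numpy(dtype=float)
    rho = stats.spearmanr(arr.T).statistic
    if np.isscalar(rho):  # spearmanr collapses the 2-gene case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    rho = np.asarray(rho, dtype=float)
    np.fill_diagonal(rho, 1.0)
    return ConditionCorrelation(
        genes=list(values.index), scc=rho, condition=condition,
        n_samples=values.shape[1],
    )


def compute_pcritic(
    corr: ConditionCorrelation, absolute: bool = False
) -> PCritic:
    """p-critic = mean + 1.96·std over the condition's pair correlations.

    Signed off-diagonal SCC values by default; ``absolute=True`` switches
    the input distribution to |SCC|.  Sample (n−1) standard deviation.
    """
    vals = corr.off_diagonal()
    if vals.size < 2:
        raise ValueError("p-critic needs at least 2 gene-pair correlations")
    if absolute:
        vals = np.abs(vals)
    return PCritic(
        condition=corr.condition,
        mean_scc=float(np.mean(vals)),
        std_scc=float(np.std(vals, ddof=1)),
    )


def select_differential_pairs(
    corr_d: ConditionCorrelation,
    corr_h: ConditionCorrelation,
    pcritic_d: PCritic,
    epsilon_threshold: float = 0.5,
    pcritic_h: PCritic | None = None,
) -> pd.DataFrame:
    """Retain pairs significantly linked in disease and rewired between states.

    A pair (a, b) is retained when |SCCd| > pcritic_d and
    ε = |SCCd − SCCh| > epsilon_threshold.  Pairs are canonicalized with
    gene_a < gene_b; significance flags are populated for both conditions
    (pcritic_h computed from the control correlations when not supplied).
    """
    if set(corr_d.genes) != set(corr_h.genes):
        raise ValueError("disease and control correlations have different genes")
    if pcritic_h is None:
        pcritic_h = compute_pcritic(corr_h)
    # align control matrix to the disease gene order
    order = [corr_h.genes.index(g) for g in corr_d.genes]
    scc_h = corr_h.scc[np.ix_(order, order)]
    genes = corr_d.genes
    iu = np.triu_indices(len(genes), k=1)
    d_vals = corr_d.scc[iu]
    h_vals = scc_h[iu]
    eps = np.abs(d_vals - h_vals)
    keep = (np.abs(d_vals) > pcritic_d.value) & (eps > epsilon_threshold)
    rows = []
    for idx in np.flatnonzero(keep):
        i, j = iu[0][idx], iu[1][idx]
        a, b = sorted((genes[i], genes[j]))
        rows.append(
            (
                a, b, float(d_vals[idx]), float(h_vals[idx]), float(eps[idx]),
                bool(abs(d_vals[idx]) > pcritic_d.value),
                bool(abs(h_vals[idx]) > pcritic_h.value),
            )
        )
    rows.sort(key=lambda r: (r[0], r[1]))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def build_network(pairs: pd.DataFrame) -> nx.Graph:
    """Simple undirected graph from retained pairs.

    Edge attributes carry scc_d, scc_h and epsilon; self-loops are ignored
    and duplicate pairs collapse onto one edge.
    """
    graph = nx.Graph()
    for row in pairs.itertuples(index=False):
        if row.gene_a == row.gene_b:
            continue
        graph.add_edge(
            row.gene_a, row.gene_b,
            scc_d=float(row.scc_d), scc_h=float(row.scc_h),
            epsilon=float(row.epsilon),
        )
    return graph


def network_density(nodes: int, edges: int) -> float:
    """Density 2E/(N(N−1)) of a simple undirected graph."""
    if nodes < 2:
        raise ValueError("density needs at least 2 nodes")
    max_edges = nodes * (nodes - 1) // 2
    if not 0 <= edges <= max_edges:
        raise ValueError(f"edge count {edges} outside [0, {max_edges}]")
    return 2.0 * edges / (nodes * (nodes - 1))


def detect_modules(
    graph: nx.Graph, min_size: int = 5, density_threshold: float = 0.5
) -> list[CoexpressionModule]:
    """Dense communities of the differential network.

    A connected component that already satisfies the size and density
    criteria is a module as it stands; partitioning a dense near-clique
    would only split it on the noise pattern of its few missing edges.
    Components that are too sparse overall are partitioned by
    deterministic greedy modularity maximization and each community is a
    candidate, filtered by the same size/density criteria.  Modules are
    ordered by decreasing size then density, ids ``M1, M2, ...``.
    """
    if min_size < 3:
        raise ValueError("min_size must be ≥ 3")
    if not 0 < density_threshold <= 1:
        raise ValueError("density_threshold must lie in (0, 1]")
    candidates = []
    for component in nx.connected_components(graph):
        sub = graph.subgraph(sorted(component))
        if sub.number_of_edges() == 0:
            continue
        if (
            sub.number_of_nodes() >= min_size
            and nx.density(sub) >= density_threshold
        ):
            communities = [set(sub.nodes)]
        elif sub.number_of_nodes() < 3:
            continue
        else:
            communities = nx.community.greedy_modularity_communities(sub)
        for community in communities:
            nodes = tuple(sorted(community))
            if len(nodes) < min_size:
                continue
            edges = frozenset(
                tuple(sorted(e)) for e in graph.subgraph(nodes).edges()
            )
            density = network_density(len(nodes), len(edges))
            if density >= density_threshold:
                candidates.append((nodes, edges, density))
    candidates.sort(key=lambda c: (-len(c[0]), -c[2], c[0]))
    return [
        CoexpressionModule(
            module_id=f"M{i + 1}", nodes=nodes, edges=edges, density=density
        )
        for i, (nodes, edges, density) in enumerate(candidates)
    ]


def correlation_pattern_summary(
    module: CoexpressionModule,
    corr_d: ConditionCorrelation,
    corr_h: ConditionCorrelation,
    pcritic_d: PCritic,
    pcritic_h: PCritic,
) -> dict:
    """Counts of significantly positive/negative module gene pairs per condition.

    A pair is positive in a condition when SCC > pcritic, negative when
    SCC < −pcritic.  Percentages are reported against two denominators —
    the per-condition significant-pair count and the total pair count —
    because the appropriate reference depends on the question asked.
    """
    missing = set(module.nodes) - set(corr_d.genes)
    if missing:
        raise ValueError(f"module genes absent from correlation: {sorted(missing)}")
    total_pairs = len(module.nodes) * (len(module.nodes) - 1) // 2
    out: dict = {"total_pairs": total_pairs, "conditions": {}}
    for corr, pc in ((corr_d, pcritic_d), (corr_h, pcritic_h)):
        pos = neg = 0
        for a, b in combinations(module.nodes, 2):
            scc = corr.lookup(a, b)
            if scc > pc.value:
                pos += 1
            elif scc < -pc.value:
                neg += 1
        n_sig = pos + neg
        out["conditions"][corr.condition] = {
            "positive": pos,
            "negative": neg,
            "n_significant": n_sig,
            "pct_positive_of_significant": 100.0 * pos / n_sig if n_sig else None,
            "pct_negative_of_significant": 100.0 * neg / n_sig if n_sig else None,
            "pct_positive_of_total": 100.0 * pos / total_pairs if total_pairs else None,
            "pct_negative_of_total": 100.0 * neg / total_pairs if total_pairs else None,
        }
    return out


def pool_condition(
    studies: list[ExpressionStudy], genes: list[str], condition: str
) -> pd.DataFrame:
    """Concatenate one condition's samples across z-scored studies."""
    blocks = []
    for study in studies:
        sub = study.condition_values(condition)
        missing = [g for g in genes if g not in sub.index]
        if missing:
            raise ValueError(
                f"study {study.study_id!r} lacks genes: {missing[:5]}"
            )
        blocks.append(sub.loc[genes])
    return pd.concat(blocks, axis=1)


class DifferentialCoexpressionModel:
    """Differential co-expression analysis over multiple cohorts.

    Parameters
    ----------
    studies : list of ExpressionStudy
        Cohorts on the log2 scale.  Each is duplicate-collapsed and
        z-scored per gene within the study, then samples are pooled per
        condition across studies.
    genes : list of str, optional
        Gene universe for the correlation analysis (typically the common
        DEGs).  Defaults to the genes shared by all studies.
    epsilon : float
        Differential-correlation threshold on |SCCd − SCCh| (default 0.5).
    min_module_size, density_threshold : int, float
        Module acceptance criteria (defaults 5 and 0.5).
    absolute_pcritic_input : bool
        Feed |SCC| instead of signed SCC into the p-critic statistic.
    """

    def __init__(
        self,
        studies: list[ExpressionStudy],
        genes: list[str] | None = None,
        *,
        epsilon: float = 0.5,
        min_module_size: int = 5,
        density_threshold: float = 0.5,
        absolute_pcritic_input: bool = False,
    ) -> None:
        if not studies:
            raise ValueError("need at least one study")
        self.studies = [
            zscore_normalize(collapse_duplicate_genes(s)) for s in studies
        ]
        if genes is None:
            shared = set(self.studies[0].genes)
            for s in self.studies[1:]:
                shared &= set(s.genes)
            genes = sorted(shared)
        else:
            genes = [str(g).strip() for g in genes]
        if len(genes) < 2:
            raise ValueError("need at least 2 genes common to all studies")
        self.genes = genes
        self.epsilon = epsilon
        self.min_module_size = min_module_size
        self.density_threshold = density_threshold
        self.absolute_pcritic_input = absolute_pcritic_input

    @classmethod
    def from_files(
        cls, matrix_paths, labels_paths, genes=None, **kwargs
    ) -> "DifferentialCoexpressionModel":
        from .io import read_expression_matrix

        studies = [
            read_expression_matrix(m, l)
            for m, l in zip(matrix_paths, labels_paths, strict=True)
        ]
        return cls(studies, genes=genes, **kwargs)

    def fit(self) -> "DifferentialCoexpressionResults":
        pooled_d = pool_condition(self.studies, self.genes, "disease")
        pooled_h = pool_condition(self.studies, self.genes, "control")
        corr_d = pairwise_scc(pooled_d, "disease")
        corr_h = pairwise_scc(pooled_h, "control")
        pcritic_d = compute_pcritic(corr_d, absolute=self.absolute_pcritic_input)
        pcritic_h = compute_pcritic(corr_h, absolute=self.absolute_pcritic_input)
        pairs = select_differential_pairs(
            corr_d, corr_h, pcritic_d, self.epsilon, pcritic_h
        )
        network = build_network(pairs)
        modules = detect_modules(
            network, self.min_module_size, self.density_threshold
        )
        modules = [
            CoexpressionModule(
                m.module_id, m.nodes, m.edges, m.density,
                pattern_counts=correlation_pattern_summary(
                    m, corr_d, corr_h, pcritic_d, pcritic_h
                ),
            )
            for m in modules
        ]
        logger.info(
            "differential co-expression: %d genes, %d pairs retained, "
            "%d module(s)", len(self.genes), len(pairs), len(modules),
        )
        return DifferentialCoexpressionResults(
            model=self, corr_d=corr_d, corr_h=corr_h,
            pcritic_d=pcritic_d, pcritic_h=pcritic_h,
            pairs=pairs, network=network, modules=modules,
        )


@dataclass
class DifferentialCoexpressionResults:
    """Fitted differential co-expression network and its modules."""

    model: DifferentialCoexpressionModel
    corr_d: ConditionCorrelation
    corr_h: ConditionCorrelation
    pcritic_d: PCritic
    pcritic_h: PCritic
    pairs: pd.DataFrame
    network: nx.Graph
    modules: list[CoexpressionModule] = field(default_factory=list)

    def modules_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (m.module_id, m.n_nodes, m.n_edges, m.density)
                for m in self.modules
            ],
            columns=["module_id", "n_nodes", "n_edges", "density"],
        )

    def to_graphml(self, path) -> None:
        write_graphml(self.network, path)

    def to_sif(self, path) -> None:
        write_sif(self.network, path)

    def modules_to_gmt(self, path) -> None:
        from .io import write_gene_sets

        write_gene_sets(
            {m.module_id: list(m.nodes) for m in self.modules}, path,
            description="differential co-expression module",
        )

    def summary(self) -> str:
        lines = [
            "Differential co-expression analysis",
            "===================================",
            f"studies: {len(self.model.studies)}   "
            f"genes: {len(self.model.genes)}   "
            f"pooled samples: {self.corr_d.n_samples} disease / "
            f"{self.corr_h.n_samples} control",
            f"p-critic (disease): {self.pcritic_d.value:.4f}  "
            f"[mean {self.pcritic_d.mean_scc:.4f}, sd {self.pcritic_d.std_scc:.4f}]",
            f"p-critic (control): {self.pcritic_h.value:.4f}  "
            f"[mean {self.pcritic_h.mean_scc:.4f}, sd {self.pcritic_h.std_scc:.4f}]",
            f"epsilon threshold: {self.model.epsilon}   "
            f"retained pairs: {len(self.pairs)}   "
            f"network: {self.network.number_of_nodes()} nodes / "
            f"{self.network.number_of_edges()} edges",
            "",
            f"{'module':<8}{'nodes':>6}{'edges':>7}{'density':>9}  "
            f"{'pos/neg (disease)':>18}  {'pos/neg (control)':>18}",
        ]
        for m in self.modules:
            pat = m.pattern_counts or {"conditions": {}}
            d = pat["conditions"].get("disease", {})
            h = pat["conditions"].get("control", {})
            lines.append(
                f"{m.module_id:<8}{m.n_nodes:>6}{m.n_edges:>7}{m.density:>9.3f}  "
                f"{d.get('positive', '-')!s:>8}/{d.get('negative', '-')!s:<9}  "
                f"{h.get('positive', '-')!s:>8}/{h.get('negative', '-')!s:<9}"
            )
        if not self.modules:
            lines.append("(no module met the size/density criteria)")
        return "\n".join(lines)
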