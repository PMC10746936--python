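"""Reading, writing and preprocessing of expression studies and gene sets.

An :class:`ExpressionStudy` is one cohort: a genes × samples matrix of
log2-scale expression values plus a binary phenotype label per sample
(``disease`` / ``control``).  Preprocessing follows the usual meta-analysis
route: duplicate gene symbols are collapsed to their mean profile, then each
gene is z-scored within the study so that cohorts can be pooled without
batch effects dominating the correlation structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PHENOTYPES = ("disease", "control")

#: minimum samples per phenotype for a cohort to enter the analysis
MIN_SAMPLES_PER_PHENOTYPE = 3


@dataclass
class ExpressionStudy:
    """One cohort's expression matrix with phenotype labels.

    Parameters
    ----------
    study_id : str
        Cohort identifier.
    values : pandas.DataFrame
        Genes × samples matrix, gene symbols as index, sample ids as
        columns.  Values are assumed to be on the log2 scale.
    labels : pandas.Series
        Phenotype per sample id; values must be ``"disease"`` or
        ``"control"``.  Reordered to match the matrix columns.
    """

    study_id: str
    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.copy()
        self.values.index = self.values.index.astype(str).str.strip()
        self.values.index.name = "gene"
        missing = [s for s in self.values.columns if s not in self.labels.index]
        if missing:
            raise ValueError(
                f"study {self.study_id!r}: samples without phenotype labels: {missing}"
            )
        self.labels = self.labels.reindex(self.values.columns)
        bad = sorted(set(self.labels.unique()) - set(PHENOTYPES))
        if bad:
            raise ValueError(
                f"study {self.study_id!r}: unknown phenotype labels {bad}; "
                f"expected one of {PHENOTYPES}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def phenotype_samples(self, phenotype: str) -> list[str]:
        if phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {phenotype!r}")
        return list(self.labels.index[self.labels == phenotype])

    def condition_values(self, phenotype: str) -> pd.DataFrame:
        """Sub-matrix restricted to samples of one phenotype."""
        return self.values[self.phenotype_samples(phenotype)]

    def validate(self) -> "ExpressionStudy":
        """Enforce the cohort-selection contract.

        Raises if the matrix contains missing values or either phenotype
        has fewer than three samples (cohorts smaller than that carry no
        usable within-condition correlation signal and are excluded from
        the analysis by design).
        """
        if self.values.isna().any().any():
            raise ValueError(f"study {self.study_id!r}: missing values in matrix")
        for phen in PHENOTYPES:
            n = len(self.phenotype_samples(phen))
            if n < MIN_SAMPLES_PER_PHENOTYPE:
                raise ValueError(
                    f"study {self.study_id!r}: phenotype {phen!r} has {n} samples; "
                    f"each phenotype must contain at least "
                    f"{MIN_SAMPLES_PER_PHENOTYPE} samples"
                )
        return self


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways) read from a GMT file."""

    sets: dict[str, list[str]]
    source: str = ""
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            cleaned = [str(g).strip() for g in genes if str(g).strip()]
            if not cleaned:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


def read_expression_matrix(
    path: str | Path,
    labels_path: str | Path,
    study_id: str | None = None,
    validate: bool = True,
) -> ExpressionStudy:
    """Read a TSV expression matrix and its phenotype labels.

    The matrix has gene symbols in the first column and sample ids in the
    header; the labels file is two-column TSV (sample_id, phenotype).  Every
    sample in the matrix must have a label; unless ``validate`` is false
    (e.g. a tumour-only validation cohort), the study must satisfy
    :meth:`ExpressionStudy.validate`.
    """
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.columns = values.columns.astype(str)
    labels = read_labels(labels_path)
    study = ExpressionStudy(
        study_id=study_id or path.stem, values=values, labels=labels
    )
    return study.validate() if validate else study


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column (sample_id, phenotype) TSV, with or without header."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"labels file {path} must have two tab-separated columns")
    # tolerate a header line
    if str(df.iloc[0, 1]).strip().lower() not in PHENOTYPES:
        df = df.iloc[1:]
    labels = pd.Series(
        df.iloc[:, 1].str.strip().str.lower().values,
        index=df.iloc[:, 0].str.strip().values,
        name="phenotype",
    )
    return labels


def write_expression_matrix(
    study: ExpressionStudy, path: str | Path, labels_path: str | Path | None = None
) -> None:
    """Write the matrix (and optionally labels) back to TSV at full precision."""
    out = study.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format=None)
    if labels_path is not None:
        study.labels.rename_axis("sample_id").to_csv(
            labels_path, sep="\t", header=False
        )


def collapse_duplicate_genes(study: ExpressionStudy) -> ExpressionStudy:
    """Replace rows sharing a gene symbol by their element-wise mean.

    Idempotent; row order follows first occurrence of each symbol.
    """
    if study.values.index.is_unique:
        return ExpressionStudy(study.study_id, study.values, study.labels)
    collapsed = study.values.groupby(level=0, sort=False).mean()
    n_dropped = study.n_genes - collapsed.shape[0]
    logger.info(
        "study %s: collapsed %d duplicate gene rows", study.study_id, n_dropped
    )
    return ExpressionStudy(study.study_id, collapsed, study.labels)


def zscore_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Z-score each gene row across all samples of the study.

    Uses the sample (n−1) standard deviation.  Rows with zero variance
    cannot be standardized and are dropped with a logged warning.
    """
    values = study.values
    mean = values.mean(axis=1)
    std = values.std(axis=1, ddof=1)
    constant = (std == 0) | std.isna()
    if constant.any():
        dropped = list(values.index[constant])
        logger.warning(
            "study %s: dropping %d constant gene row(s): %s",
            study.study_id,
            len(dropped),
            ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
        values = values.loc[~constant]
        mean = mean.loc[~constant]
        std = std.loc[~constant]
    z = values.sub(mean, axis=0).div(std, axis=0)
    return ExpressionStudy(study.study_id, z, study.labels)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (set name, description, tab-separated gene symbols)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line in {path}: {line!r}")
            name, desc, *genes = fields
            sets[name] = [g for g in genes if g.strip()]
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, source=str(path), descriptions=descriptions)


def write_gene_sets(
    sets: dict[str, list[str]], path: str | Path, description: str = "na"
) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, path)


def write_sif(graph: nx.Graph, path: str | Path, relation: str = "coexp") -> None:
    """Write a network in simple interaction format (node relation node)."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{relation}\t{b}\n")
        for node in sorted(nx.isolates(graph)):
            fh.write(f"{node}\n")
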