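"""Drug-signature reversal ranking and literature-novelty scoring.

The prognostic module is turned into an up/down gene signature (directions
and weights from the DEG meta-analysis).  Drugs from a signature library
(per-gene signed weights: positive = induced, negative = repressed) are
ranked by how strongly they *oppose* the disease signature: the score is
the negative cosine similarity between the signature weight vector and the
drug weight vector on their gene intersection, so a perfect reverser scores
+1.  Literature novelty of the top drugs is assessed by TF-IDF over an
abstract corpus under four query contexts (the drug name alone and the name
combined with "thyroid cancer", "thyroid carcinoma" or "cancer"); a drug
whose TF-IDF is zero in every context has no literature trace and is
flagged novel.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: the four query contexts; None means the whole corpus (name alone)
DEFAULT_QUERY_CONTEXTS: tuple[str | None, ...] = (
    None, "thyroid cancer", "thyroid carcinoma", "cancer",
)


@dataclass
class GeneSignature:
    """Disjoint up/down gene sets with optional per-gene weights (log2fc)."""

    up: set[str]
    down: set[str]
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.up = {str(g) for g in self.up}
        self.down = {str(g) for g in self.down}
        overlap = self.up & self.down
        if overlap:
            raise ValueError(f"genes in both up and down sets: {sorted(overlap)}")
        if not self.up and not self.down:
            raise ValueError("signature is empty")

    @property
    def genes(self) -> set[str]:
        return self.up | self.down

    def weight(self, gene: str) -> float:
        """Signed weight; falls back to ±1 when no weight is recorded."""
        if gene in self.weights:
            return float(self.weights[gene])
        return 1.0 if gene in self.up else -1.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "up": sorted(self.up), "down": sorted(self.down),
                    "weights": self.weights,
                },
                fh, indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "GeneSignature":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            up=set(payload["up"]), down=set(payload["down"]),
            weights=payload.get("weights", {}),
        )


def build_module_signature(
    module_genes, deg_table: pd.DataFrame
) -> GeneSignature:
    """Signature from a module's genes and their DEG directions/weights.

    Module genes without a DEG record are logged and dropped; an empty
    resulting signature raises.
    """
    indexed = deg_table.set_index("gene")
    up, down, weights = set(), set(), {}
    missing = []
    for gene in module_genes:
        if gene not in indexed.index:
            missing.append(gene)
            continue
        rec = indexed.loc[gene]
        if rec["direction"] == "up":
            up.add(gene)
        else:
            down.add(gene)
        weights[gene] = float(rec["log2fc"])
    if missing:
        logger.warning(
            "%d module gene(s) missing from the DEG table, dropped: %s",
            len(missing), ", ".join(missing[:10]),
        )
    if not up and not down:
        raise ValueError("no module gene has a DEG record; signature is empty")
    return GeneSignature(up=up, down=down, weights=weights)


def read_drug_library(path: str | Path) -> dict[str, dict[str, float]]:
    """Drug signature library from TSV (drug, gene, weight) or GMT pairs.

    In the GMT dialect, sets named ``<drug>_up`` / ``<drug>_down`` carry
    weight +1 / −1 per gene.
    """
    path = Path(path)
    library: dict[str, dict[str, float]] = {}
    if path.suffix.lower() == ".gmt":
        from .io import read_gene_sets

        for name, genes in read_gene_sets(path).sets.items():
            if name.endswith("_up"):
                drug, sign = name[:-3], 1.0
            elif name.endswith("_down"):
                drug, sign = name[:-5], -1.0
            else:
                raise ValueError(
                    f"GMT drug set {name!r} must end in '_up' or '_down'"
                )
            library.setdefault(drug, {}).update({g: sign for g in genes})
    else:
        table = pd.read_csv(path, sep="\t")
        required = {"drug", "gene", "weight"}
        if not required <= set(table.columns):
            raise ValueError(f"drug library needs columns {sorted(required)}")
        for row in table.itertuples(index=False):
            library.setdefault(str(row.drug), {})[str(row.gene)] = float(row.weight)
    validate_drug_library(library)
    return library


def validate_drug_library(library: dict[str, dict[str, float]]) -> None:
    for drug, weights in library.items():
        if not weights:
            raise ValueError(f"drug {drug!r} has no genes")
        if not all(math.isfinite(w) for w in weights.values()):
            raise ValueError(f"drug {drug!r} has non-finite weights")


def reversal_score(
    signature: GeneSignature,
    library: dict[str, dict[str, float]],
    top_k: int = 50,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Rank drugs by negative cosine similarity to the disease signature.

    Scores are computed on the gene intersection of signature and drug; a
    drug must share at least ``min_overlap`` genes with the signature to be
    scored (default 1; note that a one-gene overlap yields cosine ±1 by
    construction, so raising ``min_overlap`` is advisable with sparse
    libraries), and at least one drug must qualify.  Higher is better (a
    perfect reverser scores +1).  Returns the ``top_k`` rows (default 50),
    ties broken by drug name.
    """
    if top_k < 1:
        raise ValueError("top_k must be ≥ 1")
    if min_overlap < 1:
        raise ValueError("min_overlap must be ≥ 1")
    validate_drug_library(library)
    rows = []
    for drug, weights in library.items():
        shared = sorted(signature.genes & set(weights))
        if len(shared) < min_overlap:
            continue
        sig_vec = np.array([signature.weight(g) for g in shared])
        drug_vec = np.array([weights[g] for g in shared])
        denom = np.linalg.norm(sig_vec) * np.linalg.norm(drug_vec)
        cosine = float(sig_vec @ drug_vec / denom) if denom > 0 else 0.0
        rows.append((drug, len(shared), -cosine))
    if not rows:
        raise ValueError("no drug in the library overlaps the signature")
    result = pd.DataFrame(rows, columns=["drug", "n_overlap", "score"])
    result = result.sort_values(
        ["score", "drug"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    result["rank"] = np.arange(1, len(result) + 1)
    return result.head(top_k)


def _phrase_count(text: str, phrase: str) -> int:
    """Case-insensitive whole-phrase occurrence count."""
    pattern = r"(?<!\w)" + re.escape(phrase) + r"(?!\w)"
    return len(re.findall(pattern, text, flags=re.IGNORECASE))


def tfidf_novelty(
    drugs,
    corpus,
    query_contexts=DEFAULT_QUERY_CONTEXTS,
) -> pd.DataFrame:
    """TF-IDF of each drug name under each query context.

    For a context, the sub-corpus is the documents containing the context
    phrase (the bare-name query uses the whole corpus).  Within that
    sub-corpus, tf is the total occurrence count of the drug name across
    documents and idf = ln(N/df) with N the sub-corpus size and df the
    number of documents mentioning the name; df = 0 defines tfidf = 0.
    A drug is novel when tfidf is 0 under every context.

    ``corpus`` is a sequence of strings or of ``{"id": ..., "text": ...}``
    records.
    """
    texts = [
        doc["text"] if isinstance(doc, dict) else str(doc) for doc in corpus
    ]
    if not texts:
        raise ValueError("corpus is empty")
    drugs = [str(d).strip() for d in drugs]
    if any(not d for d in drugs):
        raise ValueError("drug names must be non-empty")
    rows = []
    novel: dict[str, bool] = {d: True for d in drugs}
    for context in query_contexts:
        if context is None:
            sub = texts
            label = "name"
        else:
            sub = [t for t in texts if _phrase_count(t, context) > 0]
            label = f"name + {context}"
        n_docs = len(sub)
        for drug in drugs:
            counts = [_phrase_count(t, drug) for t in sub]
            tf = float(sum(counts))
            df = sum(1 for c in counts if c > 0)
            idf = math.log(n_docs / df) if df > 0 else 0.0
            tfidf = tf * idf if df > 0 else 0.0
            if tfidf > 0:
                novel[drug] = False
            rows.append((drug, label, n_docs, tf, df, idf, tfidf))
    result = pd.DataFrame(
        rows, columns=["drug", "query", "n_docs", "tf", "df", "idf", "tfidf"]
    )
    result["novel"] = result["drug"].map(novel)
    return result


def read_corpus(path: str | Path) -> list[dict]:
    """JSON-lines corpus: one {id, text} record per abstract."""
    corpus = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                corpus.append(json.loads(line))
    return corpus


def write_corpus(corpus, path: str | Path) -> None:
    with open(path, "w") as fh:
        for doc in corpus:
            fh.write(json.dumps(doc) + "\n")
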