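"""Synthetic multi-cohort data with planted signal for every pipeline stage.

The generator emulates a multi-cohort two-phenotype transcriptome design:
several studies share a panel of planted DEGs (mean shifts on the log2
scale, half up- and half down-regulated) against a background of null
genes, and a subset of the DEGs forms a *module* driven by a shared latent
factor that is active in disease samples and (by default) silent in
controls.  That latent-factor construction directly controls the
separation between disease and control pairwise correlations that the
differential co-expression thresholds target: with loading a, module pairs
have population Pearson correlation a² in disease (Spearman slightly
lower) and ≈ 0 in control.

Matched survival data follow an exponential model whose log-hazard is
linear in the module score, with independent uniform censoring calibrated
to a requested censoring fraction and tumour stage assigned by score
quartile.  A drug-signature library (one exact reverser of the planted
signature plus random decoys) and an abstract corpus (known drugs
mentioned, novel drugs never mentioned) complete the inputs for the
repurposing and text-mining stages.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ExpressionStudy
from .repurpose import GeneSignature

#: invented drug names guaranteed absent from the generated abstracts
NOVEL_DRUG_NAMES = ("veltrazine", "opranidib", "xalofencin")
#: drugs planted into abstracts with positive frequency
KNOWN_DRUG_NAMES = ("doxorubicin", "vorinostat", "sorafenib")
#: the constructed exact reverser of the planted module signature
REVERSER_DRUG = "RVX-100"


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic multi-cohort experiment.

    Defaults echo the scale of a five-cohort microarray meta-analysis with
    ~300 pooled samples: 5 studies of 30+30 samples, 2000 genes of which 500
    are planted DEGs (log2 shift 1.5 ≈ 2.8-fold), and a 20-gene module
    with disease latent-factor loading 0.8.  Survival times are
    exponential with baseline hazard 0.02 per month and log-hazard slope
    ``survival_beta`` per unit module score, censored uniformly to ≈ 20 %.
    """

    n_studies: int = 5
    samples_per_phenotype: int = 30
    n_genes: int = 2000
    n_planted_degs: int = 500
    deg_log2fc: float = 1.5
    module_size: int = 20
    module_loading_disease: float = 0.8
    module_loading_control: float = 0.0
    noise_sd: float = 0.5
    survival_baseline_hazard: float = 0.02
    survival_beta: float = 1.0
    censoring_rate: float = 0.2
    seed: int = 0
    #: fraction of module genes given a negative factor loading (mixed-sign
    #: correlation patterns); 0 keeps all module pair correlations positive
    module_down_fraction: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_studies, self.samples_per_phenotype, self.n_genes,
               self.n_planted_degs, self.module_size) <= 0:
            raise ValueError("counts must be positive")
        if self.module_size > self.n_planted_degs:
            raise ValueError("module_size cannot exceed n_planted_degs")
        if self.n_planted_degs > self.n_genes:
            raise ValueError("n_planted_degs cannot exceed n_genes")
        if not 0 < self.module_loading_disease < 1:
            raise ValueError("module_loading_disease must lie in (0, 1)")
        if not 0 <= self.module_loading_control < 1:
            raise ValueError("module_loading_control must lie in [0, 1)")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.survival_baseline_hazard <= 0:
            raise ValueError("survival_baseline_hazard must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class GroundTruth:
    """What was planted: DEGs, directions, and module membership."""

    genes: list[str]
    planted_degs: list[str]
    directions: dict[str, str]
    module_genes: list[str]
    config: SimulationConfig

    def signature(self) -> GeneSignature:
        """The planted module signature (weights = planted log2 shifts)."""
        up = {g for g in self.module_genes if self.directions[g] == "up"}
        down = set(self.module_genes) - up
        weights = {
            g: (self.config.deg_log2fc if g in up else -self.config.deg_log2fc)
            for g in self.module_genes
        }
        return GeneSignature(up=up, down=down, weights=weights)

    def as_dict(self) -> dict:
        payload = asdict(self)
        payload["config"] = asdict(self.config)
        return payload


def _gene_names(n: int) -> list[str]:
    return [f"G{i + 1:05d}" for i in range(n)]


def simulate_multistudy_expression(
    config: SimulationConfig,
) -> tuple[list[ExpressionStudy], GroundTruth]:
    """Generate the cohorts and the ground-truth record.

    Background genes are Normal(μ_g, noise_sd) identically in both
    phenotypes (μ_g ~ U(4, 12), shared across studies, plus a small
    per-study batch offset); planted DEGs are shifted by ±deg_log2fc in
    disease; module genes additionally load on a per-sample latent factor
    with the condition-specific loading, keeping unit total variance
    before the noise_sd scale.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    planted = list(rng.choice(genes, size=config.n_planted_degs, replace=False))
    module = planted[: config.module_size]
    directions = {
        g: ("up" if i % 2 == 0 else "down") for i, g in enumerate(planted)
    }
    shift = np.array(
        [
            (config.deg_log2fc if directions[g] == "up" else -config.deg_log2fc)
            if g in set(planted) else 0.0
            for g in genes
        ]
    )
    n_neg = int(round(config.module_down_fraction * config.module_size))
    loading_sign = {
        g: (-1.0 if i < n_neg else 1.0) for i, g in enumerate(module)
    }
    mu = rng.uniform(4.0, 12.0, size=config.n_genes)
    module_idx = np.array([genes.index(g) for g in module])
    sign_vec = np.array([loading_sign[g] for g in module])
    studies = []
    m = config.samples_per_phenotype
    for s in range(config.n_studies):
        study_id = f"study{s + 1}"
        batch = rng.normal(0.0, 0.25, size=config.n_genes)
        blocks = {}
        for phenotype, loading, shifted in (
            ("disease", config.module_loading_disease, True),
            ("control", config.module_loading_control, False),
        ):
            noise = rng.normal(0.0, 1.0, size=(config.n_genes, m))
            factor = rng.normal(0.0, 1.0, size=m)
            values = noise.copy()
            # latent factor replaces part of the module genes' variance
            values[module_idx, :] = (
                loading * np.outer(sign_vec, factor)
                + np.sqrt(1.0 - loading**2) * noise[module_idx, :]
            )
            values = mu[:, None] + batch[:, None] + config.noise_sd * values
            if shifted:
                values = values + shift[:, None]
            blocks[phenotype] = values
        prefix = {"disease": "D", "control": "H"}
        columns, data, labels = [], [], []
        for phenotype in ("disease", "control"):
            for j in range(m):
                columns.append(f"{study_id}_{prefix[phenotype]}{j + 1:03d}")
                labels.append(phenotype)
            data.append(blocks[phenotype])
        matrix = pd.DataFrame(
            np.concatenate(data, axis=1), index=genes, columns=columns
        )
        studies.append(
            ExpressionStudy(
                study_id, matrix, pd.Series(labels, index=columns)
            ).validate()
        )
    truth = GroundTruth(
        genes=genes, planted_degs=planted, directions=directions,
        module_genes=module, config=config,
    )
    return studies, truth


def _calibrate_uniform_censoring(
    rates: np.ndarray, censoring_rate: float
) -> float:
    """Upper bound u of U(0, u) censoring hitting the requested fraction.

    For T ~ Exp(λ) and C ~ U(0, u), P(C < T) = (1 − e^{−λu})/(λu); the
    overall censored fraction is the mean over samples, decreasing in u.
    Solved by bisection.
    """

    def censored_fraction(u: float) -> float:
        x = rates * u
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-9, 1.0
    while censored_fraction(hi) > censoring_rate:
        hi *= 2.0
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if censored_fraction(mid) > censoring_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_survival(
    scores: pd.Series,
    config: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Exponential survival with log-hazard linear in the module score.

    Event times T_i ~ Exp(rate = baseline·exp(beta·score_i)); independent
    U(0, u) censoring with u calibrated so the expected censored fraction
    is ≈ ``censoring_rate`` (0 means fully observed).  Stage is assigned
    by score quartile (I–IV) to mimic stage-linked prognosis.  Indexed by
    sample id with columns time, event, stage, score.
    """
    scores = pd.Series(scores).astype(float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    rates = config.survival_baseline_hazard * np.exp(
        config.survival_beta * scores.to_numpy()
    )
    event_times = rng.exponential(1.0 / rates)
    if config.censoring_rate > 0:
        u = _calibrate_uniform_censoring(rates, config.censoring_rate)
        censor_times = rng.uniform(0.0, u, size=len(scores))
        time = np.minimum(event_times, censor_times)
        event = (event_times <= censor_times).astype(int)
    else:
        time = event_times
        event = np.ones(len(scores), dtype=int)
    quartile = pd.qcut(scores, 4, labels=["I", "II", "III", "IV"])
    return pd.DataFrame(
        {
            "time": time,
            "event": event,
            "stage": quartile.astype(str).to_numpy(),
            "score": scores.to_numpy(),
        },
        index=scores.index.rename("sample_id"),
    )


def simulate_validation_cohort(
    config: SimulationConfig,
    n_samples: int = 300,
    seed: int | None = None,
) -> tuple[ExpressionStudy, pd.DataFrame]:
    """Independent tumour cohort with module-driven survival.

    Mimics validating a module on an external cancer cohort: ``n_samples``
    disease samples whose module genes load on the disease latent factor;
    survival is generated from the measured module score via
    :func:`simulate_survival`.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    genes = _gene_names(config.n_genes)
    module = [
        g for g in _module_genes_of(config) if g in set(genes)
    ]
    a = config.module_loading_disease
    mu = rng.uniform(4.0, 12.0, size=len(module))
    factor = rng.normal(0.0, 1.0, size=n_samples)
    noise = rng.normal(0.0, 1.0, size=(len(module), n_samples))
    values = mu[:, None] + config.noise_sd * (
        a * factor[None, :] + np.sqrt(1.0 - a**2) * noise
    )
    columns = [f"V{j + 1:04d}" for j in range(n_samples)]
    matrix = pd.DataFrame(values, index=module, columns=columns)
    study = ExpressionStudy(
        "validation", matrix, pd.Series("disease", index=columns)
    )
    from .survival import module_score

    scores = module_score(study, module)
    base = config.seed if seed is None else seed
    table = simulate_survival(scores, config, seed=base + 3)
    return study, table


def _module_genes_of(config: SimulationConfig) -> list[str]:
    """Module gene names as drawn by simulate_multistudy_expression."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    planted = list(rng.choice(genes, size=config.n_planted_degs, replace=False))
    return planted[: config.module_size]


def simulate_corpus_and_library(
    truth: GroundTruth,
    config: SimulationConfig | None = None,
    n_decoys: int = 20,
    n_documents: int = 30,
    known_mention_count: int = 3,
) -> tuple[list[dict], dict[str, dict[str, float]], dict]:
    """Abstract corpus plus drug-signature library with planted answers.

    The library holds one exact reverser of the planted module signature
    (weights = negated signature weights) and ``n_decoys`` random-weight
    decoys over random gene subsets.  The corpus mentions each known drug
    ``known_mention_count`` times inside cancer-context abstracts; the
    designated novel drugs (and the reverser) never occur.
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 10)
    signature = truth.signature()
    library: dict[str, dict[str, float]] = {
        REVERSER_DRUG: {g: -signature.weight(g) for g in signature.genes}
    }
    # decoys either miss the module or overlap it substantially; a one-gene
    # overlap would make |cosine| = 1 by construction and is not a realistic
    # drug signature
    background = [g for g in truth.genes if g not in set(truth.module_genes)]
    module = list(truth.module_genes)
    for i in range(n_decoys):
        size = int(rng.integers(10, 40))
        drug_genes = list(rng.choice(background, size=size, replace=False))
        if rng.random() < 0.5:
            n_module = int(rng.integers(len(module) // 2, len(module) + 1))
            drug_genes += list(
                rng.choice(module, size=n_module, replace=False)
            )
        library[f"decoy{i + 1:02d}"] = {
            str(g): float(w)
            for g, w in zip(
                drug_genes, rng.normal(0.0, 1.0, size=len(drug_genes))
            )
        }
    contexts = [
        "thyroid cancer", "thyroid carcinoma", "cancer", "cell biology",
    ]
    corpus = []
    doc_id = 0
    for drug in KNOWN_DRUG_NAMES:
        context = contexts[doc_id % 3]  # always a cancer context
        mentions = " ".join(
            f"Treatment with {drug} altered proliferation."
            for _ in range(known_mention_count)
        )
        corpus.append(
            {
                "id": f"doc{doc_id:03d}",
                "text": f"A study of {context}. {mentions}",
            }
        )
        doc_id += 1
    while doc_id < n_documents:
        context = contexts[int(rng.integers(0, len(contexts)))]
        corpus.append(
            {
                "id": f"doc{doc_id:03d}",
                "text": (
                    f"An abstract about {context} discussing gene expression "
                    "programs and patient outcomes."
                ),
            }
        )
        doc_id += 1
    info = {
        "reverser": REVERSER_DRUG,
        "known_drugs": list(KNOWN_DRUG_NAMES),
        "novel_drugs": list(NOVEL_DRUG_NAMES),
        "known_mention_count": known_mention_count,
    }
    return corpus, library, info
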