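"""Prognostic evaluation of co-expression modules on censored survival data.

A module is summarized per patient as the mean z-scored expression of its
genes; patients are split at the median score into high/low risk groups and
compared with Kaplan–Meier curves and the log-rank test.  Because tumour
stage is the dominant prognostic factor, a stage-group log-rank and a
stage-stratified log-rank of the score split are also available; samples of
unknown stage are excluded from stage-involving analyses only.  A module is
flagged prognostic when the log-rank p-value falls below alpha (0.05).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .io import ExpressionStudy

logger = logging.getLogger(__name__)

STAGES = ("I", "II", "III", "IV")
UNKNOWN_STAGE = "unknown"


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns sample_id, time, event and optional stage."""
    table = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"survival table lacks columns: {sorted(missing)}")
    table = table.set_index("sample_id")
    validate_survival(table["time"], table["event"])
    return table


def validate_survival(time, event) -> None:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if np.any(time < 0):
        raise ValueError("survival times must be non-negative")
    if not set(np.unique(event)) <= {0, 1}:
        raise ValueError("event indicator must be 0 (censored) or 1 (event)")


def module_score(study: ExpressionStudy, module_genes) -> pd.Series:
    """Per-sample module score: mean of z-scored expression of module genes.

    Genes are z-scored across the study's samples (sample sd); module genes
    absent from the matrix are logged and ignored.  Constant genes carry no
    signal and are skipped.
    """
    module_genes = [str(g).strip() for g in module_genes]
    present = [g for g in module_genes if g in study.values.index]
    missing = sorted(set(module_genes) - set(present))
    if missing:
        logger.warning(
            "module genes absent from matrix (%d): %s",
            len(missing), ", ".join(missing[:10]),
        )
    if not present:
        raise ValueError("no module gene present in the expression matrix")
    sub = study.values.loc[present]
    std = sub.std(axis=1, ddof=1)
    usable = std > 0
    if not usable.any():
        raise ValueError("all module genes are constant across samples")
    z = sub.loc[usable].sub(sub.loc[usable].mean(axis=1), axis=0).div(
        std[usable], axis=0
    )
    return z.mean(axis=0).rename("score")


def assign_risk_groups(scores: pd.Series, method: str = "median") -> pd.Series:
    """Median split into high (> median) and low (≤ median) risk groups."""
    if method != "median":
        raise ValueError(f"unknown stratification method {method!r}")
    scores = pd.Series(scores)
    if len(scores) < 2:
        raise ValueError("need at least 2 samples to stratify")
    if scores.nunique() == 1:
        raise ValueError("all module scores identical; cannot stratify")
    median = scores.median()
    return pd.Series(
        np.where(scores > median, "high", "low"), index=scores.index,
        name="group",
    )


@dataclass
class KMCurve:
    """Product-limit survival estimate at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
            }
        )


def km_estimate(table: pd.DataFrame) -> KMCurve:
    """Kaplan–Meier product-limit estimator S(t) = Π (1 − d_i/n_i).

    ``table`` needs columns ``time`` and ``event``.  Events precede
    censorings at tied times (the standard convention).  Returns the curve
    evaluated at the distinct event (death) times; with no events the curve
    is flat at 1 and ``event_times`` is empty.
    """
    validate_survival(table["time"], table["event"])
    time = np.asarray(table["time"], dtype=float)
    event = np.asarray(table["event"], dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    event_times = np.unique(time[event == 1])
    if event_times.size == 0:
        return KMCurve(
            event_times=np.array([]), survival=np.array([]),
            at_risk=np.array([], dtype=int),
        )
    survival = (
        kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    )
    at_risk = np.array([(time >= t).sum() for t in event_times])
    return KMCurve(event_times=event_times, survival=survival, at_risk=at_risk)


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    df: int
    groups: tuple[str, ...]

    def __iter__(self):
        return iter((self.statistic, self.p_value))


def logrank_test(
    time, event, groups
) -> LogRankResult:
    """k-group log-rank chi-square over the pooled distinct event times.

    Observed-minus-expected event counts with the hypergeometric variance;
    (k−1) degrees of freedom.  Requires ≥ 2 non-empty groups and ≥ 1 event.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    validate_survival(time, event)
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) < 2:
        raise ValueError("log-rank test needs at least 2 non-empty groups")
    if event.sum() < 1:
        raise ValueError("log-rank test needs at least one observed event")
    res = multivariate_logrank_test(time, groups, event)
    return LogRankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        df=len(labels) - 1,
        groups=tuple(str(l) for l in labels),
    )


def stratified_logrank_test(
    time, event, groups, strata
) -> LogRankResult:
    """Log-rank test of ``groups`` pooled within levels of ``strata``.

    Observed-minus-expected vectors and hypergeometric covariance matrices
    are accumulated per stratum and summed before forming the chi-square,
    so the group comparison is adjusted for the stratifying factor.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    strata = np.asarray(strata)
    validate_survival(time, event)
    labels = sorted(pd.unique(groups).tolist())
    k = len(labels)
    if k < 2:
        raise ValueError("log-rank test needs at least 2 non-empty groups")
    if event.sum() < 1:
        raise ValueError("log-rank test needs at least one observed event")
    idx = {lab: i for i, lab in enumerate(labels)}
    o_minus_e = np.zeros(k)
    cov = np.zeros((k, k))
    for stratum in pd.unique(strata):
        mask = strata == stratum
        t_s, e_s, g_s = time[mask], event[mask], groups[mask]
        for t in np.unique(t_s[e_s == 1]):
            at_risk = t_s >= t
            n = at_risk.sum()
            d = int(((t_s == t) & (e_s == 1)).sum())
            if n <= 1:
                continue
            n_g = np.zeros(k)
            d_g = np.zeros(k)
            for lab in labels:
                gmask = g_s == lab
                n_g[idx[lab]] = (at_risk & gmask).sum()
                d_g[idx[lab]] = ((t_s == t) & (e_s == 1) & gmask).sum()
            p = n_g / n
            o_minus_e += d_g - d * p
            factor = d * (n - d) / (n - 1)
            cov += factor * (np.diag(p) - np.outer(p, p))
    v = cov[: k - 1, : k - 1]
    o = o_minus_e[: k - 1]
    statistic = float(o @ np.linalg.pinv(v) @ o)
    p_value = float(stats.chi2.sf(statistic, df=k - 1))
    return LogRankResult(
        statistic=statistic, p_value=p_value, df=k - 1,
        groups=tuple(str(l) for l in labels),
    )


@dataclass
class PrognosticReport:
    """Results of evaluating one module against a survival cohort."""

    module_genes: tuple[str, ...]
    n_samples: int
    alpha: float
    scores: pd.Series
    groups: pd.Series
    km_curves: dict[str, KMCurve]
    logrank: LogRankResult
    prognostic: bool
    stage_logrank: LogRankResult | None = None
    stratified_logrank: LogRankResult | None = None
    n_unknown_stage_excluded: int = 0
    table: pd.DataFrame = field(default=None, repr=False)

    def as_dict(self) -> dict:
        def lr(res):
            if res is None:
                return None
            return {
                "statistic": res.statistic, "p_value": res.p_value,
                "df": res.df, "groups": list(res.groups),
            }

        return {
            "n_samples": self.n_samples,
            "n_module_genes": len(self.module_genes),
            "alpha": self.alpha,
            "logrank": lr(self.logrank),
            "prognostic": self.prognostic,
            "stage_logrank": lr(self.stage_logrank),
            "stratified_logrank": lr(self.stratified_logrank),
            "n_unknown_stage_excluded": self.n_unknown_stage_excluded,
            "group_sizes": self.groups.value_counts().to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = [
            "Prognostic evaluation",
            "=====================",
            f"samples: {self.n_samples}   module genes: {len(self.module_genes)}"
            f"   alpha: {self.alpha}",
            f"risk groups: " + ", ".join(
                f"{g}={n}" for g, n in self.groups.value_counts().items()
            ),
            f"log-rank (high vs low score): chi2 = {self.logrank.statistic:.4f}, "
            f"p = {self.logrank.p_value:.3g}",
            f"prognostic: {'yes' if self.prognostic else 'no'}",
        ]
        if self.stage_logrank is not None:
            lines.append(
                f"log-rank across stages: chi2 = {self.stage_logrank.statistic:.4f},"
                f" p = {self.stage_logrank.p_value:.3g} "
                f"({self.n_unknown_stage_excluded} unknown-stage sample(s) excluded)"
            )
        if self.stratified_logrank is not None:
            lines.append(
                "stage-stratified log-rank (score split): "
                f"chi2 = {self.stratified_logrank.statistic:.4f}, "
                f"p = {self.stratified_logrank.p_value:.3g}"
            )
        return "\n".join(lines)


def evaluate_prognostic_module(
    table: pd.DataFrame,
    module_genes,
    study: ExpressionStudy,
    stratify_by_stage: bool = False,
    alpha: float = 0.05,
) -> PrognosticReport:
    """Score, stratify and log-rank test one module against survival data.

    ``table`` is indexed by sample id with columns ``time``, ``event`` and
    (when ``stratify_by_stage``) ``stage``.  Samples are intersected with
    the study's columns; the module is flagged prognostic when the
    high-vs-low log-rank p is below ``alpha``.
    """
    shared = [s for s in study.samples if s in table.index]
    if not shared:
        raise ValueError("no samples shared between survival table and matrix")
    sub_study = ExpressionStudy(
        study.study_id, study.values[shared], study.labels[shared]
    )
    scores = module_score(sub_study, module_genes)
    groups = assign_risk_groups(scores)
    surv = table.loc[shared, ["time", "event"]].copy()
    surv["score"] = scores
    surv["group"] = groups
    km_curves = {
        label: km_estimate(surv[surv["group"] == label])
        for label in ("high", "low")
    }
    logrank = logrank_test(surv["time"], surv["event"], surv["group"])
    stage_logrank = stratified = None
    n_excluded = 0
    if stratify_by_stage:
        if "stage" not in table.columns:
            raise ValueError("stratify_by_stage requires a 'stage' column")
        surv["stage"] = table.loc[shared, "stage"].fillna(UNKNOWN_STAGE)
        known = surv[surv["stage"].isin(STAGES)]
        n_excluded = len(surv) - len(known)
        if n_excluded:
            logger.info(
                "excluding %d unknown-stage sample(s) from stage analyses",
                n_excluded,
            )
        if known["stage"].nunique() >= 2 and known["event"].sum() >= 1:
            stage_logrank = logrank_test(
                known["time"], known["event"], known["stage"]
            )
            if known["group"].nunique() >= 2:
                stratified = stratified_logrank_test(
                    known["time"], known["event"], known["group"],
                    known["stage"],
                )
    return PrognosticReport(
        module_genes=tuple(module_genes),
        n_samples=len(shared),
        alpha=alpha,
        scores=scores,
        groups=groups,
        km_curves=km_curves,
        logrank=logrank,
        prognostic=bool(logrank.p_value < alpha),
        stage_logrank=stage_logrank,
        stratified_logrank=stratified,
        n_unknown_stage_excluded=n_excluded,
        table=surv,
    )


class ModulePrognosisModel:
    """Fit-style wrapper around :func:`evaluate_prognostic_module`."""

    def __init__(self, table: pd.DataFrame, study: ExpressionStudy, module_genes):
        self.table = table
        self.study = study
        self.module_genes = list(module_genes)

    def fit(
        self, stratify_by_stage: bool = False, alpha: float = 0.05
    ) -> PrognosticReport:
        return evaluate_prognostic_module(
            self.table, self.module_genes, self.study,
            stratify_by_stage=stratify_by_stage, alpha=alpha,
        )


def plot_km(report: PrognosticReport, path: str | Path) -> None:
    """Step-plot the high/low Kaplan–Meier curves to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, style in (("high", "-"), ("low", "--")):
        surv = report.table[report.table["group"] == label]
        kmf = KaplanMeierFitter()
        kmf.fit(surv["time"], surv["event"], label=f"{label} score")
        kmf.plot_survival_function(ax=ax, linestyle=style, ci_show=False)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_title(f"log-rank p = {report.logrank.p_value:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
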