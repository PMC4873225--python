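"""Candidate-biomarker prioritization cascade for grouped expression data.

The cascade mirrors a common discovery workflow for tissue biomarkers:
genes are ranked by differential expression between disease stages
(normal N, primary tumor T, metastasis M), gated on multiple-testing
adjusted significance, truncated to a top-K list per contrast, boosted
when both contrasts agree, and then filtered on tissue specificity,
survival association (Kaplan-Meier / log-rank on an expression-defined
risk split) and literature novelty.  Every gene that enters the cascade
leaves with a per-filter audit verdict (:class:`CandidateTrace`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionCohort",
    "PrioritizationConfig",
    "TwoGroupResult",
    "CandidateTrace",
    "log2_fold_change",
    "two_group_tests",
    "anova_f",
    "adjust_pvalues",
    "sam_d",
    "differential_expression",
    "select_top_k",
    "combined_rank",
    "tissue_filter",
    "literature_filter",
    "km_stratify",
    "km_curves",
    "logrank_test",
    "survival_filter",
    "run_prioritization",
]

GROUPS = ("N", "T", "M")


@dataclass
class ExpressionCohort:
    """Grouped log2 expression matrix plus the auxiliary prioritization tables.

    Parameters
    ----------
    matrix
        genes x samples DataFrame of log2 expression values.
    groups
        Per-sample label in {"N", "T", "M"} (index = sample ids).
    survival
        Per-sample DataFrame with columns ``time`` (months, >= 0) and
        ``event`` (bool; True = death/progression observed).
    tissue_scores
        genes x tissues non-negative specificity scores; must contain a
        ``prostate`` column.
    citations
        Per-gene non-negative literature co-occurrence counts.
    """

    matrix: pd.DataFrame
    groups: pd.Series
    survival: pd.DataFrame | None = None
    tissue_scores: pd.DataFrame | None = None
    citations: pd.Series | None = None

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.matrix.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without group label: {missing[:5]}")
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if self.survival is not None:
            if (self.survival["time"] < 0).any():
                raise ValueError("negative survival times")
        if self.tissue_scores is not None and "prostate" not in self.tissue_scores.columns:
            raise ValueError("tissue table lacks a 'prostate' column")

    def samples_in(self, *labels: str) -> list[str]:
        return list(self.groups.index[self.groups.isin(labels)])


@dataclass
class PrioritizationConfig:
    """Tunable knobs of the cascade (defaults follow the published workflow)."""

    K: int = 300
    alpha: float = 0.05
    adjust: str = "bonferroni"  # significance gate; "bh" optional
    s0: float | None = None  # SAM fudge factor; None -> median pooled SE
    tissue_ratio_min: float = 2.0
    citation_max: int = 5
    risk_quantile: float = 0.85
    boost: int = 5
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.risk_quantile < 1:
            raise ValueError("risk_quantile must be in (0, 1)")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.citation_max < 0:
            raise ValueError("citation_max must be >= 0")
        if self.adjust not in ("bonferroni", "bh"):
            raise ValueError("adjust must be 'bonferroni' or 'bh'")


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def log2_fold_change(
    matrix: pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    pseudocount: float = 0.0,
    input_scale: str = "log2",
) -> pd.Series:
    """log2 ratio of linear-scale group means, A over B.

    With ``input_scale="log2"`` (the cohort convention) values are
    exponentiated before averaging, so the result is the fold change of
    average expression, not the average of per-sample log ratios; pass
    ``input_scale="linear"`` for matrices already on the linear scale.
    """
    if len(samples_a) == 0 or len(samples_b) == 0:
        raise ValueError("both groups must be non-empty")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if input_scale not in ("log2", "linear"):
        raise ValueError("input_scale must be 'log2' or 'linear'")
    linear = np.power(2.0, matrix) if input_scale == "log2" else matrix
    mean_a = linear[list(samples_a)].mean(axis=1)
    mean_b = linear[list(samples_b)].mean(axis=1)
    with np.errstate(divide="ignore"):
        fc = np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)
    return pd.Series(fc, index=matrix.index, name="log2fc")


@dataclass
class TwoGroupResult:
    t: float
    t_p: float
    z: float
    z_p: float
    u: float
    u_p: float
    degenerate: bool = False  # zero variance in both groups


def two_group_tests(a: np.ndarray, b: np.ndarray) -> TwoGroupResult:
    """Welch t, reference-SD z, and Mann-Whitney U for one gene.

    The z statistic standardizes the mean difference by the standard
    deviation of the *second* (reference/normal) group.  The U test uses
    the exact null distribution when nA*nB <= 400 and there are no ties,
    otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")

    degenerate = False
    if a.size >= 2 and b.size >= 2:
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            degenerate = True
            t, t_p = 0.0, 1.0
        else:
            t, t_p = stats.ttest_ind(a, b, equal_var=False)
        sd_ref = np.std(b, ddof=1)
        if sd_ref == 0:
            z, z_p = (0.0, 1.0) if a.mean() == b.mean() else (math.inf, 0.0)
        else:
            z = (a.mean() - b.mean()) / sd_ref
            z_p = 2.0 * stats.norm.sf(abs(z))
    else:
        t = t_p = z = z_p = math.nan

    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    u, u_p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    if u == a.size * b.size / 2.0:
        u_p = 1.0  # perfectly balanced ranks: no evidence either way
    return TwoGroupResult(float(t), float(t_p), float(z), float(z_p), float(u), float(u_p), degenerate)


def anova_f(matrix: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """One-way ANOVA F and p per gene across the N/T/M groups."""
    groups = groups.reindex(matrix.columns)
    arrays = []
    for g in sorted(groups.dropna().unique()):
        cols = list(groups.index[groups == g])
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        arrays.append(matrix[cols].to_numpy())
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = stats.f_oneway(*arrays, axis=1)
    f = np.nan_to_num(f, nan=0.0)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame({"F": f, "p": p}, index=matrix.index)


def adjust_pvalues(p: Sequence[float], method: str = "bonferroni") -> np.ndarray:
    """Bonferroni (min(1, m*p)) or Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[method]
    return multipletests(p, method=key)[1]


def sam_d(a: np.ndarray, b: np.ndarray, s0: float) -> float:
    """SAM relative-difference statistic d = (meanA - meanB) / (s + s0).

    s is the pooled standard error sqrt((1/nA + 1/nB) * (SSA + SSB) /
    (nA + nB - 2)); the fudge factor s0 damps genes with tiny variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    ss = np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)
    s = math.sqrt((1.0 / a.size + 1.0 / b.size) * ss / (a.size + b.size - 2))
    if s + s0 == 0:
        raise ZeroDivisionError("s + s0 = 0")
    return float((a.mean() - b.mean()) / (s + s0))


def _pooled_se_matrix(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    na, nb = xa.shape[1], xb.shape[1]
    ssa = ((xa - xa.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssb = ((xb - xb.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return np.sqrt((1.0 / na + 1.0 / nb) * (ssa + ssb) / (na + nb - 2))


def differential_expression(
    cohort: ExpressionCohort,
    contrast: tuple[str, str],
    config: PrioritizationConfig | None = None,
) -> pd.DataFrame:
    """Vectorized per-gene statistics for one contrast (later stage first).

    Returns a DataFrame with log2 FC, Welch t/z/U statistics with raw
    p-values, Bonferroni-adjusted p, BH q, and the SAM d statistic.
    """
    config = config or PrioritizationConfig()
    later, earlier = contrast
    cols_a = cohort.samples_in(later)
    cols_b = cohort.samples_in(earlier)
    if not cols_a or not cols_b:
        raise ValueError(f"empty group in contrast {later}-vs-{earlier}")
    xa = cohort.matrix[cols_a].to_numpy(dtype=float)
    xb = cohort.matrix[cols_b].to_numpy(dtype=float)

    fc = log2_fold_change(cohort.matrix, cols_a, cols_b, config.pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, t_p = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
        sd_ref = xb.std(axis=1, ddof=1)
        z = np.where(sd_ref > 0, (xa.mean(axis=1) - xb.mean(axis=1)) / sd_ref, 0.0)
        z_p = 2.0 * stats.norm.sf(np.abs(z))
        u, u_p = stats.mannwhitneyu(xa, xb, alternative="two-sided", axis=1, method="asymptotic")
    t = np.nan_to_num(t, nan=0.0)
    t_p = np.where(np.isnan(t_p), 1.0, t_p)

    se = _pooled_se_matrix(xa, xb)
    s0 = config.s0 if config.s0 is not None else float(np.median(se))
    d = (xa.mean(axis=1) - xb.mean(axis=1)) / (se + s0)

    return pd.DataFrame(
        {
            "log2fc": fc,
            "t": t,
            "t_p": t_p,
            "z": z,
            "z_p": z_p,
            "u": u,
            "u_p": u_p,
            "sam_d": d,
            "p_bonf": adjust_pvalues(t_p, "bonferroni"),
            "q_bh": adjust_pvalues(t_p, "bh"),
        },
        index=cohort.matrix.index,
    )


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def select_top_k(de: pd.DataFrame, config: PrioritizationConfig) -> list[str]:
    """Significance-gate then rank by |log2 FC| and truncate to K.

    Genes with adjusted p below alpha are ordered by decreasing absolute
    fold change (ties broken lexicographically by gene id) and the first
    K retained.  Fewer than K significant genes yields a shorter list.
    """
    col = {"bonferroni": "p_bonf", "bh": "q_bh"}[config.adjust]
    sig = de[de[col] < config.alpha]
    order = sorted(sig.index, key=lambda g: (-abs(sig.at[g, "log2fc"]), g))
    return order[: config.K]


def combined_rank(top_tn: Sequence[str], top_mt: Sequence[str], boost: int = 5) -> pd.DataFrame:
    """Boost T-vs-N candidates that also appear in the M-vs-T top list.

    The base order is the T-vs-N list; a gene also present in the M-vs-T
    list has its (1-based) rank score reduced by ``boost``, and the list
    is stably re-sorted on the boosted score.
    """
    if len(set(top_tn)) != len(top_tn) or len(set(top_mt)) != len(top_mt):
        raise ValueError("top lists must be deduplicated")
    mt = set(top_mt)
    rows = []
    for pos, gene in enumerate(top_tn, start=1):
        in_mt = gene in mt
        rows.append((gene, pos, in_mt, pos - (boost if in_mt else 0)))
    rows.sort(key=lambda r: (r[3], r[1]))  # stable: score then original position
    out = pd.DataFrame(rows, columns=["gene", "rank_tn", "in_mt", "score"]).set_index("gene")
    out["combined_rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def tissue_filter(
    candidates: Sequence[str],
    tissue_scores: pd.DataFrame,
    tissue_ratio_min: float = 2.0,
) -> pd.DataFrame:
    """Keep genes whose prostate score dominates the other tissues.

    A gene passes iff prostate_score / median(non-prostate scores) >=
    tissue_ratio_min (boundary inclusive).  A gene missing from the
    table fails with reason ``missing`` instead of raising.
    """
    others = [c for c in tissue_scores.columns if c != "prostate"]
    rows = []
    for gene in candidates:
        if gene not in tissue_scores.index:
            rows.append((gene, math.nan, False, "missing"))
            continue
        prost = float(tissue_scores.at[gene, "prostate"])
        med = float(tissue_scores.loc[gene, others].median())
        ratio = math.inf if med == 0 else prost / med
        ok = ratio >= tissue_ratio_min
        rows.append((gene, ratio, ok, "" if ok else "tissue"))
    return pd.DataFrame(rows, columns=["gene", "ratio", "passed", "reason"]).set_index("gene")


def literature_filter(
    candidates: Sequence[str],
    citations: Mapping[str, int] | pd.Series,
    citation_max: int = 5,
) -> pd.DataFrame:
    """Exclude well-described genes: keep iff citation count <= citation_max.

    "More than citation_max" mentions excludes; a missing count is
    treated as zero (novel by absence of evidence) with a warning flag.
    """
    rows = []
    for gene in candidates:
        try:
            count = int(citations[gene])
            missing = False
        except (KeyError, TypeError):
            count, missing = 0, True
        ok = count <= citation_max
        rows.append((gene, count, missing, ok, "" if ok else "literature"))
    return pd.DataFrame(
        rows, columns=["gene", "citations", "count_missing", "passed", "reason"]
    ).set_index("gene")


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def km_stratify(values: pd.Series, risk_quantile: float = 0.85) -> pd.Series:
    """Split patients into low/high risk strata on an expression value.

    round(n * (1 - risk_quantile)) patients with the highest values are
    labelled ``high`` (half-up rounding); ties are broken by stable
    input order, so with all-equal values the first patients go high.
    """
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 patients")
    n_high = int(math.floor(n * (1.0 - risk_quantile) + 0.5))
    order = np.argsort(-values.to_numpy(), kind="stable")
    labels = np.full(n, "low", dtype=object)
    labels[order[:n_high]] = "high"
    return pd.Series(labels, index=values.index, name="risk")


def km_curves(
    times: Sequence[float], events: Sequence[bool], labels: Sequence[str]
) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit curve per stratum.

    Returns, per label, a DataFrame with columns ``time`` and
    ``survival`` (step function evaluated at the event/censor times,
    starting at S(0)=1).
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.asarray(labels)
    out: dict[str, pd.DataFrame] = {}
    for lab in pd.unique(labels):
        sel = labels == lab
        if sel.sum() == 0:
            raise ValueError(f"empty group {lab!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        sf = kmf.survival_function_
        out[str(lab)] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return out


def logrank_test(
    times: Sequence[float], events: Sequence[bool], labels: Sequence[str]
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square on 1 df, p)."""
    from lifelines.statistics import logrank_test as _lr

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError("log-rank test needs exactly two groups")
    a = labels == uniq[0]
    res = _lr(times[a], times[~a], events[a], events[~a])
    return float(res.test_statistic), float(res.p_value)


def _restricted_mean(times: np.ndarray, events: np.ndarray, horizon: float) -> float:
    """Area under the KM curve up to ``horizon`` (restricted mean survival)."""
    from lifelines import KaplanMeierFitter
    from lifelines.utils import restricted_mean_survival_time

    kmf = KaplanMeierFitter().fit(times, events)
    return float(restricted_mean_survival_time(kmf, t=horizon))


def survival_filter(
    cohort: ExpressionCohort,
    candidates: Sequence[str],
    config: PrioritizationConfig,
) -> pd.DataFrame:
    """Keep candidates whose high-expression stratum shows worse survival.

    For each gene the cohort is split 85/15 on expression; the gene
    passes iff the log-rank p is below alpha AND the high stratum has the
    smaller restricted-mean survival (high expression -> reduced
    survival, the prognostic direction sought for overexpressed markers).
    """
    if cohort.survival is None:
        raise ValueError("cohort has no survival annotations")
    surv = cohort.survival.dropna(subset=["time"])
    samples = [s for s in cohort.matrix.columns if s in surv.index]
    times = surv.loc[samples, "time"].to_numpy(dtype=float)
    events = surv.loc[samples, "event"].to_numpy(dtype=bool)
    horizon = float(times.max()) if len(times) else 0.0

    rows = []
    for gene in candidates:
        values = cohort.matrix.loc[gene, samples]
        labels = km_stratify(values, config.risk_quantile)
        chi2, p = logrank_test(times, events, labels.to_numpy())
        hi = labels.to_numpy() == "high"
        rm_high = _restricted_mean(times[hi], events[hi], horizon)
        rm_low = _restricted_mean(times[~hi], events[~hi], horizon)
        worse = rm_high < rm_low
        ok = (p < config.alpha) and worse
        rows.append((gene, chi2, p, rm_high, rm_low, ok, "" if ok else "survival"))
    return pd.DataFrame(
        rows,
        columns=["gene", "chi2", "p", "rm_high", "rm_low", "passed", "reason"],
    ).set_index("gene")


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

@dataclass
class CandidateTrace:
    """Audit trail of the cascade: per-gene ranks, verdicts and the final list."""

    table: pd.DataFrame
    final: list[str]
    audit: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.audit, fh, indent=2, default=str)


def run_prioritization(
    cohort: ExpressionCohort, config: PrioritizationConfig | None = None
) -> CandidateTrace:
    """Full cascade: DE -> top-K per contrast -> combined rank -> filters.

    Filter order is tissue specificity, survival association, literature
    novelty; each removal is attributed to the first failing filter.
    """
    config = config or PrioritizationConfig()
    stage = "differential expression"
    try:
        de_tn = differential_expression(cohort, ("T", "N"), config)
        de_mt = differential_expression(cohort, ("M", "T"), config)
        stage = "top-K selection"
        top_tn = select_top_k(de_tn, config)
        top_mt = select_top_k(de_mt, config)
        stage = "combined ranking"
        ranked = combined_rank(top_tn, top_mt, config.boost)
        candidates = list(ranked.index)

        stage = "tissue filter"
        if cohort.tissue_scores is None:
            raise ValueError("tissue filter: cohort has no tissue-score table")
        tis = tissue_filter(candidates, cohort.tissue_scores, config.tissue_ratio_min)

        stage = "survival filter"
        after_tissue = [g for g in candidates if tis.at[g, "passed"]]
        sur = survival_filter(cohort, after_tissue, config)

        stage = "literature filter"
        if cohort.citations is None:
            raise ValueError("literature filter: cohort has no citation table")
        after_survival = [g for g in after_tissue if sur.at[g, "passed"]]
        lit = literature_filter(after_survival, cohort.citations, config.citation_max)
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    final = [g for g in after_survival if lit.at[g, "passed"]]

    mt_rank = {g: i + 1 for i, g in enumerate(top_mt)}
    table = pd.DataFrame(index=pd.Index(candidates, name="gene"))
    table["fc_tn"] = de_tn.loc[candidates, "log2fc"]
    table["fc_mt"] = de_mt.loc[candidates, "log2fc"]
    table["p_tn"] = de_tn.loc[candidates, "t_p"]
    table["p_mt"] = de_mt.loc[candidates, "t_p"]
    table["q"] = de_tn.loc[candidates, "q_bh"]
    table["rank_tn"] = ranked["rank_tn"]
    table["rank_mt"] = [mt_rank.get(g, 0) for g in candidates]
    table["combined_rank"] = ranked["combined_rank"]
    table["tissue_pass"] = tis["passed"]
    table["survival_pass"] = [
        bool(sur.at[g, "passed"]) if g in sur.index else False for g in candidates
    ]
    table["literature_pass"] = [
        bool(lit.at[g, "passed"]) if g in lit.index else False for g in candidates
    ]
    table["final"] = [g in final for g in candidates]

    def first_fail(g: str) -> str:
        if not table.at[g, "tissue_pass"]:
            return str(tis.at[g, "reason"]) or "tissue"
        if g in sur.index and not sur.at[g, "passed"]:
            return "survival"
        if g in lit.index and not lit.at[g, "passed"]:
            return "literature"
        return ""

    table["first_fail"] = [first_fail(g) for g in candidates]

    audit = {
        "config": vars(config),
        "n_genes": int(len(cohort.matrix)),
        "n_top_tn": len(top_tn),
        "n_top_mt": len(top_mt),
        "n_combined": len(candidates),
        "n_after_tissue": len(after_tissue),
        "n_after_survival": len(after_survival),
        "n_final": len(final),
        "final": final,
    }
    return CandidateTrace(table=table, final=final, audit=audit)


# ---------------------------------------------------------------------------
# I/O glue (synthio TSV dialect)
# ---------------------------------------------------------------------------

def load_cohort(
    matrix_path, meta_path, tissue_path=None, citations_path=None
) -> ExpressionCohort:
    """Assemble an :class:`ExpressionCohort` from the TSV dialect on disk."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    survival = None
    if {"survival_months", "event"}.issubset(meta.columns):
        annotated = meta.dropna(subset=["survival_months", "event"])
        survival = pd.DataFrame(
            {"time": annotated["survival_months"], "event": annotated["event"].astype(bool)}
        )
    tissue = pd.read_csv(tissue_path, sep="\t", index_col=0) if tissue_path else None
    citations = (
        pd.read_csv(citations_path, sep="\t", index_col=0).iloc[:, 0]
        if citations_path
        else None
    )
    return ExpressionCohort(
        matrix=matrix,
        groups=meta["group"],
        survival=survival,
        tissue_scores=tissue,
        citations=citations,
    )
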