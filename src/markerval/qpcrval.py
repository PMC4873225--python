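"""Spike-in standardized qRT-PCR validation statistics.

Absolute quantification against a known amount of artificial spiked-in
RNA (an engineered KLK3 variant added before extraction), strict
three-replicate detection calling against the lowest detection limit
(LDL), the four-group contrast battery (CP-B, CP-IPCa, RP-B, RP-PCa),
clinical dichotomizations (Gleason, pT stage, PSA relapse, tumor
content) and ROC/AUC diagnostic evaluation.

The rank-sum identity AUC = U/(n1*n2) ties the diagnostic and the
hypothesis-testing views of the same comparison together; both are
exposed and tested against each other.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .prioritize import two_group_tests

__all__ = [
    "QpcrDataset",
    "ValidationReport",
    "QPCR_GROUPS",
    "CONTRASTS",
    "absolute_copies",
    "detection_call",
    "detection_table",
    "per_patient_value",
    "per_patient_table",
    "group_compare",
    "dichotomize",
    "roc_auc",
    "validation_report",
    "rp_sample_accounting",
    "round_percent",
]

log = logging.getLogger(__name__)

QPCR_GROUPS = ("CP-B", "CP-IPCa", "RP-B", "RP-PCa")
REP_COLS = ("rep1", "rep2", "rep3")

#: The group-contrast battery (later/positive arm first), mirroring the
#: clinical comparison table: pooled CP vs pooled RP, CP vs each RP arm,
#: field-effect comparisons, and the within-RP tumor-vs-benign contrast.
CONTRASTS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "CP vs RP": (("CP-B", "CP-IPCa"), ("RP-B", "RP-PCa")),
    "CP vs RP-PCa": (("CP-B", "CP-IPCa"), ("RP-PCa",)),
    "CP vs RP-B": (("CP-B", "CP-IPCa"), ("RP-B",)),
    "RP-B vs CP-IPCa": (("RP-B",), ("CP-IPCa",)),
    "CP-IPCa vs CP-B": (("CP-IPCa",), ("CP-B",)),
    "RP-PCa vs RP-B": (("RP-PCa",), ("RP-B",)),
}

#: Clinical dichotomies completing the battery (applied per patient).
DICHOTOMY_RULES = ("gleason", "stage", "relapse", "tumor_content")


@dataclass
class QpcrDataset:
    """Long-format triplicate copy counts with spike-in normalization fields.

    ``samples`` columns: sample, patient, lobe, group, gene, rep1..rep3,
    spike_added, spike_measured, rna_ug, ldl.  ``clinical`` is indexed by
    patient with columns gleason, pt_stage, relapse, tumor_content_pct
    (unknowns as NaN / "unknown").
    """

    samples: pd.DataFrame
    clinical: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = {"sample", "patient", "lobe", "group", "gene", *REP_COLS,
                    "spike_added", "spike_measured", "rna_ug", "ldl"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
        bad = set(self.samples["group"].unique()) - set(QPCR_GROUPS)
        if bad:
            raise ValueError(f"unknown qPCR groups: {sorted(bad)}")
        if (self.samples["rna_ug"] <= 0).any():
            raise ValueError("rna_ug must be positive")
        if (self.samples["spike_added"] <= 0).any():
            raise ValueError("spike_added must be positive")
        reps = self.samples[list(REP_COLS)].to_numpy(dtype=float)
        if (reps <= 0).any():
            raise ValueError("replicate copy counts must be positive")

    @property
    def genes(self) -> list[str]:
        return sorted(self.samples["gene"].unique())

    @classmethod
    def from_tsv(cls, qpcr_path, clinical_path=None) -> "QpcrDataset":
        samples = pd.read_csv(qpcr_path, sep="\t")
        clinical = (
            pd.read_csv(clinical_path, sep="\t", index_col="patient")
            if clinical_path is not None
            else None
        )
        return cls(samples=samples, clinical=clinical)


# ---------------------------------------------------------------------------
# quantification and detection
# ---------------------------------------------------------------------------

def absolute_copies(row: Mapping) -> dict:
    """Spike-in standardized copies per microgram of total RNA.

    recovery = spike_measured / spike_added estimates the fraction of
    material surviving extraction and reverse transcription; each raw
    replicate is divided by recovery and by the RNA input mass.
    Returns per-replicate values, their mean and median, plus flags.
    """
    spike_measured = float(row["spike_measured"])
    spike_added = float(row["spike_added"])
    if spike_measured <= 0:
        return {"quantifiable": False, "recovery": 0.0,
                "copies": (math.nan,) * 3, "mean": math.nan, "median": math.nan}
    recovery = spike_measured / spike_added
    if recovery > 1:
        log.warning("spike recovery > 1 (%.3f) for sample %s", recovery, row.get("sample"))
    rna_ug = float(row["rna_ug"])
    copies = tuple(float(row[c]) / (recovery * rna_ug) for c in REP_COLS)
    arr = np.array(copies)
    return {"quantifiable": True, "recovery": recovery, "copies": copies,
            "mean": float(arr.mean()), "median": float(np.median(arr))}


def quantify(dataset: QpcrDataset, summary: str = "mean") -> pd.DataFrame:
    """Per-sample normalized copy numbers; adds ``copies_per_ug`` and flags."""
    if summary not in ("mean", "median"):
        raise ValueError("summary must be 'mean' or 'median'")
    df = dataset.samples.copy()
    recovery = df["spike_measured"] / df["spike_added"]
    quantifiable = df["spike_measured"] > 0
    norm = df[list(REP_COLS)].to_numpy(dtype=float) / (
        recovery.to_numpy()[:, None] * df["rna_ug"].to_numpy()[:, None]
    )
    df["quantifiable"] = quantifiable
    reducer = np.mean if summary == "mean" else np.median
    df["copies_per_ug"] = np.where(quantifiable, reducer(norm, axis=1), np.nan)
    return df


def detection_call(replicates: Sequence[float], ldl: float) -> bool:
    """Positive iff *all three* raw replicates exceed the LDL (strict >)."""
    if len(replicates) != 3:
        raise ValueError("exactly 3 replicates required")
    return bool(min(float(r) for r in replicates) > float(ldl))


def round_percent(k: int, n: int) -> int:
    """Nearest-integer percentage, half away from zero."""
    return int(math.floor(100.0 * k / n + 0.5))


def detection_table(dataset: QpcrDataset) -> pd.DataFrame:
    """Gene x group detection frequencies: positives, n, integer percent."""
    rows = []
    for gene, gdf in dataset.samples.groupby("gene", sort=True):
        for group in QPCR_GROUPS:
            sub = gdf[gdf["group"] == group]
            if len(sub) == 0:
                continue
            pos = sum(
                detection_call(tuple(r), ldl)
                for r, ldl in zip(sub[list(REP_COLS)].to_numpy(), sub["ldl"])
            )
            rows.append((gene, group, int(pos), len(sub), round_percent(pos, len(sub))))
    return pd.DataFrame(rows, columns=["gene", "group", "positive", "n", "percent"])


# ---------------------------------------------------------------------------
# per-patient reduction and contrasts
# ---------------------------------------------------------------------------

def per_patient_value(samples: pd.DataFrame) -> float:
    """Single representative value for a patient represented by >1 sample.

    Preference order: right-lobe sample, else the single available
    sample, else the lexicographically smaller sample id; the value is
    the sample's summarized copies/µg.
    """
    quant = samples[samples["quantifiable"]] if "quantifiable" in samples else samples
    quant = quant.dropna(subset=["copies_per_ug"])
    if len(quant) == 0:
        raise ValueError("no quantifiable sample for patient")
    right = quant[quant["lobe"] == "right"]
    pool = right if len(right) else quant
    pool = pool.sort_values("sample", kind="stable")
    return float(pool.iloc[0]["copies_per_ug"])


def per_patient_table(quantified: pd.DataFrame, gene: str,
                      groups: Sequence[str] | None = None) -> pd.Series:
    """Patient -> single copies/µg value for one gene (right-lobe rule)."""
    sub = quantified[quantified["gene"] == gene]
    if groups is not None:
        sub = sub[sub["group"].isin(groups)]
    out = {}
    for patient, pdf in sub.groupby("patient", sort=True):
        try:
            out[patient] = per_patient_value(pdf)
        except ValueError:
            continue
    return pd.Series(out, name=gene)


def group_compare(
    dataset: QpcrDataset,
    gene: str,
    contrast: str | tuple[Sequence[str], Sequence[str]],
    summary: str = "mean",
) -> tuple[float, float]:
    """Mann-Whitney U comparison of normalized copy numbers for one gene.

    ``contrast`` is either a named battery entry or an explicit pair of
    group tuples (arm A first).  Returns (U of arm A, two-sided p).
    """
    if isinstance(contrast, str):
        if contrast not in CONTRASTS:
            raise KeyError(f"unknown contrast {contrast!r}")
        arm_a, arm_b = CONTRASTS[contrast]
    else:
        arm_a, arm_b = contrast
    for label in (*arm_a, *arm_b):
        if label not in QPCR_GROUPS:
            raise ValueError(f"unknown group label {label!r}")
    q = quantify(dataset, summary)
    q = q[q["gene"] == gene]
    a = q[q["group"].isin(arm_a)]["copies_per_ug"].dropna().to_numpy()
    b = q[q["group"].isin(arm_b)]["copies_per_ug"].dropna().to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"empty arm in contrast for gene {gene!r}")
    res = two_group_tests(a, b)
    return res.u, res.u_p


def dichotomize(clinical: pd.DataFrame, rule: str) -> pd.Series:
    """Binary clinical split per patient; unknowns are excluded.

    gleason: score >= 7 (aggressive) vs < 7; stage: pT3/pT4 vs pT2;
    relapse: PSA relapse vs none; tumor_content: > 33% tumor vs <= 33%.
    True marks the adverse arm.
    """
    if rule not in DICHOTOMY_RULES:
        raise ValueError(f"unknown rule {rule!r}")
    if rule == "gleason":
        g = pd.to_numeric(clinical["gleason"], errors="coerce")
        out = (g >= 7).where(g.notna())
    elif rule == "stage":
        s = clinical["pt_stage"].astype(str)
        out = s.map(lambda v: {"pT2": False, "pT3": True, "pT4": True}.get(v, np.nan))
    elif rule == "relapse":
        out = clinical["relapse"].map(
            lambda v: bool(v) if v in (True, False, 0, 1) else np.nan
        )
    else:  # tumor_content
        t = pd.to_numeric(clinical["tumor_content_pct"], errors="coerce")
        out = (t > 33.0).where(t.notna())
    return out.dropna().astype(bool)


def clinical_compare(
    dataset: QpcrDataset, gene: str, rule: str, summary: str = "mean"
) -> tuple[float, float]:
    """Mann-Whitney test of per-patient values across a clinical dichotomy.

    Applies the right-lobe per-patient reduction (the battery's footnote
    scope) over RP samples before testing adverse vs non-adverse arms.
    """
    if dataset.clinical is None:
        raise ValueError("dataset has no clinical table")
    labels = dichotomize(dataset.clinical, rule)
    q = quantify(dataset, summary)
    values = per_patient_table(q, gene, groups=("RP-B", "RP-PCa"))
    common = values.index.intersection(labels.index)
    a = values[common][labels[common]].to_numpy()
    b = values[common][~labels[common]].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"empty arm for rule {rule!r}")
    res = two_group_tests(a, b)
    return res.u, res.u_p


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_auc(values: Sequence[float], labels: Sequence[bool]) -> tuple[float, pd.DataFrame]:
    """AUC by the rank-sum identity, plus the full threshold-sweep curve.

    AUC = U/(n1*n2) where U counts positive-negative pairs ranked
    correctly, with half credit for ties — identical to the probability
    that a random positive scores above a random negative.  Curve points
    (fpr, tpr, threshold) come from a full threshold sweep.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(values)  # midranks give the tie half-credit
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    auc = float(u / (n1 * n0))

    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, values)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return auc, curve


def plot_roc(curve: pd.DataFrame, auc: float, title: str, path) -> None:
    """Write a single-gene ROC curve as a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve["fpr"], curve["tpr"], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"{title} (AUC = {auc:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """The four clinical-validation tables (detection, contrasts, dichotomies, ROC)."""

    detection: pd.DataFrame
    contrasts: pd.DataFrame
    dichotomies: pd.DataFrame
    roc: pd.DataFrame
    curves: dict = field(default_factory=dict)
    issues: list = field(default_factory=list)

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.detection.to_csv(out / "detection.tsv", sep="\t", index=False)
        self.contrasts.to_csv(out / "contrasts.tsv", sep="\t", index=False)
        self.dichotomies.to_csv(out / "dichotomies.tsv", sep="\t", index=False)
        self.roc.to_csv(out / "roc.tsv", sep="\t", index=False)


#: ROC comparisons: positive arm vs pooled CP reference (per-patient values).
ROC_COMPARISONS = {"RP-PCa vs CP": "RP-PCa", "RP-B vs CP": "RP-B"}


def validation_report(dataset: QpcrDataset, summary: str = "mean") -> ValidationReport:
    """Assemble detection, contrast, dichotomy and ROC tables for every gene."""
    issues: list[str] = []
    q = quantify(dataset, summary)
    det = detection_table(dataset)

    contrast_rows = []
    for gene in dataset.genes:
        for name in CONTRASTS:
            try:
                u, p = group_compare(dataset, gene, name, summary)
            except ValueError as exc:
                issues.append(f"{gene}/{name}: {exc}")
                continue
            contrast_rows.append((gene, name, u, p))
    contrasts = pd.DataFrame(contrast_rows, columns=["gene", "contrast", "U", "p"])

    dich_rows = []
    if dataset.clinical is not None:
        for gene in dataset.genes:
            for rule in DICHOTOMY_RULES:
                try:
                    u, p = clinical_compare(dataset, gene, rule, summary)
                except (ValueError, KeyError) as exc:
                    issues.append(f"{gene}/{rule}: {exc}")
                    continue
                dich_rows.append((gene, rule, u, p))
    dichotomies = pd.DataFrame(dich_rows, columns=["gene", "rule", "U", "p"])

    roc_rows = []
    curves: dict[tuple[str, str], pd.DataFrame] = {}
    for gene in dataset.genes:
        cp = per_patient_table(q, gene, groups=("CP-B", "CP-IPCa"))
        for name, pos_group in ROC_COMPARISONS.items():
            pos = per_patient_table(q, gene, groups=(pos_group,))
            if len(pos) == 0 or len(cp) == 0:
                issues.append(f"{gene}/{name}: empty class")
                continue
            values = np.concatenate([pos.to_numpy(), cp.to_numpy()])
            labels = np.concatenate([np.ones(len(pos), bool), np.zeros(len(cp), bool)])
            auc, curve = roc_auc(values, labels)
            roc_rows.append((gene, name, auc, len(pos), len(cp)))
            curves[(gene, name)] = curve
    roc = pd.DataFrame(roc_rows, columns=["gene", "comparison", "auc", "n_pos", "n_neg"])

    return ValidationReport(det, contrasts, dichotomies, roc, curves, issues)


# ---------------------------------------------------------------------------
# cohort bookkeeping
# ---------------------------------------------------------------------------

def rp_sample_accounting(
    n_patients: int = 90,
    n_both_benign: int = 30,
    n_both_cancer: int = 15,
    n_mixed: int = 45,
    excluded_benign: int = 1,
    excluded_cancer: int = 1,
) -> dict[str, int]:
    """Sample bookkeeping for a two-samples-per-patient prostatectomy cohort.

    Each patient contributes two tissue samples whose histology falls in
    one of three patterns (both benign, both cancerous, one of each);
    technically failed samples are excluded afterwards.  Returns the
    benign, cancerous and total sample counts entering the analysis.
    """
    if n_both_benign + n_both_cancer + n_mixed != n_patients:
        raise ValueError("pathology pattern counts must sum to the patient count")
    benign = 2 * n_both_benign + n_mixed - excluded_benign
    cancer = 2 * n_both_cancer + n_mixed - excluded_cancer
    return {"benign": benign, "cancer": cancer, "total": benign + cancer}
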