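"""Synthetic data generators emulating the study's statistical structure.

Four generators cover the pipeline's inputs: a grouped (N/T/M)
expression cohort with planted differential genes, tissue-specificity
and citation tables, and expression-linked survival; a four-group qPCR
cohort (CP-B, CP-IPCa, RP-B, RP-PCa) with triplicate copy counts,
spike-in recovery and a cancer-adjacent "field effect" elevating the
histologically benign RP-B samples over true normal CP-B; two-channel
organoid projection images with known protrusion counts and dead-cell
fractions; and a closing scratch-wound mask series.

Each generator consumes a named child stream of one master seed, so
outputs are bit-reproducible and adding a generator does not perturb
the others.  Ground truth accompanies every artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .prioritize import ExpressionCohort
from .qpcrval import QpcrDataset

__all__ = [
    "PlantedGene",
    "SimConfig",
    "gen_expression_cohort",
    "gen_qpcr_cohort",
    "gen_organoid_image",
    "gen_wound_series",
    "write_expression_cohort",
    "write_qpcr_cohort",
    "DEFAULT_PLANTED",
]

# Fixed stream ids: append-only so new generators never shift old streams.
_STREAMS = {
    "expression": 0,
    "survival": 1,
    "tissue": 2,
    "citations": 3,
    "qpcr": 4,
    "clinical": 5,
    "image": 6,
    "wound": 7,
}


@dataclass(frozen=True)
class PlantedGene:
    """Ground-truth effects for one planted biomarker candidate.

    effect_tn / effect_mt are additive log2 shifts of the T group over N
    and the M group over T; tissue_ratio is the prostate-over-other
    specificity; citations the literature count; hazard_log_ratio the
    log hazard increase per SD of expression in the survival model.
    """

    gene: str
    effect_tn: float = 2.0
    effect_mt: float = 0.0
    tissue_ratio: float = 5.0
    citations: int = 2
    hazard_log_ratio: float = 0.0


#: The study's eight validated markers as default planted genes; three of
#: them additionally separate metastatic from primary disease and carry a
#: survival association, mirroring the discovery structure.
DEFAULT_PLANTED: tuple[PlantedGene, ...] = tuple(
    PlantedGene(
        gene=g,
        effect_tn=2.0,
        effect_mt=1.0 if g in ("CACNA1D", "RHOU", "LMNB1") else 0.0,
        tissue_ratio=5.0,
        citations=2,
        hazard_log_ratio=2.0,
    )
    for g in ("ACSM1", "CACNA1D", "DLX1", "LMNB1", "PLA2G7", "RHOU", "SPON2", "TDRD1")
)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with one master seed.

    Group sizes default to a one-third-scale version of a 29/181/37
    N/T/M microarray cohort; qPCR groups keep the two small CP arms at
    full published size (7 and 12) and reduce the two RP arms.  The
    field-effect/cancer-effect defaults (3x and 10x over CP-B) preserve
    the study's ordering CP-B < RP-B < RP-PCa.
    """

    seed: int = 0
    # expression cohort
    n_genes: int = 2000
    group_sizes: tuple[int, int, int] = (10, 60, 12)  # N, T, M
    planted_genes: tuple[PlantedGene, ...] = DEFAULT_PLANTED
    noise_sd: float = 0.5
    baseline_range: tuple[float, float] = (4.0, 12.0)
    # survival model
    base_median_months: float = 60.0
    censor_horizon: float = 120.0
    prognostic_loading: float = 0.9  # correlation of prognostic genes with the latent factor
    # tissue / citation tables
    tissues: tuple[str, ...] = (
        "prostate", "breast", "lung", "colon", "liver", "kidney", "brain",
    )
    background_citation_mean: float = 20.0
    # qPCR cohort
    qpcr_group_sizes: tuple[int, int, int, int] = (7, 12, 20, 20)
    field_effect: float = 3.0
    cancer_effect: float = 10.0
    incidental_effect: float | None = None  # default sqrt(field_effect)
    base_copies_per_ug: float = 5e3
    biological_cv: float = 0.6  # lognormal sigma of between-sample spread
    replicate_cv: float = 0.15
    ldl: float = 100.0
    spike_added: float = 1e6
    recovery_range: tuple[float, float] = (0.3, 0.9)
    rna_ug_range: tuple[float, float] = (0.05, 0.2)
    # organoid images
    canvas: tuple[int, int] = (512, 512)
    n_organoids: int = 3
    radius_range: tuple[int, int] = (25, 40)
    protrusions_per_organoid: int = 0
    protrusion_length: int = 30
    protrusion_width: int = 6
    protrusion_shape: str = "rect"  # or "tri"
    dead_fraction: float = 0.0
    live_intensity: int = 20000
    dead_intensity: int = 30000
    placement_retries: int = 200
    # wound series
    wound_canvas: tuple[int, int] = (120, 200)
    wound_width: int = 60
    closure_rate: float = 0.1
    n_frames: int = 10
    frame_interval_h: float = 1.0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.group_sizes):
            raise ValueError("group sizes must be positive")
        if any(n < 0 for n in self.qpcr_group_sizes):
            raise ValueError("qPCR group sizes must be non-negative")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        lo, hi = self.recovery_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("recovery_range must satisfy 0 < lo <= hi <= 1")
        if self.field_effect > self.cancer_effect:
            raise ValueError("field_effect must not exceed cancer_effect")
        names = [p.gene for p in self.planted_genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate planted gene ids")
        if not 0 <= self.dead_fraction <= 1:
            raise ValueError("dead_fraction must be in [0, 1]")
        if not 0 <= self.closure_rate <= 1:
            raise ValueError("closure_rate must be in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        """Child generator for one named stream of the master seed."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# expression cohort
# ---------------------------------------------------------------------------

def _gene_names(config: SimConfig) -> list[str]:
    planted = [p.gene for p in config.planted_genes]
    width = len(str(config.n_genes))
    background = [f"G{str(i).zfill(width)}" for i in range(config.n_genes - len(planted))]
    return planted + background


def gen_expression_cohort(config: SimConfig) -> tuple[ExpressionCohort, dict]:
    """Grouped log2 expression matrix with planted effects and survival.

    Background genes share a flat baseline across groups; planted genes
    carry additive log2 shifts (T over N, M over T).  Prognostic planted
    genes (nonzero hazard_log_ratio) co-express with a per-sample latent
    "disease aggressiveness" factor (correlation = prognostic_loading of
    their within-group noise), and survival times for the primary-tumor
    patients are exponential with log hazard proportional to that
    factor, administratively censored at the configured horizon — so
    each prognostic gene individually stratifies outcome, as a
    co-expressed aggressiveness program does in real cohorts.  Ground
    truth lists per-gene true effects and per-sample true group.
    """
    rng = config.rng("expression")
    n_n, n_t, n_m = config.group_sizes
    n_samples = n_n + n_t + n_m
    genes = _gene_names(config)
    groups = np.array(["N"] * n_n + ["T"] * n_t + ["M"] * n_m)
    sample_ids = [f"S{str(i).zfill(3)}" for i in range(n_samples)]

    baseline = rng.uniform(*config.baseline_range, size=len(genes))
    matrix = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(len(genes), n_samples))
    aggressiveness = rng.normal(0.0, 1.0, size=n_samples)
    load = config.prognostic_loading
    planted_index = {p.gene: i for i, p in enumerate(config.planted_genes)}
    for gene, i in planted_index.items():
        p = config.planted_genes[i]
        row = genes.index(gene)
        if p.hazard_log_ratio != 0.0:
            # replace independent noise with factor-correlated noise of equal variance
            eps = rng.normal(0.0, 1.0, size=n_samples)
            matrix[row] = baseline[row] + config.noise_sd * (
                load * aggressiveness + np.sqrt(1.0 - load**2) * eps
            )
        matrix[row, groups == "T"] += p.effect_tn
        matrix[row, groups == "M"] += p.effect_tn + p.effect_mt

    mat = pd.DataFrame(matrix, index=pd.Index(genes, name="gene"), columns=sample_ids)
    group_s = pd.Series(groups, index=sample_ids, name="group")

    # survival for primary-tumor patients: exponential, log hazard =
    # (mean prognostic coefficient) x latent aggressiveness
    srng = config.rng("survival")
    betas = [p.hazard_log_ratio for p in config.planted_genes if p.hazard_log_ratio != 0.0]
    beta = float(np.mean(betas)) if betas else 0.0
    t_mask = groups == "T"
    lam0 = np.log(2.0) / config.base_median_months
    hazard = lam0 * np.exp(beta * aggressiveness[t_mask])
    raw_t = srng.exponential(1.0 / hazard)
    event = raw_t <= config.censor_horizon
    time = np.minimum(raw_t, config.censor_horizon)
    t_ids = [s for s, m in zip(sample_ids, t_mask) if m]
    survival = pd.DataFrame({"time": time, "event": event}, index=t_ids)

    # tissue-specificity scores: lognormal noise around 1, planted genes
    # elevated in the prostate column by their configured ratio
    trng = config.rng("tissue")
    base = trng.lognormal(mean=0.0, sigma=0.25, size=(len(genes), len(config.tissues)))
    tissue = pd.DataFrame(base, index=mat.index, columns=config.tissues)
    for p in config.planted_genes:
        tissue.at[p.gene, "prostate"] = p.tissue_ratio * float(
            tissue.loc[p.gene, [t for t in config.tissues if t != "prostate"]].median()
        )

    # citation counts: background well-described on average, planted novel
    crng = config.rng("citations")
    counts = crng.poisson(config.background_citation_mean, size=len(genes))
    citations = pd.Series(counts, index=mat.index, name="count")
    for p in config.planted_genes:
        citations.at[p.gene] = p.citations

    cohort = ExpressionCohort(
        matrix=mat, groups=group_s, survival=survival,
        tissue_scores=tissue, citations=citations,
    )
    truth = {
        "planted": pd.DataFrame(
            [vars(p) for p in config.planted_genes]
        ).set_index("gene") if config.planted_genes else pd.DataFrame(),
        "groups": group_s.copy(),
    }
    return cohort, truth


def write_expression_cohort(cohort: ExpressionCohort, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "expression_matrix.tsv",
        "meta": out / "sample_metadata.tsv",
        "tissue": out / "tissue_scores.tsv",
        "citations": out / "citations.tsv",
    }
    cohort.matrix.to_csv(paths["matrix"], sep="\t")
    meta = pd.DataFrame({"group": cohort.groups})
    if cohort.survival is not None:
        surv = cohort.survival.reindex(meta.index)
        meta["survival_months"] = surv["time"]
        meta["event"] = surv["event"].astype("Int64")
    meta.index.name = "sample"
    meta.to_csv(paths["meta"], sep="\t")
    if cohort.tissue_scores is not None:
        cohort.tissue_scores.to_csv(paths["tissue"], sep="\t")
    if cohort.citations is not None:
        cohort.citations.to_frame().to_csv(paths["citations"], sep="\t")
    return paths


# ---------------------------------------------------------------------------
# qPCR cohort
# ---------------------------------------------------------------------------

def gen_qpcr_cohort(config: SimConfig) -> tuple[QpcrDataset, dict]:
    """Four-group qPCR cohort with spike-in recovery and a field effect.

    Per-sample true copy numbers are lognormal around a group mean:
    CP-B at baseline, CP-IPCa mildly elevated (geometric midpoint of the
    field effect by default), RP-B elevated by the field effect and
    RP-PCa by the cancer effect.  Raw replicate counts fold in the
    per-sample spike recovery and RNA mass plus multiplicative replicate
    noise, so spike-in normalization is required to recover the truth.
    Paired RP samples share a patient id and carry left/right lobes.
    """
    rng = config.rng("qpcr")
    n_cpb, n_ipca, n_rpb, n_rppca = config.qpcr_group_sizes
    genes = [p.gene for p in config.planted_genes] or ["MARKER1"]
    incidental = (
        config.incidental_effect
        if config.incidental_effect is not None
        else float(np.sqrt(config.field_effect))
    )
    multipliers = {
        "CP-B": 1.0,
        "CP-IPCa": incidental,
        "RP-B": config.field_effect,
        "RP-PCa": config.cancer_effect,
    }

    # sample frame: CP patients contribute one sample; RP patients are
    # paired (one benign, one cancerous) until one arm is exhausted
    entries: list[tuple[str, str, str, str]] = []  # sample, patient, lobe, group
    sid = 0
    for group, count in (("CP-B", n_cpb), ("CP-IPCa", n_ipca)):
        for _ in range(count):
            entries.append((f"Q{sid:04d}", f"CP{sid:03d}", "NA", group))
            sid += 1
    n_paired = min(n_rpb, n_rppca)
    # one coin per patient decides which lobe holds the cancerous sample
    for i in range(n_paired):
        pat = f"RP{i:03d}"
        lobe_b, lobe_c = ("right", "left") if rng.random() < 0.5 else ("left", "right")
        entries.append((f"Q{sid:04d}", pat, lobe_b, "RP-B")); sid += 1
        entries.append((f"Q{sid:04d}", pat, lobe_c, "RP-PCa")); sid += 1
    for j in range(n_rpb - n_paired):
        entries.append((f"Q{sid:04d}", f"RP{n_paired + j:03d}", "right", "RP-B")); sid += 1
    for j in range(n_rppca - n_paired):
        entries.append((f"Q{sid:04d}", f"RP{n_paired + (n_rpb - n_paired) + j:03d}",
                        "right", "RP-PCa")); sid += 1

    frame = pd.DataFrame(entries, columns=["sample", "patient", "lobe", "group"])
    n = len(frame)
    recovery = rng.uniform(*config.recovery_range, size=n)
    rna_ug = rng.uniform(*config.rna_ug_range, size=n)

    rows = []
    truth_rows = []
    for gene in genes:
        mult = frame["group"].map(multipliers).to_numpy()
        true_level = config.base_copies_per_ug * mult * rng.lognormal(
            mean=0.0, sigma=config.biological_cv, size=n
        )
        expected_raw = true_level * recovery * rna_ug
        reps = expected_raw[:, None] * rng.lognormal(
            mean=0.0, sigma=config.replicate_cv, size=(n, 3)
        )
        for i in range(n):
            rows.append((
                frame.at[i, "sample"], frame.at[i, "patient"], frame.at[i, "lobe"],
                frame.at[i, "group"], gene,
                reps[i, 0], reps[i, 1], reps[i, 2],
                config.spike_added, config.spike_added * recovery[i],
                rna_ug[i], config.ldl,
            ))
            truth_rows.append((frame.at[i, "sample"], gene, true_level[i]))

    samples = pd.DataFrame(rows, columns=[
        "sample", "patient", "lobe", "group", "gene",
        "rep1", "rep2", "rep3", "spike_added", "spike_measured", "rna_ug", "ldl",
    ])

    # clinical annotations for RP patients (independent of expression: a
    # null association, so dichotomy p-values are calibrated, not planted)
    crng = config.rng("clinical")
    rp_patients = sorted(frame.loc[frame["group"].str.startswith("RP"), "patient"].unique())
    clinical = pd.DataFrame({
        "patient": rp_patients,
        "gleason": crng.choice([5, 6, 7, 8, 9], size=len(rp_patients),
                               p=[0.15, 0.35, 0.35, 0.1, 0.05]),
        "pt_stage": crng.choice(["pT2", "pT3", "pT4"], size=len(rp_patients),
                                p=[0.6, 0.35, 0.05]),
        "relapse": crng.random(len(rp_patients)) < 0.2,
        "tumor_content_pct": np.round(crng.uniform(5, 95, size=len(rp_patients)), 1),
    }).set_index("patient")

    dataset = QpcrDataset(samples=samples, clinical=clinical)
    truth = {
        "true_copies": pd.DataFrame(truth_rows, columns=["sample", "gene", "copies_per_ug"]),
        "group_multipliers": multipliers,
        "recovery": pd.Series(recovery, index=frame["sample"], name="recovery"),
    }
    return dataset, truth


def write_qpcr_cohort(dataset: QpcrDataset, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"qpcr": out / "qpcr_long.tsv", "clinical": out / "clinical.tsv"}
    dataset.samples.to_csv(paths["qpcr"], sep="\t", index=False)
    if dataset.clinical is not None:
        dataset.clinical.to_csv(paths["clinical"], sep="\t")
    return paths


# ---------------------------------------------------------------------------
# organoid images
# ---------------------------------------------------------------------------

def _disk_mask(shape: tuple[int, int], center: tuple[int, int], radius: int) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _protrusion_mask(
    shape: tuple[int, int], center: tuple[int, int], radius: int,
    angle: float, length: int, width: int, kind: str,
) -> np.ndarray:
    """Rectangle (or triangle) radiating outward from the organoid boundary."""
    from skimage.draw import polygon

    cy, cx = center
    d = np.array([np.cos(angle), np.sin(angle)])  # (row, col) direction
    p = np.array([-np.sin(angle), np.cos(angle)])  # perpendicular
    r0 = radius - 2  # anchor just inside the body so the spike is attached
    base = np.array([cy, cx]) + r0 * d
    tip = np.array([cy, cx]) + (r0 + length) * d
    half = width / 2.0
    if kind == "rect":
        corners = np.array([base + half * p, base - half * p, tip - half * p, tip + half * p])
    else:  # triangle tapering to a point
        corners = np.array([base + half * p, base - half * p, tip])
    rr, cc = polygon(corners[:, 0], corners[:, 1], shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def gen_organoid_image(config: SimConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Two-channel 16-bit projection image with ground-truth morphology.

    Channel 0 (live stain) holds disks with evenly spaced protrusions of
    the configured shape; channel 1 (dead stain) holds random interior
    speckles covering ``dead_fraction`` of each body.  Organoids are
    placed without overlap within a margin that accommodates the
    protrusion length; placement failure after bounded retries raises.
    Returns (image[2, H, W], truth table).
    """
    rng = config.rng("image")
    h, w = config.canvas
    margin = config.radius_range[1] + config.protrusion_length + 2
    if min(h, w) <= 2 * margin:
        raise ValueError("canvas too small for organoid diameter + protrusion length")

    live = np.zeros((h, w), dtype=np.uint16)
    dead = np.zeros((h, w), dtype=np.uint16)
    placed: list[tuple[int, int, int]] = []
    truth_rows = []
    for k in range(config.n_organoids):
        for attempt in range(config.placement_retries):
            r = int(rng.integers(config.radius_range[0], config.radius_range[1] + 1))
            cy = int(rng.integers(margin, h - margin))
            cx = int(rng.integers(margin, w - margin))
            clearance = r + config.protrusion_length
            if all(
                (cy - py) ** 2 + (cx - px) ** 2
                > (clearance + pr + config.protrusion_length + 2) ** 2
                for py, px, pr in placed
            ):
                break
        else:
            raise RuntimeError(
                f"could not place organoid {k} without overlap "
                f"after {config.placement_retries} retries"
            )
        placed.append((cy, cx, r))

        body = _disk_mask((h, w), (cy, cx), r)
        mask = body.copy()
        n_prot = config.protrusions_per_organoid
        if n_prot > 0:
            spacing = 2 * np.pi / n_prot
            phase = rng.uniform(0, 2 * np.pi)
            jitter = rng.uniform(-0.2, 0.2, size=n_prot) * spacing
            for j in range(n_prot):
                ang = phase + j * spacing + jitter[j]
                mask |= _protrusion_mask(
                    (h, w), (cy, cx), r, ang,
                    config.protrusion_length, config.protrusion_width,
                    config.protrusion_shape,
                )
        live[mask] = config.live_intensity

        if config.dead_fraction > 0:
            interior = np.flatnonzero(body)
            n_dead = int(round(config.dead_fraction * interior.size))
            chosen = rng.choice(interior, size=n_dead, replace=False)
            flat = dead.reshape(-1)
            flat[chosen] = config.dead_intensity
        truth_rows.append((k, cy, cx, r, int(np.sum(body)), n_prot, config.dead_fraction))

    truth = pd.DataFrame(
        truth_rows,
        columns=["organoid", "center_row", "center_col", "radius",
                 "body_area", "protrusions", "dead_fraction"],
    )
    return np.stack([live, dead]), truth


# ---------------------------------------------------------------------------
# wound series
# ---------------------------------------------------------------------------

def gen_wound_series(config: SimConfig) -> tuple[list[np.ndarray], np.ndarray, pd.DataFrame]:
    """Binary confluence masks of a scratch wound closing inward.

    The initial frame has a fully confluent monolayer except a centered
    vertical wound strip of the configured width; at frame t the
    remaining open width is w0 * max(0, 1 - rate*t), filled symmetrically
    from both wound edges.  Returns (frames, wound_region, truth).
    """
    h, w = config.wound_canvas
    w0 = config.wound_width
    if w0 >= w:
        raise ValueError("wound wider than canvas")
    left = (w - w0) // 2
    wound_region = np.zeros((h, w), dtype=bool)
    wound_region[:, left : left + w0] = True

    frames = []
    widths = []
    for t in range(config.n_frames):
        open_w = w0 * max(0.0, 1.0 - config.closure_rate * t)
        open_px = int(round(open_w))
        frame = np.ones((h, w), dtype=bool)
        if open_px > 0:
            start = left + (w0 - open_px) // 2
            frame[:, start : start + open_px] = False
        frames.append(frame)
        widths.append(open_px)

    truth = pd.DataFrame({
        "frame": np.arange(config.n_frames),
        "hours": np.arange(config.n_frames) * config.frame_interval_h,
        "open_width_px": widths,
        "closure_rate": config.closure_rate,
    })
    return frames, wound_region, truth
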