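"""Cross-validated diagnostic evaluation with clustered inference.

Patient-level stratified 5-fold cross-validation (all eyes of a patient
share a fold; folds are stratified by diagnosis), horizontal-mirroring
augmentation of the minority class on training folds only, rank-based
AUROC / step-integrated AUPRC, sensitivity at fixed specificity, patient-
cluster bootstrap confidence intervals, Wald tests on AUROC differences
using the paired bootstrap covariance, covariate-adjusted AUROC via
placement values, and the axial-length cohort summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import spawn_seed, substream
from .autoencoder import AEConfig, train_autoencoder
from .mrf import MRFConfig
from .scoring import MODEL_NAMES, LeakageError, healthy_reference, model_scores
from .types import EyeRecord, TextureEnfaceMap, ThicknessMap

__all__ = [
    "FoldAssignment",
    "make_folds",
    "augment_minority",
    "auroc",
    "auprc",
    "sens_at_spec",
    "cluster_bootstrap",
    "BootstrapResult",
    "wald_auroc_diff",
    "WaldResult",
    "adjusted_auroc",
    "cohort_summary",
    "CohortSummary",
    "ExperimentConfig",
    "DiagnosticReport",
    "run_experiment",
]


# ---------------------------------------------------------------------------
# Folds and augmentation


@dataclass
class FoldAssignment:
    mapping: dict  # patient_id -> fold in 1..k
    k: int
    seed: int

    def fold_of(self, patient_id: str) -> int:
        return self.mapping[patient_id]


def make_folds(records: Sequence[EyeRecord], k: int = 5, seed: int = 0) -> FoldAssignment:
    """Stratified-by-diagnosis patient-level partition into ``k`` folds."""
    by_patient: dict = {}
    for r in records:
        by_patient.setdefault(r.patient_id, set()).add(r.diagnosis)
    for pid, diags in by_patient.items():
        if len(diags) > 1:
            raise ValueError(f"patient {pid} has mixed diagnoses; cannot stratify")
    mapping: dict = {}
    for diagnosis in ("healthy", "glaucoma"):
        patients = sorted(p for p, d in by_patient.items() if diagnosis in d)
        if not patients:
            continue
        if len(patients) < k:
            raise ValueError(f"need at least {k} {diagnosis} patients, got {len(patients)}")
        rng = substream(seed, "folds", diagnosis)
        order = rng.permutation(len(patients))
        for i, idx in enumerate(order):
            mapping[patients[idx]] = (i % k) + 1
    return FoldAssignment(mapping=mapping, k=k, seed=seed)


def augment_minority(
    train_images: Sequence[np.ndarray],
    train_labels: Sequence[int],
    patient_ids: Optional[Sequence[str]] = None,
) -> tuple[list, list, list, list]:
    """Append horizontally mirrored copies of minority-class images until
    class counts are within 1.

    Returns ``(images, labels, patient_ids, mirrored_flags)``; mirrored
    copies inherit the patient_id of their source image.  Balanced input is
    returned unchanged.
    """
    labels = [int(l) for l in train_labels]
    if len(set(labels)) < 2:
        raise ValueError("both classes must be present")
    pids = list(patient_ids) if patient_ids is not None else [""] * len(labels)
    images = list(train_images)
    flags = [False] * len(images)
    counts = {c: labels.count(c) for c in (0, 1)}
    minority = 0 if counts[0] < counts[1] else 1
    deficit = abs(counts[0] - counts[1])
    sources = [i for i, l in enumerate(labels) if l == minority]
    for j in range(deficit):
        src = sources[j % len(sources)]
        images.append(np.fliplr(np.asarray(train_images[src])))
        labels.append(minority)
        pids.append(pids[src])
        flags.append(True)
    return images, labels, pids, flags


# ---------------------------------------------------------------------------
# Metrics


def _check_two_class(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(int)
    if not ((labels == 0) | (labels == 1)).all():
        raise ValueError("labels must be 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return labels == 1, labels == 0


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUROC by the rank (Mann-Whitney) formula with tie correction."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_class(np.asarray(labels))
    ranks = stats.rankdata(scores)  # average ranks handle ties
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve by step integration
    (sum over recall increments of the precision at each threshold)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_two_class(labels)
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    # group tied scores: evaluate at distinct-threshold boundaries
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    n_pos = labels.sum()
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def sens_at_spec(scores: Sequence[float], labels: Sequence[int], spec: float) -> float:
    """Sensitivity at the smallest threshold achieving specificity >= spec.

    An eye is called positive when its score exceeds the threshold; the
    threshold is the smallest observed score cut with empirical specificity
    at or above the target (no ROC interpolation).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos, neg = _check_two_class(labels)
    neg_scores = scores[pos == False]  # noqa: E712
    pos_scores = scores[pos]
    candidates = np.unique(scores)
    for t in candidates:
        specificity = float((neg_scores <= t).mean())
        if specificity >= spec:
            return float((pos_scores > t).mean())
    # unreachable specificity: threshold above all scores
    t = candidates[-1]
    return float((pos_scores > t).mean())


# ---------------------------------------------------------------------------
# Clustered bootstrap inference


@dataclass
class BootstrapResult:
    point: dict
    ci: dict  # name -> (lo, hi)
    draws: dict  # name -> (n_boot,) replicate metrics
    n_boot: int
    seed: int
    n_redrawn: int = 0


def cluster_bootstrap(
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    scores_by_eye,
    labels: Sequence[int],
    patient_ids: Sequence[str],
    n_boot: int = 1000,
    seed: int = 0,
    max_redraws: int = 10_000,
) -> BootstrapResult:
    """Percentile bootstrap CIs resampling patient clusters of eyes.

    ``scores_by_eye`` may be one score vector or a dict of named vectors;
    all vectors share each replicate's resample, so the returned draws are
    paired across models (required for the Wald covariance).  Replicates in
    which the metric is undefined (a class absent) are redrawn and counted.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if not isinstance(scores_by_eye, dict):
        scores_by_eye = {"metric": np.asarray(scores_by_eye, dtype=float)}
    scores_by_eye = {k: np.asarray(v, dtype=float) for k, v in scores_by_eye.items()}
    labels = np.asarray(labels).astype(int)
    pids = np.asarray([str(p) for p in patient_ids])
    patients = np.unique(pids)
    eye_idx = {p: np.nonzero(pids == p)[0] for p in patients}

    point = {k: float(metric_fn(v, labels)) for k, v in scores_by_eye.items()}
    rng = substream(seed, "bootstrap")
    draws = {k: np.empty(n_boot) for k in scores_by_eye}
    n_redrawn = 0
    b = 0
    attempts = 0
    while b < n_boot:
        attempts += 1
        if attempts > n_boot + max_redraws:
            raise RuntimeError("too many degenerate bootstrap replicates")
        chosen = rng.choice(patients, size=len(patients), replace=True)
        idx = np.concatenate([eye_idx[p] for p in chosen])
        yb = labels[idx]
        if yb.min() == yb.max():
            n_redrawn += 1
            continue
        for k, v in scores_by_eye.items():
            draws[k][b] = metric_fn(v[idx], yb)
        b += 1
    ci = {k: (float(np.percentile(d, 2.5)), float(np.percentile(d, 97.5))) for k, d in draws.items()}
    return BootstrapResult(point=point, ci=ci, draws=draws, n_boot=n_boot, seed=seed, n_redrawn=n_redrawn)


@dataclass
class WaldResult:
    delta: float
    se: float
    p: float
    degenerate_se: bool = False


def wald_auroc_diff(
    draws_a: np.ndarray, draws_b: np.ndarray, point_a: float, point_b: float
) -> WaldResult:
    """Wald test of a metric difference using the paired bootstrap draws."""
    draws_a = np.asarray(draws_a, dtype=float)
    draws_b = np.asarray(draws_b, dtype=float)
    if draws_a.shape != draws_b.shape:
        raise ValueError("draws must be paired by replicate")
    delta = float(point_a - point_b)
    se = float(np.std(draws_a - draws_b, ddof=1))
    if se == 0.0:
        if delta == 0.0:
            return WaldResult(delta=delta, se=se, p=1.0)
        return WaldResult(delta=delta, se=se, p=1.0 / draws_a.size, degenerate_se=True)
    z = delta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return WaldResult(delta=delta, se=se, p=p)


def adjusted_auroc(
    scores: Sequence[float], labels: Sequence[int], covariates: np.ndarray
) -> float:
    """Covariate-adjusted AUROC via placement values.

    A linear model of score on covariates is fit among controls; every
    eye's score is residualised against it, and each case's placement value
    is the fraction of control residuals it exceeds (ties counted half).
    The mean placement value is the adjusted AUROC; with covariates that
    carry no information it reduces to the ordinary AUROC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos, neg = _check_two_class(labels)
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != scores.size:
        raise ValueError("covariates must align with scores")
    if not np.isfinite(x).all():
        raise ValueError("covariates must be complete")
    design = np.column_stack([np.ones(scores.size), x])
    beta, *_ = np.linalg.lstsq(design[neg], scores[neg], rcond=None)
    resid = scores - design @ beta
    r_controls = resid[neg]
    r_cases = resid[pos]
    placements = [
        (r_controls < r).mean() + 0.5 * (r_controls == r).mean() for r in r_cases
    ]
    return float(np.mean(placements))


# ---------------------------------------------------------------------------
# Cohort summary (axial-length categories)

AL_CATEGORIES = ("emmetropic_mild", "moderate", "high")


def al_category(axial_length: float) -> str:
    """Axial-length myopia category: <24.5 mm emmetropic-mild myopic,
    24.5-26.0 mm moderately myopic, >26.0 mm highly myopic."""
    if axial_length < 24.5:
        return "emmetropic_mild"
    if axial_length <= 26.0:
        return "moderate"
    return "high"


@dataclass
class CohortSummary:
    table: pd.DataFrame  # one row per AL category
    overall_chi2_p: float
    demographics: pd.DataFrame  # per-diagnosis means with CIs and tests


def _mean_ci(x: np.ndarray) -> tuple[float, float, float]:
    x = np.asarray(x, dtype=float)
    m = float(x.mean())
    if x.size < 2:
        return m, m, m
    half = float(stats.t.ppf(0.975, x.size - 1) * x.std(ddof=1) / np.sqrt(x.size))
    return m, m - half, m + half


def cohort_summary(manifest: Sequence[EyeRecord] | pd.DataFrame) -> CohortSummary:
    """Per-diagnosis eye counts and column percentages per axial-length
    category, with AL means (95% CI) and between-group tests."""
    if isinstance(manifest, pd.DataFrame):
        df = manifest.copy()
    else:
        from .io import records_to_frame

        df = records_to_frame(manifest)
    df["al_cat"] = df["axial_length"].map(al_category)
    totals = df.groupby("diagnosis")["eye_id"].count()
    rows = []
    counts = np.zeros((2, len(AL_CATEGORIES)), dtype=int)  # [healthy, glaucoma] x cat
    for ci_, cat in enumerate(AL_CATEGORIES):
        sub = df[df["al_cat"] == cat]
        row: dict = {"category": cat}
        for di, diagnosis in enumerate(("healthy", "glaucoma")):
            grp = sub[sub["diagnosis"] == diagnosis]
            n = len(grp)
            counts[di, ci_] = n
            total = int(totals.get(diagnosis, 0))
            row[f"n_{diagnosis}"] = n
            row[f"pct_{diagnosis}"] = 100.0 * n / total if total else np.nan
            if n:
                m, lo, hi = _mean_ci(grp["axial_length"].to_numpy())
                row[f"al_mean_{diagnosis}"] = m
                row[f"al_ci_low_{diagnosis}"] = lo
                row[f"al_ci_high_{diagnosis}"] = hi
            else:
                row[f"al_mean_{diagnosis}"] = np.nan
                row[f"al_ci_low_{diagnosis}"] = np.nan
                row[f"al_ci_high_{diagnosis}"] = np.nan
        # per-category proportion test: in-category vs not, by diagnosis
        table22 = np.array(
            [
                [counts[0, ci_], int(totals.get("healthy", 0)) - counts[0, ci_]],
                [counts[1, ci_], int(totals.get("glaucoma", 0)) - counts[1, ci_]],
            ]
        )
        row["p_proportion"] = _prop_test_p(table22)
        h_al = sub[sub["diagnosis"] == "healthy"]["axial_length"].to_numpy()
        g_al = sub[sub["diagnosis"] == "glaucoma"]["axial_length"].to_numpy()
        if h_al.size > 1 and g_al.size > 1:
            row["p_al"] = float(stats.ttest_ind(h_al, g_al, equal_var=False).pvalue)
        else:
            row["p_al"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows).set_index("category")
    if (counts.sum(axis=1) > 0).all() and (counts.sum(axis=0) > 0).all():
        overall = float(stats.chi2_contingency(counts, correction=False)[1])
    else:
        overall = np.nan

    demo_rows = []
    for col in ("age", "axial_length", "quality"):
        if col not in df.columns:
            continue
        h = df[df["diagnosis"] == "healthy"][col].to_numpy(dtype=float)
        g = df[df["diagnosis"] == "glaucoma"][col].to_numpy(dtype=float)
        mh, lh, uh = _mean_ci(h)
        mg, lg, ug = _mean_ci(g)
        p = float(stats.ttest_ind(h, g, equal_var=False).pvalue) if h.size > 1 and g.size > 1 else np.nan
        demo_rows.append(
            {
                "variable": col,
                "healthy_mean": mh,
                "healthy_ci_low": lh,
                "healthy_ci_high": uh,
                "glaucoma_mean": mg,
                "glaucoma_ci_low": lg,
                "glaucoma_ci_high": ug,
                "p": p,
            }
        )
    demographics = pd.DataFrame(demo_rows)
    return CohortSummary(table=table, overall_chi2_p=overall, demographics=demographics)


def _prop_test_p(table22: np.ndarray) -> float:
    """Chi-square without continuity correction; Fisher when any expected
    cell count is below 5 (the convention of small-sample 2x2 tables)."""
    if (table22 < 0).any() or table22.sum() == 0:
        return np.nan
    expected = stats.contingency.expected_freq(table22)
    if (expected < 5).any():
        return float(stats.fisher_exact(table22)[1])
    return float(stats.chi2_contingency(table22, correction=False)[1])


# ---------------------------------------------------------------------------
# The full experiment


@dataclass
class ExperimentConfig:
    k_folds: int = 5
    ae: AEConfig = field(default_factory=AEConfig)
    mrf: MRFConfig = field(default_factory=MRFConfig)
    score_domain: str = "annulus"
    n_boot: int = 1000
    seed: int = 0


@dataclass
class DiagnosticReport:
    metrics: pd.DataFrame  # per-model point metrics and CIs
    pairwise: pd.DataFrame  # model-vs-model AUROC/AUPRC deltas and Wald p
    scores: pd.DataFrame  # per-eye out-of-fold scores (eye_id, model, score, fold)
    folds: FoldAssignment
    n_boot: int
    seed: int

    def auroc_of(self, model: str) -> float:
        return float(self.metrics.loc[model, "auroc"])


def run_experiment(
    records: Sequence[EyeRecord],
    enface: dict,
    thickness: dict,
    cfg: ExperimentConfig,
) -> DiagnosticReport:
    """Train and evaluate all four models with patient-level 5-fold CV.

    For every fold the two class autoencoders are trained on the training
    split (minority class balanced by horizontal mirroring), the healthy
    intensity reference is computed from the same split, and the held-out
    eyes are scored by the four models.  Pooled out-of-fold scores feed the
    clustered-bootstrap metric machinery.  Fully deterministic in
    ``cfg.seed``.
    """
    records = list(records)
    folds = make_folds(records, k=cfg.k_folds, seed=spawn_seed(cfg.seed, "folds"))
    eye_ids = [r.eye_id for r in records]
    if len(set(eye_ids)) != len(eye_ids):
        raise ValueError("duplicate eye_id in manifest")

    score_rows = []
    tested: set = set()
    for fold in range(1, cfg.k_folds + 1):
        test_recs = [r for r in records if folds.fold_of(r.patient_id) == fold]
        train_recs = [r for r in records if folds.fold_of(r.patient_id) != fold]
        test_patients = {r.patient_id for r in test_recs}
        train_patients = {r.patient_id for r in train_recs}
        if test_patients & train_patients:
            raise LeakageError("fold partition is not patient-disjoint")

        train_images = [enface[r.eye_id].values for r in train_recs]
        train_labels = [1 if r.diagnosis == "glaucoma" else 0 for r in train_recs]
        train_pids = [r.patient_id for r in train_recs]
        aug_images, aug_labels, aug_pids, _ = augment_minority(train_images, train_labels, train_pids)
        if set(aug_pids) - train_patients:
            raise LeakageError("augmented images crossed the fold boundary")

        healthy_imgs = [im for im, l in zip(aug_images, aug_labels) if l == 0]
        healthy_pids = [p for p, l in zip(aug_pids, aug_labels) if l == 0]
        glaucoma_imgs = [im for im, l in zip(aug_images, aug_labels) if l == 1]
        glaucoma_pids = [p for p, l in zip(aug_pids, aug_labels) if l == 1]

        geo = {
            "onh_center": enface[train_recs[0].eye_id].onh_center,
            "mm_per_px": enface[train_recs[0].eye_id].mm_per_px,
        }
        ref = healthy_reference([TextureEnfaceMap(values=im, **geo) for im in healthy_imgs])

        ae_h = AEConfig(**{**_cfg_dict(cfg.ae), "seed": spawn_seed(cfg.seed, "ae", fold, "healthy")})
        ae_g = AEConfig(**{**_cfg_dict(cfg.ae), "seed": spawn_seed(cfg.seed, "ae", fold, "glaucoma")})
        h_model = train_autoencoder(healthy_imgs, ae_h, "healthy", patient_ids=healthy_pids)
        g_model = train_autoencoder(glaucoma_imgs, ae_g, "glaucoma", patient_ids=glaucoma_pids)
        fold_models = {
            "h_model": h_model,
            "g_model": g_model,
            "mrf_cfg": cfg.mrf,
            "mean_healthy_ref": ref,
            "train_patients": train_patients,
        }
        for r in test_recs:
            if r.eye_id in tested:
                raise LeakageError(f"eye {r.eye_id} tested more than once")
            tested.add(r.eye_id)
            for model in MODEL_NAMES:
                s = model_scores(
                    enface[r.eye_id],
                    thickness[r.eye_id],
                    model,
                    fold_models=fold_models,
                    patient_id=r.patient_id,
                    domain=cfg.score_domain,
                )
                score_rows.append(
                    {
                        "eye_id": r.eye_id,
                        "patient_id": r.patient_id,
                        "label": 1 if r.diagnosis == "glaucoma" else 0,
                        "model": model,
                        "score": s,
                        "fold": fold,
                    }
                )
    if tested != set(eye_ids):
        raise LeakageError("some eyes were never tested")

    scores_df = pd.DataFrame(score_rows)
    wide = scores_df.pivot(index="eye_id", columns="model", values="score").loc[eye_ids]
    labels = np.array([1 if r.diagnosis == "glaucoma" else 0 for r in records])
    pids = [r.patient_id for r in records]
    score_vectors = {m: wide[m].to_numpy() for m in MODEL_NAMES}

    boot_seed = spawn_seed(cfg.seed, "boot")
    boot_auroc = cluster_bootstrap(auroc, score_vectors, labels, pids, n_boot=cfg.n_boot, seed=boot_seed)
    boot_auprc = cluster_bootstrap(auprc, score_vectors, labels, pids, n_boot=cfg.n_boot, seed=boot_seed)

    metric_rows = []
    for m in MODEL_NAMES:
        s = score_vectors[m]
        metric_rows.append(
            {
                "model": m,
                "auroc": boot_auroc.point[m],
                "auroc_ci_low": boot_auroc.ci[m][0],
                "auroc_ci_high": boot_auroc.ci[m][1],
                "auprc": boot_auprc.point[m],
                "auprc_ci_low": boot_auprc.ci[m][0],
                "auprc_ci_high": boot_auprc.ci[m][1],
                "sens_at_spec80": sens_at_spec(s, labels, 0.80),
                "sens_at_spec95": sens_at_spec(s, labels, 0.95),
            }
        )
    metrics = pd.DataFrame(metric_rows).set_index("model")

    pair_rows = []
    for a in MODEL_NAMES:
        for b in MODEL_NAMES:
            if a >= b:
                continue
            w_roc = wald_auroc_diff(
                boot_auroc.draws[a], boot_auroc.draws[b], boot_auroc.point[a], boot_auroc.point[b]
            )
            w_prc = wald_auroc_diff(
                boot_auprc.draws[a], boot_auprc.draws[b], boot_auprc.point[a], boot_auprc.point[b]
            )
            pair_rows.append(
                {
                    "model_a": a,
                    "model_b": b,
                    "delta_auroc": w_roc.delta,
                    "wald_p_auroc": w_roc.p,
                    "delta_auprc": w_prc.delta,
                    "wald_p_auprc": w_prc.p,
                }
            )
    pairwise = pd.DataFrame(pair_rows)
    return DiagnosticReport(
        metrics=metrics,
        pairwise=pairwise,
        scores=scores_df,
        folds=folds,
        n_boot=cfg.n_boot,
        seed=cfg.seed,
    )


def _cfg_dict(cfg: AEConfig) -> dict:
    import dataclasses

    d = dataclasses.asdict(cfg)
    d["input_size"] = tuple(d["input_size"])
    return d
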