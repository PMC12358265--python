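"""The ROI-Based Glaucoma Score (GLS) and per-eye model scores.

GLS combines the extent of the segmented glaucoma-like region with the
intensity loss inside it:

    GLS = 0.5 * ROI_size / Total_area
        + 0.5 * clamp(1 - Mean_ROI / Mean_Healthy, 0, 1)

where Mean_ROI is the mean texture intensity inside the glaucoma-like
region and Mean_Healthy the mean intensity of the healthy maps in the
current training fold.  The intensity term is clamped so that ROIs brighter
than the healthy reference count as no evidence, keeping GLS in [0, 1]; an
empty ROI scores 0 by definition.  The score domain defaults to the 2-6 mm
peripapillary annulus so all four compared models look at the same region;
the full map is available as an option.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .texture import annulus_mask, annulus_mean, baseline_scores
from .types import GLSResult, ROIMap, TextureEnfaceMap, ThicknessMap

__all__ = ["healthy_reference", "gls", "model_scores", "MODEL_NAMES"]

MODEL_NAMES = ("dual_ae", "single_ae", "rnfl_global", "texture_global")


def healthy_reference(training_healthy_maps: Sequence[TextureEnfaceMap]) -> float:
    """Mean annulus texture intensity over the healthy training eyes.

    Must be computed per cross-validation fold from that fold's training
    split only, so the reference never sees a test eye.
    """
    if len(training_healthy_maps) == 0:
        raise ValueError("need at least one healthy training map")
    return float(np.mean([annulus_mean(m) for m in training_healthy_maps]))


def gls(
    roi: ROIMap,
    enface: TextureEnfaceMap,
    mean_healthy_ref: float,
    domain: str = "annulus",
) -> GLSResult:
    """Evaluate the ROI-Based Glaucoma Score for one eye."""
    if mean_healthy_ref <= 0:
        raise ValueError("mean_healthy_ref must be positive")
    if roi.labels.shape != enface.values.shape:
        raise ValueError("ROI map and enface map must be co-registered")
    if domain == "annulus":
        dom = annulus_mask(enface)
        if not dom.any():
            raise ValueError("annulus does not intersect the map")
    elif domain == "full_map":
        dom = np.ones_like(roi.mask, dtype=bool)
    else:
        raise ValueError(f"unknown domain {domain!r}")
    sel = roi.mask & dom
    n_roi = int(sel.sum())
    if n_roi == 0:
        return GLSResult(
            gls=0.0,
            roi_fraction=0.0,
            mean_roi=float(mean_healthy_ref),
            mean_healthy_ref=float(mean_healthy_ref),
            intensity_term=0.0,
        )
    roi_fraction = n_roi / int(dom.sum())
    mean_roi = float(enface.values[sel].mean())
    intensity_term = float(np.clip(1.0 - mean_roi / mean_healthy_ref, 0.0, 1.0))
    score = 0.5 * roi_fraction + 0.5 * intensity_term
    return GLSResult(
        gls=float(score),
        roi_fraction=float(roi_fraction),
        mean_roi=mean_roi,
        mean_healthy_ref=float(mean_healthy_ref),
        intensity_term=intensity_term,
    )


class LeakageError(RuntimeError):
    """An eye was scored with models trained on its own patient."""


def model_scores(
    enface: TextureEnfaceMap,
    thickness: ThicknessMap,
    mode: str,
    *,
    fold_models: Optional[dict] = None,
    patient_id: Optional[str] = None,
    domain: str = "annulus",
) -> float:
    """Per-eye diagnostic score, oriented so larger = more glaucoma-like.

    ``fold_models`` (required for the autoencoder modes) holds the fold's
    trained artefacts: ``h_model``, ``g_model``, ``mrf_cfg``,
    ``mean_healthy_ref`` and ``train_patients`` (used to refuse scoring an
    eye whose patient contributed to training).
    """
    if mode in ("dual_ae", "single_ae"):
        if fold_models is None:
            raise ValueError(f"mode {mode!r} requires fold_models")
        train_patients = fold_models.get("train_patients")
        if patient_id is not None and train_patients is not None and patient_id in train_patients:
            raise LeakageError(f"patient {patient_id} appears in the training fold")
        from .autoencoder import dual_features, error_map, upsample_to
        from .mrf import segment_eye
        from .types import ReconErrorFeature

        h_model = fold_models["h_model"]
        if mode == "dual_ae":
            feats = dual_features(h_model, fold_models["g_model"], enface.values)
        else:
            feats = ReconErrorFeature(e_healthy=error_map(h_model, enface.values))
        roi_small = segment_eye(feats, fold_models["mrf_cfg"], mode="dual" if mode == "dual_ae" else "single")
        labels = upsample_to(roi_small.labels.astype(float), enface.values.shape) > 0.5
        roi = ROIMap(
            labels=labels.astype(np.int8),
            energy=roi_small.energy,
            converged=roi_small.converged,
            degenerate=roi_small.degenerate,
        )
        return gls(roi, enface, fold_models["mean_healthy_ref"], domain=domain).gls
    if mode == "rnfl_global":
        return baseline_scores(thickness, enface)[0]
    if mode == "texture_global":
        return baseline_scores(thickness, enface)[1]
    raise ValueError(f"unknown model mode {mode!r}")
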