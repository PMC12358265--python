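"""Two-class Markov-random-field segmentation of reconstruction-error maps.

Each pixel carries a feature vector (the 2D healthy/glaucoma error pair, or
the 1D healthy error in single-autoencoder mode).  Class evidence is a
Gaussian per class, estimated per image by a deterministic two-means split;
spatial coherence comes from a Potts pairwise term on the 4- (or 8-)
neighbourhood.  The labelling minimises

    E(L) = sum_p -log N(f_p | mu_{L_p}, Sigma_{L_p})
         + beta * sum_{p~q} 1[L_p != L_q]

by iterated conditional modes (ICM) in raster order, started from the
per-pixel maximum-likelihood labelling.  ICM only ever accepts moves that
lower the local (hence global) energy, so the energy trace is
non-increasing; iteration stops when a full sweep changes no label.

Healthy eyes often contain no glaucoma-like region at all.  A degeneracy
guard declares "no ROI" when the two fitted components are closer than
``separation_tau`` (Euclidean distance between component means, in error
units): splitting pure noise produces two nearby components, whereas a true
defect produces a well-separated high-error component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .types import GLAUCOMA_LIKE, HEALTHY_LIKE, ReconErrorFeature, ROIMap

__all__ = ["MRFConfig", "ClassModel", "fit_class_models", "mrf_segment", "segment_eye"]


@dataclass
class MRFConfig:
    beta: float = 1.5
    neighborhood: int = 4
    max_icm_iters: int = 50
    separation_tau: float = 0.05
    init: str = "kmeans"  # kmeans | ml
    cov_eps: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.neighborhood not in (4, 8):
            raise ValueError("neighborhood must be 4 or 8")
        if self.max_icm_iters < 1:
            raise ValueError("max_icm_iters must be >= 1")


@dataclass
class ClassModel:
    """Per-class Gaussian evidence for the two labels."""

    means: np.ndarray  # (2, n_channels); row 0 = healthy_like
    covs: np.ndarray  # (2, n_channels, n_channels), epsilon-regularised
    degenerate: bool = False

    @property
    def n_channels(self) -> int:
        return self.means.shape[1]


def _two_means(feats: np.ndarray, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic, permutation-invariant Lloyd 2-means.

    Initialised by splitting at the median of the first feature channel
    (the healthy-autoencoder error), so results do not depend on pixel
    order — which also makes segmentation equivariant to mirroring.
    """
    assign = None
    for ch in range(feats.shape[1]):
        key = feats[:, ch]
        cand = key > np.median(key)
        if cand.any() and not cand.all():
            assign = cand
            break
    if assign is None:
        # (near-)constant image: both components collapse to the grand mean
        return np.vstack([feats.mean(0), feats.mean(0)]), np.zeros(len(feats), dtype=int)
    for _ in range(max_iter):
        c0 = feats[~assign].mean(axis=0)
        c1 = feats[assign].mean(axis=0)
        d0 = ((feats - c0) ** 2).sum(axis=1)
        d1 = ((feats - c1) ** 2).sum(axis=1)
        new_assign = d1 < d0
        if not new_assign.any() or new_assign.all():
            break  # refuse to empty a cluster; keep previous assignment
        if (new_assign == assign).all():
            assign = new_assign
            break
        assign = new_assign
    centers = np.vstack([feats[~assign].mean(axis=0), feats[assign].mean(axis=0)])
    return centers, assign.astype(int)


def fit_class_models(features: ReconErrorFeature, cfg: MRFConfig, mode: str = "dual") -> ClassModel:
    """Estimate the two-component Gaussian evidence model for one image.

    The component with the larger mean healthy-autoencoder error is labelled
    glaucoma-like.  If the component means are closer than
    ``cfg.separation_tau`` the model is flagged degenerate ("no ROI").
    """
    feats = features.stack(mode)
    if feats.shape[0] < 4:
        raise ValueError("need at least 2 pixels per tentative class")
    if not np.isfinite(feats).all():
        raise ValueError("non-finite features")
    centers, assign = _two_means(feats)
    # the glaucoma-like component is defined by its healthy-AE error, so the
    # separation that matters is the gap along that channel; the second
    # channel's spread is uninformative noise for degeneracy purposes
    gap = float(abs(centers[0, 0] - centers[1, 0]))
    if gap < cfg.separation_tau:
        d = feats.shape[1]
        mu = feats.mean(axis=0)
        cov = np.cov(feats.T).reshape(d, d) + cfg.cov_eps * np.eye(d)
        return ClassModel(means=np.vstack([mu, mu]), covs=np.stack([cov, cov]), degenerate=True)
    # orient: higher e_healthy component is glaucoma_like
    order = np.argsort(centers[:, 0])  # [healthy_like, glaucoma_like]
    means, covs = [], []
    for comp in order:
        sel = feats[assign == comp]
        d = feats.shape[1]
        mu = sel.mean(axis=0)
        if sel.shape[0] < 2:
            cov = cfg.cov_eps * np.eye(d)
        else:
            cov = np.cov(sel.T).reshape(d, d)
        cov = cov + max(cfg.cov_eps, 1e-8 * float(np.trace(cov))) * np.eye(d)
        means.append(mu)
        covs.append(cov)
    return ClassModel(means=np.vstack(means), covs=np.stack(covs))


def _neg_log_likelihoods(feats: np.ndarray, model: ClassModel) -> np.ndarray:
    """(n_pixels, 2) Gaussian negative log-likelihoods."""
    out = np.empty((feats.shape[0], 2))
    d = feats.shape[1]
    for c in range(2):
        diff = feats - model.means[c]
        cov = model.covs[c]
        chol = np.linalg.cholesky(cov)
        sol = np.linalg.solve(chol, diff.T)
        maha = (sol**2).sum(axis=0)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        out[:, c] = 0.5 * (maha + logdet + d * np.log(2 * np.pi))
    return out


def mrf_energy(labels: np.ndarray, nll: np.ndarray, beta: float, neighborhood: int = 4) -> float:
    """Total MRF energy of a labelling (data + Potts terms)."""
    h, w = labels.shape
    e = float(nll[np.arange(h * w), labels.ravel()].sum())
    diff = 0
    diff += int((labels[:, 1:] != labels[:, :-1]).sum())
    diff += int((labels[1:, :] != labels[:-1, :]).sum())
    if neighborhood == 8:
        diff += int((labels[1:, 1:] != labels[:-1, :-1]).sum())
        diff += int((labels[1:, :-1] != labels[:-1, 1:]).sum())
    return e + beta * diff


def mrf_segment(
    features: ReconErrorFeature,
    model: ClassModel,
    cfg: MRFConfig,
    mode: str = "dual",
) -> ROIMap:
    """ICM minimisation from the per-pixel maximum-likelihood labelling.

    Ties in the per-pixel update resolve to healthy-like (conservative
    toward no disease).  A degenerate model returns the all-healthy map.
    """
    h, w = features.shape
    if model.degenerate:
        labels = np.full((h, w), HEALTHY_LIKE, dtype=np.int8)
        return ROIMap(labels=labels, energy=0.0, converged=True, degenerate=True)
    feats = features.stack(mode)
    if not np.isfinite(feats).all():
        raise ValueError("non-finite features")
    nll = _neg_log_likelihoods(feats, model)
    # ML init; ties -> healthy_like
    labels = np.where(nll[:, GLAUCOMA_LIKE] < nll[:, HEALTHY_LIKE], GLAUCOMA_LIKE, HEALTHY_LIKE)
    labels = labels.reshape(h, w).astype(np.int8)
    if cfg.beta == 0.0:
        energy = mrf_energy(labels, nll, 0.0, cfg.neighborhood)
        return ROIMap(labels=labels, energy=energy, converged=True)

    if cfg.neighborhood == 4:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1)]
    nll_grid = nll.reshape(h, w, 2)
    energy = mrf_energy(labels, nll, cfg.beta, cfg.neighborhood)
    energies = [energy]
    converged = False
    # plain-python raster sweeps (scalar numpy indexing is too slow here)
    nll_h = nll_grid[:, :, HEALTHY_LIKE].tolist()
    nll_g = nll_grid[:, :, GLAUCOMA_LIKE].tolist()
    lab = labels.tolist()
    beta = float(cfg.beta)
    glab = GLAUCOMA_LIKE
    for _ in range(cfg.max_icm_iters):
        changed = 0
        for i in range(h):
            row = lab[i]
            for j in range(w):
                n_g = 0
                n_tot = 0
                for di, dj in offsets:
                    ii, jj = i + di, j + dj
                    if 0 <= ii < h and 0 <= jj < w:
                        n_tot += 1
                        if lab[ii][jj] == glab:
                            n_g += 1
                cost_h = nll_h[i][j] + beta * n_g
                cost_g = nll_g[i][j] + beta * (n_tot - n_g)
                new = glab if cost_g < cost_h else HEALTHY_LIKE
                if new != row[j]:
                    row[j] = new
                    changed += 1
        labels = np.asarray(lab, dtype=np.int8)
        energy = mrf_energy(labels, nll, cfg.beta, cfg.neighborhood)
        if energy > energies[-1] + 1e-9:
            raise AssertionError("ICM energy increased — internal error")
        energies.append(energy)
        if changed == 0:
            converged = True
            break
    return ROIMap(labels=labels, energy=float(energies[-1]), converged=converged)


def segment_eye(features: ReconErrorFeature, cfg: MRFConfig, mode: str = "dual") -> ROIMap:
    """Fit the per-image class models and run the MRF segmentation."""
    model = fit_class_models(features, cfg, mode=mode)
    return mrf_segment(features, model, cfg, mode=mode)
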