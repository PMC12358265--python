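"""Slab-based texture enface construction and the two global baselines.

The texture descriptor follows the SALSA-Texture recipe: a 70 um slab below
the inner limiting membrane is lifted out of the volume; within each B-scan
a difference-of-Gaussians (DoG) band-pass isolates local granularity, the
response is z-normalised over a 9x9 neighbourhood (with an epsilon guard
proportional to the B-scan-wide response scale, which makes the descriptor
exactly invariant to global affine intensity changes), and the magnitude of
the normalised response is quantised into equal-frequency homogeneous bins
(H-bins) over the B-scan, mapped to [0, 1].  The enface value of an A-scan
is the mean descriptor value across the slab depth: bright pixels mark
strong local texture.

Quantising the response magnitude (rather than the signed response) makes
the descriptor a monotone measure of local texture energy, which is what
the enface rendering of nerve-fibre-bundle reflectance needs; the signed
response is symmetric about zero and would average to mid-grey everywhere.

The global baselines average RNFL thickness and texture intensity over the
2-6 mm peripapillary annulus (between circles of 2 mm and 6 mm diameter
centred on the ONH).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import OCTVolume, TextureEnfaceMap, ThicknessMap

__all__ = [
    "TextureParams",
    "extract_slab",
    "texture_descriptor",
    "build_enface",
    "annulus_mean",
    "annulus_mask",
    "baseline_scores",
]


@dataclass
class TextureParams:
    slab_um: float = 70.0
    nbhd: int = 9
    sigma1: float = 1.0
    sigma2: float = 2.0
    h_bins: int = 8
    eps_rel: float = 1.0  # epsilon guard as a fraction of the B-scan DoG scale

    def __post_init__(self) -> None:
        if self.slab_um <= 0:
            raise ValueError("slab_um must be positive")
        if self.nbhd % 2 != 1 or self.nbhd < 3:
            raise ValueError("nbhd must be an odd integer >= 3")
        if not (self.sigma2 > self.sigma1 > 0):
            raise ValueError("need sigma2 > sigma1 > 0")
        if self.h_bins < 2:
            raise ValueError("h_bins must be >= 2")


def extract_slab(vol: OCTVolume, slab_um: float = 70.0) -> tuple[np.ndarray, np.ndarray]:
    """Lift the sub-ILM slab out of the volume.

    Returns ``(slab, clipped)`` where ``slab[b, a, :]`` holds the
    ``ceil(slab_um / axial_res)`` depth samples starting at the ILM and
    ``clipped`` flags A-scans whose slab ran off the bottom of the volume
    (padded by edge replication).
    """
    if slab_um <= 0:
        raise ValueError("slab_um must be positive")
    n_px = int(np.ceil(slab_um / vol.axial_res_um))
    if n_px < 1:
        raise ValueError("slab thinner than one depth pixel")
    n_depth = vol.intensities.shape[2]
    idx = vol.ilm[:, :, None] + np.arange(n_px)[None, None, :]
    clipped = (idx >= n_depth).any(axis=2)
    idx = np.clip(idx, 0, n_depth - 1)
    slab = np.take_along_axis(vol.intensities, idx, axis=2)
    return slab, clipped


def texture_descriptor(
    slab_bscan: np.ndarray,
    nbhd: int = 9,
    sigma1: float = 1.0,
    sigma2: float = 2.0,
    h_bins: int = 8,
    eps_rel: float = 1.0,
) -> np.ndarray:
    """SALSA-style descriptor for one B-scan slab image.

    Output values lie on the grid ``{k / (h_bins - 1)}``.  A constant image
    maps to a single bin.  Invariant to global affine intensity maps of the
    input (the DoG is linear and the normalisations are scale-relative).
    """
    TextureParams(nbhd=nbhd, sigma1=sigma1, sigma2=sigma2, h_bins=h_bins, eps_rel=eps_rel)
    t = normalized_response(slab_bscan, nbhd=nbhd, sigma1=sigma1, sigma2=sigma2, eps_rel=eps_rel)
    return hbin_quantize(t, h_bins)


def normalized_response(
    slab_bscan: np.ndarray,
    nbhd: int = 9,
    sigma1: float = 1.0,
    sigma2: float = 2.0,
    eps_rel: float = 1.0,
) -> np.ndarray:
    """Magnitude of the locally normalised DoG response of one B-scan."""
    x = np.asarray(slab_bscan, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("slab_bscan must be 2D")
    if nbhd > min(x.shape):
        raise ValueError("neighbourhood window larger than the image")
    dog = ndimage.gaussian_filter(x, sigma1, mode="reflect") - ndimage.gaussian_filter(
        x, sigma2, mode="reflect"
    )
    mu = ndimage.uniform_filter(dog, size=nbhd, mode="reflect")
    sq = ndimage.uniform_filter(dog**2, size=nbhd, mode="reflect")
    var = np.clip(sq - mu**2, 0.0, None)
    sigma = np.sqrt(var)
    eps = eps_rel * float(dog.std()) + 1e-12
    return np.abs((dog - mu) / (sigma + eps))


def hbin_quantize(t: np.ndarray, h_bins: int, edges: np.ndarray | None = None) -> np.ndarray:
    """Equal-frequency (homogeneous-bin) quantisation to the grid
    ``{k / (h_bins - 1)}``; ``edges`` may be supplied to share a
    quantisation across B-scans."""
    if edges is None:
        edges = np.quantile(t, np.arange(1, h_bins) / h_bins)
    bins = np.searchsorted(edges, t, side="left")
    return bins / (h_bins - 1)


def build_enface(vol: OCTVolume, params: TextureParams | None = None) -> TextureEnfaceMap:
    """Texture enface map: per A-scan mean of the descriptor over the slab.

    The H-bin quantisation uses equal-frequency edges pooled over the whole
    slab volume (rather than per B-scan), so between-B-scan differences in
    texture strength survive into the enface map.
    """
    params = params or TextureParams()
    slab, _ = extract_slab(vol, params.slab_um)
    n_b, n_a, _ = slab.shape
    responses = np.empty_like(slab)
    for b in range(n_b):
        responses[b] = normalized_response(
            slab[b],
            nbhd=params.nbhd,
            sigma1=params.sigma1,
            sigma2=params.sigma2,
            eps_rel=params.eps_rel,
        )
    edges = np.quantile(responses, np.arange(1, params.h_bins) / params.h_bins)
    values = np.empty((n_b, n_a))
    for b in range(n_b):
        values[b] = hbin_quantize(responses[b], params.h_bins, edges=edges).mean(axis=1)
    return TextureEnfaceMap(
        values=values,
        onh_center=((n_b - 1) / 2.0, (n_a - 1) / 2.0),
        mm_per_px=(vol.mm_extent / n_b, vol.mm_extent / n_a),
    )


def annulus_mask(
    m: TextureEnfaceMap | ThicknessMap, d_inner_mm: float = 2.0, d_outer_mm: float = 6.0
) -> np.ndarray:
    """Pixels whose centre lies in the [d_inner/2, d_outer/2] mm ring."""
    h, w = m.values.shape
    cr, cc = m.onh_center
    rows = (np.arange(h) - cr)[:, None] * m.mm_per_px[0]
    cols = (np.arange(w) - cc)[None, :] * m.mm_per_px[1]
    r = np.hypot(rows, cols)
    return (r >= d_inner_mm / 2.0) & (r <= d_outer_mm / 2.0)


def annulus_mean(
    m: TextureEnfaceMap | ThicknessMap, d_inner_mm: float = 2.0, d_outer_mm: float = 6.0
) -> float:
    """Mean map value over the peripapillary annulus (centre-point rule)."""
    mask = annulus_mask(m, d_inner_mm, d_outer_mm)
    if not mask.any():
        raise ValueError("annulus does not intersect the map")
    return float(m.values[mask].mean())


def baseline_scores(
    thickness: ThicknessMap, enface: TextureEnfaceMap, d_inner_mm: float = 2.0, d_outer_mm: float = 6.0
) -> tuple[float, float]:
    """Global-baseline diagnostic scores (larger = more glaucoma-like):
    negated annulus means of RNFL thickness and texture intensity."""
    return (
        -annulus_mean(thickness, d_inner_mm, d_outer_mm),
        -annulus_mean(enface, d_inner_mm, d_outer_mm),
    )
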