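"""Phantom cohort generator.

Emulates the statistical structure of a two-group optic-nerve-head (ONH)
imaging study: healthy eyes carry a smooth, bright superior/inferior arcuate
nerve-fibre-bundle pattern around a central disc; glaucomatous eyes
additionally carry one or more wedge-shaped angular defects anchored at the
disc margin, in which intensity is multiplied by ``1 - depth``.  Two eyes of
the same patient share a latent intensity offset (intra-patient correlation),
global intensity declines linearly with age, and axial length is drawn
per-diagnosis so the glaucoma group is longer on average — the main nuisance
covariates of the clinical problem.

The generator emits, per eye: a texture enface map, a matched RNFL thickness
map (an affine transform of the same latent pattern plus independent noise),
the ground-truth defect depth field, and optionally a layered OCT volume
whose 70 um sub-ILM slab carries the eye's pattern as multiplicative
speckle texture, for exercising the slab/texture-descriptor path.

All randomness derives from ``PhantomConfig.seed`` through named substreams
(see ``glaucroi._rng``): stream ("cohort", patient_index, eye_index, stage)
for eye-level draws, so the cohort is byte-for-byte reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from ._rng import substream
from .io import write_manifest, write_map
from .types import EyeRecord, OCTVolume, TextureEnfaceMap, ThicknessMap

__all__ = [
    "PhantomConfig",
    "EyeTruth",
    "PhantomCohort",
    "generate_cohort",
    "generate_volume",
]


@dataclass
class PhantomConfig:
    """Knobs of the phantom cohort.

    Intensities are on a [0, 1] scale; lateral geometry in millimetres with
    the ONH fixed at the map centre and a 0.9 mm disc radius.
    """

    n_patients_healthy: int = 63
    n_patients_glaucoma: int = 62
    p_both_eyes: float = 0.6
    map_height: int = 64
    map_width: int = 64
    mm_extent: float = 6.0
    defect_count_range: tuple[int, int] = (1, 3)
    defect_angle_deg_range: tuple[float, float] = (20.0, 60.0)
    defect_depth_range: tuple[float, float] = (0.5, 0.7)
    age_slope: float = 0.002  # intensity units lost per year past 50
    al_mean: dict = field(default_factory=lambda: {"healthy": 24.9, "glaucoma": 25.6})
    al_sd: dict = field(default_factory=lambda: {"healthy": 1.25, "glaucoma": 1.05})
    noise_sd: float = 0.05
    intra_patient_corr: float = 0.5
    seed: int = 0
    # secondary knobs (rarely touched)
    disc_radius_mm: float = 0.9
    patient_offset_sd: float = 0.03
    thickness_offset_um: float = 30.0
    thickness_gain_um: float = 110.0
    thickness_noise_sd_um: float = 4.0

    def __post_init__(self) -> None:
        if self.n_patients_healthy < 1 or self.n_patients_glaucoma < 1:
            raise ValueError("need at least one patient per group")
        if not 0.0 <= self.p_both_eyes <= 1.0:
            raise ValueError("p_both_eyes must be in [0, 1]")
        if not 0.0 <= self.intra_patient_corr <= 1.0:
            raise ValueError("intra_patient_corr must be in [0, 1]")
        if self.map_height < 16 or self.map_width < 16:
            raise ValueError("map dimensions must be >= 16 pixels")
        for name in ("defect_count_range", "defect_angle_deg_range", "defect_depth_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is empty")
        lo, hi = self.defect_depth_range
        if lo < 0 or hi > 1:
            raise ValueError("defect depths must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class EyeTruth:
    """Generator ground truth for one eye."""

    pattern: np.ndarray  # noiseless post-defect intensity pattern
    defect_mask: np.ndarray  # bool, union of wedge defects
    depth_field: np.ndarray  # per-pixel fractional intensity loss
    mean_defect_depth: float  # oracle severity score


@dataclass
class PhantomCohort:
    config: PhantomConfig
    records: list[EyeRecord]
    enface: dict  # eye_id -> TextureEnfaceMap
    thickness: dict  # eye_id -> ThicknessMap
    truth: dict  # eye_id -> EyeTruth

    def labels(self) -> np.ndarray:
        return np.array([1 if r.diagnosis == "glaucoma" else 0 for r in self.records])


def _polar_grids(cfg: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """(radius_mm, angle_deg) about the ONH centre; angle 0 = temporal
    horizontal, +90 = superior."""
    h, w = cfg.map_height, cfg.map_width
    mm_row = cfg.mm_extent / h
    mm_col = cfg.mm_extent / w
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    rows = (np.arange(h) - cr)[:, None] * mm_row
    cols = (np.arange(w) - cc)[None, :] * mm_col
    r = np.hypot(rows, cols)
    theta = np.degrees(np.arctan2(-rows, cols))  # image rows grow downward
    return r, theta


def _ang_dist(theta: np.ndarray, center: float) -> np.ndarray:
    d = np.abs(theta - center) % 360.0
    return np.minimum(d, 360.0 - d)


def healthy_pattern(cfg: PhantomConfig) -> np.ndarray:
    """Noiseless healthy texture pattern: dim disc, bright arcuate bundles
    peaking superiorly/inferiorly at ~1.5 mm from the centre, fading
    gradually toward the periphery so intensities are graded rather than
    piecewise-flat."""
    r, theta = _polar_grids(cfg)
    bundles = np.exp(-(_ang_dist(theta, 90.0) ** 2) / (2 * 45.0**2)) + np.exp(
        -(_ang_dist(theta, -90.0) ** 2) / (2 * 45.0**2)
    )
    radial = np.exp(-((r - 1.5) ** 2) / (2 * 1.6**2))
    pattern = 0.22 + 0.58 * bundles * radial
    # smooth disc cup
    disc = 1.0 / (1.0 + np.exp(-(r - cfg.disc_radius_mm) / 0.15))
    pattern = 0.12 + (pattern - 0.12) * disc
    return pattern


def _draw_defects(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-pixel fractional intensity-loss field from wedge defects."""
    r, theta = _polar_grids(cfg)
    depth_field = np.zeros((cfg.map_height, cfg.map_width))
    lo, hi = cfg.defect_count_range
    n_defects = int(rng.integers(lo, hi + 1))
    for _ in range(n_defects):
        # anchor in the arcuate zones where bundle loss occurs
        hemi = 1.0 if rng.random() < 0.5 else -1.0
        center = hemi * rng.uniform(30.0, 150.0)
        width = rng.uniform(*cfg.defect_angle_deg_range)
        depth = rng.uniform(*cfg.defect_depth_range)
        wedge = (_ang_dist(theta, center) <= width / 2.0) & (r >= cfg.disc_radius_mm)
        soft = ndimage.gaussian_filter(wedge.astype(float), sigma=0.7)
        # combine multiplicatively: overlapping wedges deepen the loss
        depth_field = 1.0 - (1.0 - depth_field) * (1.0 - depth * soft)
    return depth_field


def _map_geometry(cfg: PhantomConfig) -> dict:
    return {
        "onh_center": ((cfg.map_height - 1) / 2.0, (cfg.map_width - 1) / 2.0),
        "mm_per_px": (cfg.mm_extent / cfg.map_height, cfg.mm_extent / cfg.map_width),
    }


def _patient_counts(cfg: PhantomConfig) -> dict:
    return {"healthy": cfg.n_patients_healthy, "glaucoma": cfg.n_patients_glaucoma}


def generate_cohort(cfg: PhantomConfig, out_dir: str | Path | None = None) -> PhantomCohort:
    """Generate the full phantom cohort.

    The number of two-eye patients per group is the deterministic
    ``round(p_both_eyes * n_patients)`` (which patients get both eyes is
    random), so cohort size is reproducible at fixed config.  If ``out_dir``
    is given, per-eye enface/thickness maps are written as NPY + JSON
    sidecars and a ``manifest.csv`` is written alongside; ``image_path`` in
    the returned records then points at the enface file.
    """
    base = healthy_pattern(cfg)
    records: list[EyeRecord] = []
    enface: dict = {}
    thickness: dict = {}
    truth: dict = {}

    out_path: Optional[Path] = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        try:
            out_path.mkdir(parents=True, exist_ok=True)
        except OSError as exc:  # pragma: no cover - environment dependent
            raise IOError(f"cannot create output directory {out_path}: {exc}") from exc

    pidx = 0
    for diagnosis in ("healthy", "glaucoma"):
        n_pat = _patient_counts(cfg)[diagnosis]
        rng_group = substream(cfg.seed, "cohort", diagnosis)
        n_both = int(round(cfg.p_both_eyes * n_pat))
        both = np.zeros(n_pat, dtype=bool)
        both[rng_group.permutation(n_pat)[:n_both]] = True
        for j in range(n_pat):
            pidx += 1
            patient_id = f"P{pidx:04d}"
            rng_pat = substream(cfg.seed, "patient", pidx)
            # same age law for both groups: at zero defect depth the two
            # groups' maps must be identically distributed (a pure null)
            age = float(np.clip(rng_pat.normal(49.5, 8.0), 30, 70))
            z_pat = rng_pat.normal()
            lateralities = ("OD", "OS") if both[j] else (("OD",) if rng_pat.random() < 0.5 else ("OS",))
            for lat in lateralities:
                lc = 0 if lat == "OD" else 1
                rng_cov = substream(cfg.seed, "eyecov", pidx, lc)
                rng_noise = substream(cfg.seed, "noise", pidx, lc)
                al = float(
                    np.clip(
                        rng_cov.normal(cfg.al_mean[diagnosis], cfg.al_sd[diagnosis]),
                        22.0,
                        28.0,
                    )
                )
                quality = float(np.clip(rng_cov.normal(80.0, 8.0), 40.0, 100.0))
                eye_id = f"{patient_id}-{lat}"
                record = EyeRecord(
                    patient_id=patient_id,
                    eye_id=eye_id,
                    laterality=lat,
                    diagnosis=diagnosis,
                    age=age,
                    axial_length=al,
                    quality=quality,
                )
                # latent intensity offset shared within a patient
                rho = cfg.intra_patient_corr
                offset = cfg.patient_offset_sd * (
                    np.sqrt(rho) * z_pat + np.sqrt(1.0 - rho) * rng_cov.normal()
                )
                if diagnosis == "glaucoma":
                    depth_field = _draw_defects(cfg, substream(cfg.seed, "defect", pidx, lc))
                else:
                    depth_field = np.zeros_like(base)
                pattern = base * (1.0 - depth_field)
                intensity = (
                    pattern
                    + offset
                    - cfg.age_slope * (age - 50.0)
                    + rng_noise.normal(0.0, cfg.noise_sd, size=base.shape)
                )
                intensity = np.clip(intensity, 0.0, 1.0)
                geo = _map_geometry(cfg)
                enface[eye_id] = TextureEnfaceMap(values=intensity, **geo)
                thick = (
                    cfg.thickness_offset_um
                    + cfg.thickness_gain_um * pattern
                    + rng_noise.normal(0.0, cfg.thickness_noise_sd_um, size=base.shape)
                )
                thickness[eye_id] = ThicknessMap(values=np.clip(thick, 0.0, None), **geo)
                truth[eye_id] = EyeTruth(
                    pattern=pattern,
                    defect_mask=depth_field > 0.05,
                    depth_field=depth_field,
                    mean_defect_depth=float(depth_field.mean()),
                )
                if out_path is not None:
                    p = write_map(enface[eye_id], out_path / f"{eye_id}_enface.npy")
                    write_map(thickness[eye_id], out_path / f"{eye_id}_thickness.npy")
                    record.image_path = str(p)
                records.append(record)

    if out_path is not None:
        write_manifest(records, out_path / "manifest.csv")
    return PhantomCohort(config=cfg, records=records, enface=enface, thickness=thickness, truth=truth)


def generate_volume(
    record: EyeRecord,
    cfg: PhantomConfig,
    pattern: np.ndarray | None = None,
    n_depth: int = 64,
    axial_res_um: float = 2.6,
    ilm_tilt_px_per_mm_al: float = 2.0,
) -> OCTVolume:
    """Build a layered OCT volume whose sub-ILM slab carries the eye's
    texture pattern.

    The slab signal is a lamellar reflectance texture — a depth-periodic
    banding aligned to the ILM plus fine speckle — whose local modulation
    amplitude scales with the eye's 2D pattern and decays with depth below
    the ILM.  Texture amplitude, not mean brightness, carries the pattern:
    this is what a contrast-normalised texture descriptor reads out.  Above
    the ILM lies dark vitreous, below the slab a dim uniform tissue band.
    The ILM is a smooth bowl with a lateral tilt proportional to
    ``axial_length - 24.5`` (longer, more myopic eyes are more tilted).

    ``pattern`` defaults to the eye's ground-truth noiseless pattern,
    re-derived deterministically from the record ids and ``cfg.seed``.
    """
    if pattern is None:
        pattern = _rederive_pattern(record, cfg)
    h, w = pattern.shape
    rng = substream(cfg.seed, "volume", record.eye_id)

    slab_px = int(np.ceil(70.0 / axial_res_um))
    cols = (np.arange(w) - (w - 1) / 2.0) / w  # -0.5..0.5
    rows = (np.arange(h) - (h - 1) / 2.0) / h
    bowl = 4.0 * (rows[:, None] ** 2 + cols[None, :] ** 2)
    tilt = ilm_tilt_px_per_mm_al * max(record.axial_length - 24.5, 0.0)
    ilm = 6.0 + bowl + tilt * (cols[None, :] + 0.5) * np.ones((h, 1))
    ilm = np.clip(np.round(ilm), 0, max(n_depth - slab_px - 2, 0)).astype(int)

    depth_idx = np.arange(n_depth)[None, None, :]
    rel = depth_idx - ilm[:, :, None]
    speckle = rng.normal(0.0, 1.0, size=(h, w, n_depth))
    speckle = ndimage.gaussian_filter(speckle, sigma=(0.8, 0.8, 0.8))
    speckle /= max(speckle.std(), 1e-12)
    lamellae = np.sin(2.0 * np.pi * rel / 5.0)  # ILM-aligned banding
    in_slab = (rel >= 0) & (rel < slab_px)
    decay = np.exp(-np.clip(rel, 0, None) / (2.5 * slab_px))
    amp = pattern[:, :, None] * decay
    vol = np.full((h, w, n_depth), 0.05)
    vol = np.where(in_slab, 0.5 + amp * (0.55 * lamellae + 0.02 * speckle), vol)
    below = rel >= slab_px
    vol = np.where(below, 0.25 + 0.04 * speckle, vol)
    vol = np.clip(vol, 0.0, 1.5)
    return OCTVolume(intensities=vol, ilm=ilm, axial_res_um=axial_res_um, mm_extent=cfg.mm_extent)


def _rederive_pattern(record: EyeRecord, cfg: PhantomConfig) -> np.ndarray:
    """Re-derive the eye's noiseless pattern from its ids (determinism
    contract of the cohort substreams)."""
    pidx = int(record.patient_id.lstrip("P"))
    base = healthy_pattern(cfg)
    lc = 0 if record.laterality == "OD" else 1
    if record.diagnosis == "glaucoma":
        depth_field = _draw_defects(cfg, substream(cfg.seed, "defect", pidx, lc))
    else:
        depth_field = np.zeros_like(base)
    return base * (1.0 - depth_field)
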