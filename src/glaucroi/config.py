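"""YAML run configuration.

A single nested document configures every stage; unknown keys are rejected
so typos fail fast.  The root seed is expanded deterministically into
per-stage substreams (see ``glaucroi._rng``), making a whole pipeline run
reproducible from one integer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .autoencoder import AEConfig
from .evaluation import ExperimentConfig
from .mrf import MRFConfig
from .synthetic import PhantomConfig
from .texture import TextureParams


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomSection(_Strict):
    n_patients_healthy: int = 63
    n_patients_glaucoma: int = 62
    p_both_eyes: float = 0.6
    map_height: int = 64
    map_width: int = 64
    mm_extent: float = 6.0
    defect_count_range: tuple[int, int] = (1, 3)
    defect_angle_deg_range: tuple[float, float] = (20.0, 60.0)
    defect_depth_range: tuple[float, float] = (0.5, 0.7)
    age_slope: float = 0.002
    noise_sd: float = 0.05
    intra_patient_corr: float = 0.5


class TextureSection(_Strict):
    slab_um: float = 70.0
    nbhd: int = 9
    sigma1: float = 1.0
    sigma2: float = 2.0
    h_bins: int = 8


class AESection(_Strict):
    input_height: int = 128
    input_width: int = 128
    hidden: int = 256
    bottleneck: int = 64
    learning_rate: float = 1e-3
    batch_size: int = 50
    epochs: int = 150
    smooth_error: bool = True


class MRFSection(_Strict):
    beta: float = 1.5
    neighborhood: int = 4
    max_icm_iters: int = 50
    separation_tau: float = 0.03


class ScoringSection(_Strict):
    domain: str = "annulus"


class EvalSection(_Strict):
    k_folds: int = 5
    n_boot: int = 1000


class RunConfig(_Strict):
    phantom: PhantomSection = Field(default_factory=PhantomSection)
    texture: TextureSection = Field(default_factory=TextureSection)
    ae: AESection = Field(default_factory=AESection)
    mrf: MRFSection = Field(default_factory=MRFSection)
    scoring: ScoringSection = Field(default_factory=ScoringSection)
    eval: EvalSection = Field(default_factory=EvalSection)
    seed: int = 0
    out_dir: str = "glaucroi_out"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    # bridges into the library dataclasses -----------------------------------

    def phantom_config(self, seed: int | None = None) -> PhantomConfig:
        return PhantomConfig(**self.phantom.model_dump(), seed=self.seed if seed is None else seed)

    def texture_params(self) -> TextureParams:
        return TextureParams(**self.texture.model_dump())

    def ae_config(self, seed: int = 0) -> AEConfig:
        s = self.ae.model_dump()
        return AEConfig(
            input_size=(s.pop("input_height"), s.pop("input_width")), seed=seed, **s
        )

    def mrf_config(self) -> MRFConfig:
        return MRFConfig(**self.mrf.model_dump())

    def experiment_config(self, ae_input: tuple[int, int] | None = None) -> ExperimentConfig:
        ae = self.ae_config()
        if ae_input is not None:
            ae = dataclasses.replace(ae, input_size=tuple(ae_input))
        return ExperimentConfig(
            k_folds=self.eval.k_folds,
            ae=ae,
            mrf=self.mrf_config(),
            score_domain=self.scoring.domain,
            n_boot=self.eval.n_boot,
            seed=self.seed,
        )
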