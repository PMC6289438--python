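"""Declarative study configuration for the end-to-end pipeline.

A :class:`StudyConfig` describes one synthetic study: the cohort, the
monthly window, trial-recording settings, gait-waveform profiles per
phenotype, the generative local-level parameters per fitted outcome,
covariate settings, the MRI simulation plan and the MCMC settings.  Two
configurations ship with the package: ``study_defaults`` (the study
design: 5 dystrophic + 6 wild-type dogs, months 2-12, 20 ms sampling,
10 s standing window, four 15-m passes) and ``strong_effect`` (larger
group separation and covariate effects, used for planted-effect checks).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from .trend import MCMCSettings


@dataclass
class DogSpec:
    id: str
    phenotype: str
    sex: str


@dataclass
class TrialSettings:
    duration_s: float = 14.0
    standing_s: float = 10.0
    sampling_interval_ms: float = 20.0
    passes_per_session: int = 4


@dataclass
class GaitSettings:
    """Canonical waveform amplitudes; dystrophic profiles decay with month."""

    stride_frequency: dict = field(
        default_factory=lambda: {"WT": 2.8, "DYS": 2.2}
    )
    wt_axis_amplitudes: dict = field(
        default_factory=lambda: {
            "thoracic": [2.0, 0.8, 1.2],
            "lumbar": [1.8, 0.9, 1.4],
        }
    )
    wt_gyro_amplitudes: dict = field(
        default_factory=lambda: {
            "thoracic": [150.0, 300.0, 120.0],
            "lumbar": [140.0, 160.0, 200.0],
        }
    )
    dys_factor_start: float = 0.6   # DYS amplitude multiplier at first month
    dys_factor_end: float = 0.25    # ... decaying linearly to the last month
    noise_sd: float = 0.05          # G
    dog_factor_range_wt: tuple = (0.85, 1.15)
    dog_factor_range_dys: tuple = (0.6, 1.0)


@dataclass
class OutcomeSpec:
    """Generative local-level parameters for one fitted outcome.

    ``anchors`` maps phenotype -> region -> {month: natural-scale value};
    the true trend m_t interpolates the anchors linearly on the
    transformed scale.  ``betas`` maps covariate kind to the true
    coefficient on the standardized covariate.
    """

    name: str
    transform: str
    sigma0_sq: float
    sigma1_sq: float
    anchors: dict
    betas: dict = field(default_factory=dict)


@dataclass
class CovariateSettings:
    kinds: list = field(
        default_factory=lambda: ["clinical_score", "locomotor_activity"]
    )
    severity: float = 0.7


@dataclass
class MRISettings:
    group_shift: float = 30.0    # added to dystrophic intensities
    #: per-muscle coupling sign/strength between Ave SNR and gait AM
    coupling: dict = field(
        default_factory=lambda: {
            "TC": -1.0, "EDL": -0.8, "FDL": 0.3, "FHL": 0.3,
            "GM": -0.5, "GL": 0.8, "FDS": 0.8,
        }
    )
    coupling_scale: float = 8.0  # intensity units per SD of AM
    noise_sd: float = 2.0
    sd_air: float = 4.0
    n_rois_per_side: int = 3


@dataclass
class StudyConfig:
    name: str = "study_defaults"
    seed: int = 0
    dogs: list = field(default_factory=list)       # list[DogSpec]
    months: list = field(default_factory=lambda: list(range(2, 13)))
    regions: list = field(default_factory=lambda: ["thoracic", "lumbar"])
    trial: TrialSettings = field(default_factory=TrialSettings)
    gait: GaitSettings = field(default_factory=GaitSettings)
    outcomes: list = field(default_factory=list)   # list[OutcomeSpec]
    covariates: CovariateSettings = field(default_factory=CovariateSettings)
    mri: MRISettings = field(default_factory=MRISettings)
    mcmc: MCMCSettings = field(
        default_factory=lambda: MCMCSettings(
            chains=2, iterations=4000, burn_in=2000, thin=1, seed=0
        )
    )
    apply_missing_pattern: bool = True
    write_trials: bool = False
    standardize_covariate: bool = True

    def __post_init__(self) -> None:
        if not self.dogs:
            from .synth import COHORT
            self.dogs = [DogSpec(*d) for d in COHORT]
        self.dogs = [
            d if isinstance(d, DogSpec) else DogSpec(**d) for d in self.dogs
        ]
        ids = [d.id for d in self.dogs]
        if len(ids) != len(set(ids)):
            raise ValueError("dog ids must be unique")
        m = self.months
        if len(m) == 2 and m[1] - m[0] > 1:
            self.months = list(range(m[0], m[1] + 1))
        if any(b - a != 1 for a, b in zip(self.months, self.months[1:])):
            raise ValueError("months must be contiguous")
        if not self.outcomes:
            self.outcomes = [_default_am_outcome()]
        self.outcomes = [
            o if isinstance(o, OutcomeSpec) else OutcomeSpec(**o)
            for o in self.outcomes
        ]
        if not isinstance(self.trial, TrialSettings):
            self.trial = TrialSettings(**self.trial)
        if not isinstance(self.gait, GaitSettings):
            self.gait = GaitSettings(**self.gait)
        if not isinstance(self.covariates, CovariateSettings):
            self.covariates = CovariateSettings(**self.covariates)
        if not isinstance(self.mri, MRISettings):
            self.mri = MRISettings(**self.mri)
        if not isinstance(self.mcmc, MCMCSettings):
            self.mcmc = MCMCSettings(**self.mcmc)
        for o in self.outcomes:
            for phen, by_region in o.anchors.items():
                for region in by_region:
                    if region not in self.regions:
                        raise ValueError(
                            f"outcome {o.name}: anchors reference unknown "
                            f"region {region!r}"
                        )

    @property
    def dog_ids(self) -> list[str]:
        return [d.id for d in self.dogs]

    def dogs_of(self, phenotype: str) -> list[str]:
        return [d.id for d in self.dogs if d.phenotype == phenotype]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _default_am_outcome() -> OutcomeSpec:
    """AM trends: wild-type rises to a mid-study peak (month 4 thoracic,
    7-8 lumbar); dystrophic starts lower and declines throughout."""
    return OutcomeSpec(
        name="AM",
        transform="log",
        sigma0_sq=0.04,
        sigma1_sq=0.01,
        anchors={
            "WT": {
                "thoracic": {2: 1.2, 4: 2.0, 12: 1.5},
                "lumbar": {2: 1.0, 7: 1.9, 12: 1.6},
            },
            "DYS": {
                "thoracic": {2: 0.55, 12: 0.25},
                "lumbar": {2: 0.85, 12: 0.3},
            },
        },
        betas={"clinical_score": -0.3, "locomotor_activity": 0.3},
    )


def load_packaged_config(name: str) -> StudyConfig:
    """Load a configuration shipped with the package by name."""
    ref = resources.files("dogait") / "configs" / f"{name}.yaml"
    return StudyConfig.from_dict(yaml.safe_load(ref.read_text()))


def study_defaults() -> StudyConfig:
    return load_packaged_config("study_defaults")


def strong_effect() -> StudyConfig:
    return load_packaged_config("strong_effect")
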