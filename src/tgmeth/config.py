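"""Simulation configuration and reproducible RNG stream derivation."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

#: Treatments in the experimental design and the experiment whose control
#: line each is evaluated against.
TREATMENT_EXPERIMENT = {
    "microcystin": "T1",
    "temperature": "T1",
    "azacytidine": "T1",
    "zinc": "T2",
}
GENERATIONS = ("F1", "F2", "F4")
PERSISTENCE_CLASSES = ("F1-only", "F1F2", "F1F4", "transgenerational")


@dataclass
class StressorConfig:
    """Planted differential-methylation signal for one stressor."""

    n_planted_dmps: int = 200
    effect_size: float = 40.0  # percentage points
    hyper_fraction: float = 0.5
    persistence_prob: float = 0.5

    def validate(self) -> None:
        if self.n_planted_dmps < 0:
            raise ValueError("n_planted_dmps must be >= 0")
        if not 0 < self.effect_size <= 100:
            raise ValueError("effect_size must be in (0, 100]")
        if not 0 <= self.hyper_fraction <= 1:
            raise ValueError("hyper_fraction must be in [0, 1]")
        if not 0 <= self.persistence_prob <= 1:
            raise ValueError("persistence_prob must be in [0, 1]")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic WGBS experiment.

    Defaults emulate the statistical structure of a low-methylation
    invertebrate genome sequenced at low depth: ~0.5% of CpGs in a
    methylated state, mean coverage 5.3X with strong site-to-site
    (mappability) heterogeneity, methylation concentrated in gene bodies
    and preferentially in exons.
    """

    n_chromosomes: int = 4
    n_cpgs: int = 50_000
    cpg_spacing: int = 100  # mean bp between consecutive CpGs
    n_genes: int = 400
    exons_per_gene: int = 4
    genic_fraction: float = 0.60  # target fraction of the genome in gene bodies
    exon_fraction_of_gene: float = 0.70

    coverage_mean: float = 5.3
    # site-level "mappability" factor: two-component gamma mixture with mean 1;
    # a well-mappable fraction at several-fold depth and a poorly-mappable rest
    mappable_fraction: float = 0.15
    mappable_coverage_factor: float = 5.0
    mappable_shape: float = 8.0
    coverage_dispersion: float = 1.0  # gamma shape of the poorly-mappable component
    library_factor_range: tuple[float, float] = (0.95, 1.05)

    # two-component site-level methylation mixture; the methylated-fraction
    # default is calibrated so that the packaged call rule (total >= 1 and
    # fraction >= 0.5) yields ~0.50% called-methylated CpGs per control sample
    baseline_methylated_fraction: float = 0.00713
    high_meth_beta_params: tuple[float, float] = (13.5, 1.5)
    low_meth_beta_params: tuple[float, float] = (0.5, 500.0)
    genebody_enrichment: float = 12.0  # odds multiplier for genic placement
    exon_enrichment: float = 3.0  # extra odds multiplier for exonic placement

    sample_dispersion: float = 0.02  # beta-binomial phi (isogenic clone line)
    n_replicates: int = 3

    stressors: dict[str, StressorConfig] = field(
        default_factory=lambda: {
            "microcystin": StressorConfig(),
            "temperature": StressorConfig(),
            "zinc": StressorConfig(),
            "azacytidine": StressorConfig(n_planted_dmps=0),
        }
    )
    aza_f1_factor: float = 0.1
    aza_recovery_factor: float = 0.9

    # life-history generator
    lh_individuals_per_cell: int = 30
    lh_age1_mean: float = 8.0
    lh_age1_sd: float = 0.8
    lh_interbrood_mean: float = 3.0
    lh_interbrood_sd: float = 0.4
    lh_brood1_mean: float = 12.0
    lh_brood2_mean: float = 16.0
    lh_clone_sd: float = 0.05  # lognormal SD of clone-line brood multiplier
    lh_n_clones: int = 5
    # per-generation brood-size multiplier applied to every stressor
    lh_stressor_brood_effect: dict[str, float] = field(
        default_factory=lambda: {"F0": 0.80, "F1": 0.85, "F2": 0.95, "F3": 1.0, "F4": 1.0}
    )

    master_seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes <= 0 or self.n_cpgs <= 0:
            raise ValueError("counts must be positive")
        if self.n_genes < 0 or self.exons_per_gene <= 0:
            raise ValueError("n_genes must be >= 0 and exons_per_gene positive")
        for name in ("genic_fraction", "exon_fraction_of_gene",
                     "baseline_methylated_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage parameters must be positive")
        if not 0 <= self.mappable_fraction < 1:
            raise ValueError("mappable_fraction must be in [0, 1)")
        if self.mappable_fraction * self.mappable_coverage_factor >= 1:
            raise ValueError("mappable component would exceed the overall "
                             "coverage mean; lower fraction or factor")
        if not 0 <= self.sample_dispersion < 1:
            raise ValueError("sample_dispersion must be in [0, 1)")
        for f in (self.aza_f1_factor, self.aza_recovery_factor):
            if not 0 < f <= 1:
                raise ValueError("aza factors must be in (0, 1]")
        for sc in self.stressors.values():
            sc.validate()

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "stressors" in d:
            d["stressors"] = {
                k: StressorConfig(**v) if not isinstance(v, StressorConfig) else v
                for k, v in d["stressors"].items()
            }
        for key in ("library_factor_range", "high_meth_beta_params",
                    "low_meth_beta_params"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# RNG stream derivation: one master seed; each named stage gets an
# independent child stream keyed by a fixed integer so every stage is
# reproducible in isolation.  PCG64 via numpy default_rng everywhere.
_STAGE_KEYS = {
    "annotation": 1,
    "site_levels": 2,
    "planting": 3,
    "coverage": 4,
    "counts": 5,
    "lifehistory": 6,
    "permutation": 7,
    "bootstrap": 8,
    "overlap": 9,
}


def stage_rng(master_seed: int, stage: str, extra: int = 0) -> np.random.Generator:
    """Derive the RNG stream for a named pipeline stage from the master seed."""
    key = _STAGE_KEYS.get(stage)
    if key is None:
        raise KeyError(f"unknown RNG stage {stage!r}")
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(key, int(extra)))
    return np.random.default_rng(ss)
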