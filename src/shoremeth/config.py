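"""Simulation and pipeline configuration.

The defaults encode the cohort structure of a population-based colorectal
cancer series of 349 cases genotyped at the *MLH1* promoter SNP rs1800734:
genotype counts 211 GG / 119 GA / 19 AA, genotype- and tissue-stratified
mean (SD) percent-methylated-reference (PMR) values at the *MLH1* CpG
shore, genotype-dependent MSI-high rates, TNM stage margins, and a
stage-IV tumour hypomethylation override.  All percentages are on the
0-100 PMR scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

from .errors import ConfigurationError

GENOTYPES = ("GG", "GA", "AA")
TISSUES = ("PBMC", "normal_colon", "tumour")
STAGES = (1, 2, 3, 4, "unavailable")

#: Default microsatellite marker panel (NCI consensus plus extended markers).
DEFAULT_MSI_PANEL = (
    "ACTC", "BAT-25", "BAT-26", "BAT-40", "BAT-34C4",
    "D10S197", "D18S55", "D17S250", "D5S346", "MYC-L",
)


@dataclass
class QPCRParams:
    """Real-time PCR simulation parameters.

    efficiency        amplification factor per cycle, in (1, 2]
    ct_noise_sd       SD of Gaussian noise added to each replicate Ct
    alu_ct            Ct level of the ALU-C4 input control reaction
    reference_goi_ct  Ct of the shore reaction in fully methylated
                      reference DNA (sets the calibrator ratio)
    """

    efficiency: float = 2.0
    ct_noise_sd: float = 0.2
    alu_ct: float = 18.0
    reference_goi_ct: float = 22.0


@dataclass
class CloneParams:
    """Bisulfite clone simulation parameters.

    methylation_prob maps (tissue, genotype) to the per-CpG Bernoulli
    methylation probability.  conversion_failure_rate is the chance a
    non-CpG cytosine escapes bisulfite conversion (remains C);
    sequencing_error_rate is the per-base chance of a random substitution.
    fully_methylated_fraction mixes in clones methylated at every CpG,
    emulating correlated molecule-level patterns (0 = independent sites).
    """

    n_clones_min: int = 15
    n_clones_max: int = 27
    methylation_prob: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("PBMC", "GG"): 0.30, ("PBMC", "GA"): 0.28, ("PBMC", "AA"): 0.22,
            ("normal_colon", "GG"): 0.42, ("normal_colon", "GA"): 0.25,
            ("normal_colon", "AA"): 0.10,
            ("tumour", "GG"): 0.42, ("tumour", "GA"): 0.40,
            ("tumour", "AA"): 0.45,
        }
    )
    conversion_failure_rate: float = 0.005
    sequencing_error_rate: float = 0.001
    fully_methylated_fraction: float = 0.0


@dataclass
class SimulationConfig:
    """Full synthetic-cohort configuration; defaults mirror the study design."""

    n_per_genotype: Mapping[str, int] = field(
        default_factory=lambda: {"GG": 211, "GA": 119, "AA": 19}
    )
    # (tissue, genotype) -> (mean PMR %, SD %)
    tissue_genotype_params: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: {
            ("PBMC", "GG"): (30.1, 4.8),
            ("PBMC", "GA"): (28.3, 3.6),
            ("PBMC", "AA"): (22.6, 3.0),
            ("normal_colon", "GG"): (32.8, 6.5),
            ("normal_colon", "GA"): (27.3, 4.5),
            ("normal_colon", "AA"): (24.0, 3.2),
            ("tumour", "GG"): (33.3, 7.4),
            ("tumour", "GA"): (32.8, 7.0),
            ("tumour", "AA"): (37.0, 7.3),
        }
    )
    msi_high_rate_by_genotype: Mapping[str, float] = field(
        default_factory=lambda: {"GG": 30 / 211, "GA": 24 / 119, "AA": 8 / 19}
    )
    stage_probs: Mapping[object, float] = field(
        default_factory=lambda: {
            1: 22 / 349, 2: 81 / 349, 3: 208 / 349, 4: 21 / 349,
            "unavailable": 17 / 349,
        }
    )
    stage4_tumour_params: tuple[float, float] = (20.8, 3.6)
    island_methylated_rate: float = 34 / 349
    mmr_mutation_rate_by_genotype: Mapping[str, float] = field(
        default_factory=lambda: {"GG": 2 / 211, "GA": 5 / 119, "AA": 1 / 19}
    )
    sex_female_rate: float = 163 / 349
    age_mean: float = 61.9
    age_sd: float = 8.8
    age_range: tuple[float, float] = (20.0, 74.0)
    clone_params: CloneParams = field(default_factory=CloneParams)
    qpcr_params: QPCRParams = field(default_factory=QPCRParams)
    msi_panel: tuple[str, ...] = DEFAULT_MSI_PANEL
    msi_marker_failure_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.n_per_genotype.items():
            if g not in GENOTYPES:
                raise ConfigurationError(f"unknown genotype {g!r}")
            if n < 0:
                raise ConfigurationError(f"negative count for genotype {g}")
        for (tissue, g), (mean, sd) in self.tissue_genotype_params.items():
            if tissue not in TISSUES or g not in GENOTYPES:
                raise ConfigurationError(
                    f"unknown (tissue, genotype) key ({tissue!r}, {g!r})"
                )
            if sd <= 0:
                raise ConfigurationError(f"SD must be > 0 for ({tissue}, {g})")
        for name, probs in (
            ("msi_high_rate_by_genotype", self.msi_high_rate_by_genotype),
            ("mmr_mutation_rate_by_genotype", self.mmr_mutation_rate_by_genotype),
        ):
            for g, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(f"{name}[{g}] outside [0, 1]")
        total = sum(self.stage_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"stage_probs sums to {total}, expected 1")
        for s in self.stage_probs:
            if s not in STAGES:
                raise ConfigurationError(f"unknown stage {s!r}")
        if not 0.0 <= self.island_methylated_rate <= 1.0:
            raise ConfigurationError("island_methylated_rate outside [0, 1]")
        if not 0.0 <= self.sex_female_rate <= 1.0:
            raise ConfigurationError("sex_female_rate outside [0, 1]")
        if self.stage4_tumour_params[1] <= 0:
            raise ConfigurationError("stage4 tumour SD must be > 0")
        cp = self.clone_params
        if cp.n_clones_min < 1 or cp.n_clones_max < cp.n_clones_min:
            raise ConfigurationError("invalid clone count range")
        for key, p in cp.methylation_prob.items():
            if key[0] not in TISSUES or key[1] not in GENOTYPES:
                raise ConfigurationError(f"unknown clone methylation key {key!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"methylation_prob{key} outside [0, 1]")
        for name, p in (
            ("conversion_failure_rate", cp.conversion_failure_rate),
            ("sequencing_error_rate", cp.sequencing_error_rate),
            ("fully_methylated_fraction", cp.fully_methylated_fraction),
            ("msi_marker_failure_rate", self.msi_marker_failure_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} outside [0, 1]")
        if not 1.0 < self.qpcr_params.efficiency <= 2.0:
            raise ConfigurationError("qPCR efficiency must be in (1, 2]")
        if self.qpcr_params.ct_noise_sd < 0:
            raise ConfigurationError("Ct noise SD must be >= 0")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tissue_genotype_params"] = {
            f"{t}|{g}": list(v) for (t, g), v in self.tissue_genotype_params.items()
        }
        d["clone_params"]["methylation_prob"] = {
            f"{t}|{g}": p for (t, g), p in self.clone_params.methylation_prob.items()
        }
        d["stage_probs"] = {str(k): v for k, v in self.stage_probs.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        if "tissue_genotype_params" in d:
            d["tissue_genotype_params"] = {
                tuple(k.split("|")): tuple(v)
                for k, v in d["tissue_genotype_params"].items()
            }
        if "stage_probs" in d:
            d["stage_probs"] = {
                (int(k) if str(k).isdigit() else k): v
                for k, v in d["stage_probs"].items()
            }
        if "clone_params" in d and isinstance(d["clone_params"], Mapping):
            cp = dict(d["clone_params"])
            if "methylation_prob" in cp:
                cp["methylation_prob"] = {
                    tuple(k.split("|")): v for k, v in cp["methylation_prob"].items()
                }
            d["clone_params"] = CloneParams(**cp)
        if "qpcr_params" in d and isinstance(d["qpcr_params"], Mapping):
            d["qpcr_params"] = QPCRParams(**d["qpcr_params"])
        if "n_per_genotype" in d:
            d["n_per_genotype"] = {k: int(v) for k, v in d["n_per_genotype"].items()}
        if "msi_panel" in d:
            d["msi_panel"] = tuple(d["msi_panel"])
        if "stage4_tumour_params" in d:
            d["stage4_tumour_params"] = tuple(d["stage4_tumour_params"])
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
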