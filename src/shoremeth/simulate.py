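"""Synthetic cohort, qPCR plate, clone-set and MSI-marker generation.

Every downstream stage of the pipeline (PMR quantification, bisulfite
clone calling, MSI classification, association statistics) is exercised
against cohorts produced here.  The generator draws per-tissue true shore
methylation from genotype-stratified truncated normals, overrides tumour
methylation for stage-IV disease, and emits qPCR wells, bisulfite clone
FASTA sequences and microsatellite marker calls whose downstream
quantifications are unbiased for the generating truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import GENOTYPES, TISSUES, SimulationConfig
from .errors import ConfigurationError

# Fixed per-module RNG stream offsets: sub-simulations are independently
# reproducible from the one config seed.
_STREAM_COHORT = 0
_STREAM_QPCR = 1
_STREAM_CLONES = 2
_STREAM_MSI = 3


def stream_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent reproducible RNG stream derived from the config seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass
class SubjectRecord:
    """One case: genotype, demographics, stage and per-tissue truth."""

    subject_id: str
    genotype: str
    age: float
    sex: str  # "female" | "male"
    stage: object  # 1..4 or "unavailable"
    msi_class: str  # "MSS/MSI-L" | "MSI-H"
    island_methylated: bool
    mmr_mutation: bool
    true_shore_methylation: Optional[dict[str, float]] = None

    def __post_init__(self):
        if self.genotype not in GENOTYPES:
            raise ConfigurationError(f"unknown genotype {self.genotype!r}")
        if self.true_shore_methylation is not None:
            if set(self.true_shore_methylation) != set(TISSUES):
                raise ConfigurationError(
                    f"true_shore_methylation must cover tissues {TISSUES}"
                )
            for t, v in self.true_shore_methylation.items():
                if not 0.0 <= v <= 100.0:
                    raise ConfigurationError(
                        f"methylation {v} outside [0, 100] for tissue {t}"
                    )


@dataclass
class QPCRWell:
    plate_id: str
    well: str
    sample_id: str
    tissue: str  # PBMC | normal_colon | tumour | reference
    assay: str  # MLH1_shore | ALU_C4
    replicate: int
    ct: Optional[float]  # None = undetermined


@dataclass
class ReferenceRegion:
    """Bisulfite amplicon reference: top-strand sequence plus CpG coordinates.

    ``cpg_sites`` holds the 0-based coordinate of the C of each CpG,
    strictly increasing; sites are numbered 1..k in 5'->3' order.
    """

    name: str
    sequence: str
    cpg_sites: tuple[int, ...]
    amplicon_span: tuple[int, int] = None  # half-open; default whole sequence

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if self.amplicon_span is None:
            self.amplicon_span = (0, len(self.sequence))
        lo, hi = self.amplicon_span
        prev = -1
        for pos in self.cpg_sites:
            if self.sequence[pos : pos + 2] != "CG":
                raise ConfigurationError(f"no CpG at position {pos} of {self.name}")
            if pos <= prev:
                raise ConfigurationError("cpg_sites must be strictly increasing")
            if not lo <= pos < hi:
                raise ConfigurationError(f"CpG at {pos} outside amplicon span")
            prev = pos

    @property
    def n_sites(self) -> int:
        return len(self.cpg_sites)

    def non_cpg_c_positions(self) -> tuple[int, ...]:
        """Positions of cytosines outside CpG dinucleotides (conversion QC)."""
        sites = set(self.cpg_sites)
        return tuple(
            i for i, b in enumerate(self.sequence) if b == "C" and i not in sites
        )


@dataclass
class CloneSet:
    """Simulated clone sequences for one sample+tissue, with ground truth."""

    sample_id: str
    tissue: str
    genotype: str
    names: list[str]
    sequences: list[str]
    truth: np.ndarray = field(repr=False)  # clones x sites bool


# ---------------------------------------------------------------------------
# reference amplicon


def default_reference(length: int = 232, n_cpgs: int = 6) -> ReferenceRegion:
    """Synthetic 232-bp shore-like amplicon with six CpGs.

    The real amplicon sequence is not redistributable, so a deterministic
    synthetic stand-in with matched length, CpG count and realistic non-CpG
    cytosine density is constructed.  CpG dinucleotides occur only at the
    six designated sites.
    """
    rng = np.random.default_rng(20170309)
    gap = length // (n_cpgs + 1)
    sites = [gap * (i + 1) for i in range(n_cpgs)]
    seq = [""] * length
    site_set = set(sites)
    i = 0
    while i < length:
        if i in site_set:
            seq[i] = "C"
            seq[i + 1] = "G"
            i += 2
            continue
        prev = seq[i - 1] if i > 0 else ""
        nxt_is_site = (i + 1) in site_set  # next C would make a stray CG? no: site is C
        choices = ["A", "C", "G", "T"]
        if prev == "C":
            choices.remove("G")  # no stray CpG
        if nxt_is_site:
            # next position starts a CpG (C); any base here is fine
            pass
        seq[i] = choices[rng.integers(len(choices))]
        i += 1
    ref = ReferenceRegion(
        name="MLH1_shore_amplicon_synthetic",
        sequence="".join(seq),
        cpg_sites=tuple(sites),
    )
    return ref


# ---------------------------------------------------------------------------
# cohort


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  low: float, high: float) -> float:
    """Normal draw truncated to [low, high] by redrawing."""
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    raise RuntimeError("truncated normal rejection did not terminate")


def generate_cohort(config: SimulationConfig) -> list[SubjectRecord]:
    """Generate the configured number of subjects per genotype.

    Per-tissue true shore methylation is drawn from the configured
    (tissue, genotype) normal truncated to [0, 100]; stage-IV subjects'
    tumour methylation comes from ``stage4_tumour_params`` instead.
    Identical (config, seed) yields identical cohorts.
    """
    config.validate()
    rng = stream_rng(config.seed, _STREAM_COHORT)
    stages = list(config.stage_probs)
    stage_p = np.array([config.stage_probs[s] for s in stages], dtype=float)
    stage_p = stage_p / stage_p.sum()
    subjects: list[SubjectRecord] = []
    idx = 0
    for genotype in GENOTYPES:
        n = config.n_per_genotype.get(genotype, 0)
        for _ in range(n):
            idx += 1
            sid = f"S{idx:04d}"
            age = round(_trunc_normal(rng, config.age_mean, config.age_sd,
                                      *config.age_range), 1)
            sex = "female" if rng.random() < config.sex_female_rate else "male"
            stage = stages[rng.choice(len(stages), p=stage_p)]
            msi = ("MSI-H" if rng.random() < config.msi_high_rate_by_genotype[genotype]
                   else "MSS/MSI-L")
            island = bool(rng.random() < config.island_methylated_rate)
            mmr = bool(rng.random() < config.mmr_mutation_rate_by_genotype[genotype])
            meth: dict[str, float] = {}
            for tissue in TISSUES:
                key = (tissue, genotype)
                if key not in config.tissue_genotype_params:
                    raise ConfigurationError(f"no PMR parameters for {key}")
                mean, sd = config.tissue_genotype_params[key]
                if tissue == "tumour" and stage == 4:
                    mean, sd = config.stage4_tumour_params
                meth[tissue] = _trunc_normal(rng, mean, sd, 0.0, 100.0)
            subjects.append(SubjectRecord(
                subject_id=sid, genotype=genotype, age=age, sex=sex,
                stage=stage, msi_class=msi, island_methylated=island,
                mmr_mutation=mmr, true_shore_methylation=meth,
            ))
    return subjects


# ---------------------------------------------------------------------------
# qPCR


def _shore_ct(methylation_pct: float, params) -> Optional[float]:
    """Ct of the shore reaction given true methylation, inverting the PMR model.

    The well layout is constructed so that the downstream PMR computation
    (sample shore/ALU ratio over the fully-methylated-reference ratio)
    returns exactly the true methylation in the absence of Ct noise.
    """
    if methylation_pct <= 0.0:
        return None  # below detection: no amplification
    e = params.efficiency
    ref_ratio_log = params.alu_ct - params.reference_goi_ct  # log_E(ref GOI/ALU)
    return params.alu_ct - (math.log(methylation_pct / 100.0, e) + ref_ratio_log)


def simulate_qpcr(subject: SubjectRecord, tissue: str, config: SimulationConfig,
                  rng: Optional[np.random.Generator] = None,
                  plate_id: str = "P001",
                  include_reference: bool = True) -> list[QPCRWell]:
    """Duplicate shore and ALU-C4 wells for one sample, plus reference wells.

    Replicate Ct values are perturbed by Gaussian noise of the configured
    SD; the expectation of the downstream PMR equals the subject's true
    methylation for the tissue.
    """
    if subject.true_shore_methylation is None or tissue not in subject.true_shore_methylation:
        raise ConfigurationError(f"tissue {tissue!r} not present in subject")
    if rng is None:
        rng = stream_rng(config.seed, _STREAM_QPCR)
    p = config.qpcr_params
    truth = subject.true_shore_methylation[tissue]
    goi_ct = _shore_ct(truth, p)
    wells: list[QPCRWell] = []

    def add(sample_id, tiss, assay, rep, base_ct):
        ct = None
        if base_ct is not None:
            ct = base_ct + (rng.normal(0.0, p.ct_noise_sd) if p.ct_noise_sd > 0 else 0.0)
            ct = float(min(max(ct, 1.0), 50.0))
        wells.append(QPCRWell(plate_id, f"W{len(wells)+1:02d}", sample_id, tiss,
                              assay, rep, ct))

    for rep in (1, 2):
        add(subject.subject_id, tissue, "MLH1_shore", rep, goi_ct)
    for rep in (1, 2):
        add(subject.subject_id, tissue, "ALU_C4", rep, p.alu_ct)
    if include_reference:
        for rep in (1, 2):
            add("methylated_reference", "reference", "MLH1_shore", rep,
                p.reference_goi_ct)
        for rep in (1, 2):
            add("methylated_reference", "reference", "ALU_C4", rep, p.alu_ct)
    return wells


def simulate_plates(cohort: Sequence[SubjectRecord],
                    config: SimulationConfig) -> list[QPCRWell]:
    """Wells for every (subject, tissue), one reference set per 96-well plate.

    22 sample/tissue pairs (4 wells each) plus one duplicate reference
    pair per plate fill 92 of 96 wells, mirroring duplicate analysis on
    96-well plates.
    """
    rng = stream_rng(config.seed, _STREAM_QPCR)
    pairs = [(s, t) for s in cohort for t in TISSUES]
    wells: list[QPCRWell] = []
    per_plate = 22
    for pi in range(0, len(pairs), per_plate):
        plate = f"P{pi // per_plate + 1:03d}"
        chunk = pairs[pi : pi + per_plate]
        plate_wells: list[QPCRWell] = []
        for j, (subj, tissue) in enumerate(chunk):
            w = simulate_qpcr(subj, tissue, config, rng=rng, plate_id=plate,
                              include_reference=(j == 0))
            plate_wells.extend(w)
        for k, w in enumerate(plate_wells):
            w.well = f"{'ABCDEFGH'[k // 12]}{k % 12 + 1}"
        wells.extend(plate_wells)
    return wells


# ---------------------------------------------------------------------------
# bisulfite clones

_BASES = "ACGT"


def simulate_clones(subject: SubjectRecord, tissue: str, reference: ReferenceRegion,
                    config: SimulationConfig,
                    rng: Optional[np.random.Generator] = None) -> CloneSet:
    """Bisulfite clone sequences for one sample+tissue.

    Clone count is uniform in [n_clones_min, n_clones_max]; each CpG is
    methylated independently Bernoulli(p) for the (tissue, genotype)
    probability (optionally mixed with fully methylated molecules); the
    sequence is the bisulfite image of the reference with conversion
    failures and per-base sequencing errors at the configured rates.
    """
    if reference.n_sites < 1:
        raise ConfigurationError("reference has no CpG sites")
    cp = config.clone_params
    key = (tissue, subject.genotype)
    if key not in cp.methylation_prob:
        raise ConfigurationError(f"no clone methylation probability for {key}")
    p = cp.methylation_prob[key]
    if rng is None:
        rng = stream_rng(config.seed, _STREAM_CLONES)
    n = int(rng.integers(cp.n_clones_min, cp.n_clones_max + 1))
    site_set = set(reference.cpg_sites)
    names, seqs = [], []
    truth = np.zeros((n, reference.n_sites), dtype=bool)
    for ci in range(n):
        if cp.fully_methylated_fraction > 0 and rng.random() < cp.fully_methylated_fraction:
            states = np.ones(reference.n_sites, dtype=bool)
        else:
            states = rng.random(reference.n_sites) < p
        truth[ci] = states
        by_site = dict(zip(reference.cpg_sites, states))
        out = []
        for i, b in enumerate(reference.sequence):
            if b != "C":
                out.append(b)
            elif i in site_set:
                out.append("C" if by_site[i] else "T")
            else:  # non-CpG C: converted unless bisulfite failure
                out.append("C" if rng.random() < cp.conversion_failure_rate else "T")
        if cp.sequencing_error_rate > 0:
            for i in range(len(out)):
                if rng.random() < cp.sequencing_error_rate:
                    alt = [x for x in _BASES if x != out[i]]
                    out[i] = alt[rng.integers(3)]
        names.append(f"{subject.subject_id}|{tissue}|clone{ci + 1}")
        seqs.append("".join(out))
    return CloneSet(subject.subject_id, tissue, subject.genotype, names, seqs, truth)


# ---------------------------------------------------------------------------
# MSI markers


def simulate_msi_markers(subject: SubjectRecord, config: SimulationConfig,
                         rng: Optional[np.random.Generator] = None
                         ) -> list[tuple[str, str, str]]:
    """(sample_id, marker, status) rows consistent with the subject's MSI class.

    MSI-H subjects receive >= 30% unstable markers; MSS/MSI-L subjects
    receive 0-2 unstable of the 10-marker panel (< 30%).
    """
    if rng is None:
        rng = stream_rng(config.seed, _STREAM_MSI)
    panel = list(config.msi_panel)
    k = len(panel)
    if subject.msi_class == "MSI-H":
        min_unstable = math.ceil(0.30 * k)
        n_unstable = min_unstable + int(rng.binomial(k - min_unstable, 0.4))
    else:
        n_unstable = int(rng.choice([0, 1, 2], p=[0.6, 0.3, 0.1]))
    unstable = set(rng.choice(k, size=n_unstable, replace=False).tolist())
    rows = []
    for i, marker in enumerate(panel):
        if config.msi_marker_failure_rate > 0 and rng.random() < config.msi_marker_failure_rate:
            status = "failed"
        else:
            status = "unstable" if i in unstable else "stable"
        rows.append((subject.subject_id, marker, status))
    return rows
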