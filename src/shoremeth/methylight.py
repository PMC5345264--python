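"""MethyLight quantification: Ct values to Percent Methylated Reference.

PMR = 100 * (shore/ALU-C4 quantity ratio in the sample) divided by the
same ratio in fully methylated reference DNA.  Duplicate wells are
aggregated on the Ct scale (arithmetic mean of Ct, i.e. geometric mean of
quantities); a CpG-island methylation call uses the PMR >= 10% rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MissingControlError

FLAG_NO_AMPLIFICATION = "NO_AMPLIFICATION"
FLAG_REPLICATE_DISCORDANT = "REPLICATE_DISCORDANT"
FLAG_MISSING_CONTROL = "MISSING_CONTROL"

ISLAND_PMR_CUTOFF = 10.0  # PMR >= 10% calls the CpG island methylated

REFERENCE_SAMPLE_TISSUE = "reference"


@dataclass
class PMRResult:
    """One (sample, tissue) PMR quantification with QC flags."""

    sample_id: str
    tissue: str
    assay: str
    mean_ct_goi: float | None
    mean_ct_alu: float | None
    quantity_ratio_sample: float
    quantity_ratio_reference: float
    pmr: float
    flags: frozenset = field(default_factory=frozenset)


def ct_to_quantity(ct: float | None, efficiency: float = 2.0) -> float:
    """Relative quantity efficiency**(-Ct); undetermined Ct maps to 0."""
    if not 1.0 < efficiency <= 2.0:
        raise ConfigurationError(f"efficiency {efficiency} outside (1, 2]")
    if ct is None or (isinstance(ct, float) and math.isnan(ct)):
        return 0.0
    return float(efficiency) ** (-float(ct))


def aggregate_replicates(cts, max_delta_ct: float = 1.5) -> tuple[float | None, frozenset]:
    """Mean Ct of replicate wells with QC flags.

    Undetermined replicates (None/NaN) are dropped from the mean; if all
    are undetermined the group is flagged NO_AMPLIFICATION.  A numeric
    spread above ``max_delta_ct`` flags REPLICATE_DISCORDANT.
    """
    cts = list(cts)
    if not cts:
        raise ValueError("no replicate wells to aggregate")
    numeric = [float(c) for c in cts
               if c is not None and not (isinstance(c, float) and math.isnan(c))]
    flags = set()
    if not numeric:
        return None, frozenset({FLAG_NO_AMPLIFICATION})
    if len(numeric) > 1 and (max(numeric) - min(numeric)) > max_delta_ct:
        flags.add(FLAG_REPLICATE_DISCORDANT)
    if len(numeric) < len(cts):
        # partial amplification failure also merits a discordance flag
        flags.add(FLAG_REPLICATE_DISCORDANT)
    return float(np.mean(numeric)), frozenset(flags)


def compute_pmr(sample_goi_q: float, sample_alu_q: float,
                ref_goi_q: float, ref_alu_q: float) -> float:
    """PMR percent from four relative quantities; uncapped above 100."""
    if sample_alu_q <= 0:
        raise MissingControlError("sample ALU-C4 quantity is non-positive")
    if ref_alu_q <= 0 or ref_goi_q <= 0:
        raise MissingControlError("reference quantities must be positive")
    if sample_goi_q < 0:
        raise ValueError("negative quantity")
    return 100.0 * (sample_goi_q / sample_alu_q) / (ref_goi_q / ref_alu_q)


def classify_island(pmr: float) -> str:
    """CpG-island methylation call: methylated iff PMR >= 10%."""
    if pmr < 0:
        raise ValueError(f"negative PMR {pmr}")
    return "methylated" if pmr >= ISLAND_PMR_CUTOFF else "unmethylated"


def pmr_from_wells(wells: pd.DataFrame, efficiency: float = 2.0,
                   max_delta_ct: float = 1.5) -> pd.DataFrame:
    """Quantify PMR for every (sample, tissue) group in a well table.

    ``wells`` columns: plate_id, well, sample_id, tissue, assay, replicate,
    ct (NaN for undetermined).  Reference wells are identified by
    tissue == "reference" and calibrate per plate; a plate without
    reference wells falls back to the study-wide reference ratio.

    Returns a tidy frame (one row per sample/tissue) with mean Cts,
    quantity ratios, PMR percent, island call and semicolon-joined flags.
    """
    required = {"plate_id", "sample_id", "tissue", "assay", "replicate", "ct"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"well table missing columns {sorted(missing)}")

    def group_mean(sub: pd.DataFrame) -> tuple[float | None, frozenset]:
        cts = [None if pd.isna(c) else float(c) for c in sub["ct"]]
        return aggregate_replicates(cts, max_delta_ct)

    # per-plate reference calibrator ratios
    ref_rows = wells[wells["tissue"] == REFERENCE_SAMPLE_TISSUE]
    if ref_rows.empty:
        raise MissingControlError("no fully-methylated reference wells in table")
    ref_ratio_by_plate: dict[str, float] = {}
    for plate, sub in ref_rows.groupby("plate_id"):
        goi_ct, _ = group_mean(sub[sub["assay"] == "MLH1_shore"])
        alu_ct, _ = group_mean(sub[sub["assay"] == "ALU_C4"])
        if goi_ct is None or alu_ct is None:
            continue
        ref_ratio_by_plate[plate] = (
            ct_to_quantity(goi_ct, efficiency) / ct_to_quantity(alu_ct, efficiency)
        )
    if not ref_ratio_by_plate:
        raise MissingControlError("reference wells never amplified")
    global_ref_ratio = float(np.mean(list(ref_ratio_by_plate.values())))

    results = []
    sample_rows = wells[wells["tissue"] != REFERENCE_SAMPLE_TISSUE]
    for (sample_id, tissue), sub in sample_rows.groupby(
            ["sample_id", "tissue"], sort=True):
        plate = sub["plate_id"].iloc[0]
        ref_ratio = ref_ratio_by_plate.get(plate, global_ref_ratio)
        goi_ct, goi_flags = group_mean(sub[sub["assay"] == "MLH1_shore"])
        alu_sub = sub[sub["assay"] == "ALU_C4"]
        flags = set(goi_flags)
        if alu_sub.empty:
            raise MissingControlError(
                f"no ALU-C4 wells for sample {sample_id} tissue {tissue}")
        alu_ct, alu_flags = group_mean(alu_sub)
        flags |= alu_flags
        if alu_ct is None:
            flags.add(FLAG_MISSING_CONTROL)
            results.append(PMRResult(sample_id, tissue, "MLH1_shore", goi_ct, None,
                                     float("nan"), ref_ratio, float("nan"),
                                     frozenset(flags)))
            continue
        alu_q = ct_to_quantity(alu_ct, efficiency)
        if goi_ct is None:
            # methylation below detection, not missing data
            results.append(PMRResult(sample_id, tissue, "MLH1_shore", None, alu_ct,
                                     0.0, ref_ratio, 0.0, frozenset(flags)))
            continue
        sample_ratio = ct_to_quantity(goi_ct, efficiency) / alu_q
        pmr = 100.0 * sample_ratio / ref_ratio
        results.append(PMRResult(sample_id, tissue, "MLH1_shore", goi_ct, alu_ct,
                                 sample_ratio, ref_ratio, pmr, frozenset(flags)))

    df = pd.DataFrame([{
        "sample_id": r.sample_id,
        "tissue": r.tissue,
        "assay": r.assay,
        "mean_ct_goi": np.nan if r.mean_ct_goi is None else r.mean_ct_goi,
        "mean_ct_alu": np.nan if r.mean_ct_alu is None else r.mean_ct_alu,
        "quantity_ratio_sample": r.quantity_ratio_sample,
        "quantity_ratio_reference": r.quantity_ratio_reference,
        "pmr": r.pmr,
        "methylated_call": "." if math.isnan(r.pmr) else classify_island(r.pmr),
        "flags": ";".join(sorted(r.flags)) if r.flags else ".",
    } for r in results])
    return df.sort_values(["sample_id", "tissue"]).reset_index(drop=True)
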