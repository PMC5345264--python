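"""File formats, run manifest, and the end-to-end pipeline driver.

Conventions, enforced everywhere: TSV/CSV with UTF-8 and LF endings,
"." for missing values, "Undetermined" for failed qPCR wells, FASTA
wrapped at 80 columns, BED strictly 0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from . import clones as cl
from . import methylight as ml
from . import msi as msimod
from . import stats as ss
from .config import SimulationConfig, TISSUES
from .errors import ParseError, PipelineError
from .model import ShoreAssociationModel
from .simulate import (QPCRWell, ReferenceRegion, SubjectRecord,
                       default_reference, generate_cohort, simulate_clones,
                       simulate_msi_markers, simulate_plates, stream_rng)

log = logging.getLogger("shoremeth")

MISSING = "."
UNDETERMINED = "Undetermined"

SHEET_COLUMNS = ("subject_id", "genotype", "age", "sex", "stage", "msi_class",
                 "island_methylated", "mmr_mutation")
WELL_COLUMNS = ("plate_id", "well", "sample_id", "tissue", "assay",
                "replicate", "ct")


# ---------------------------------------------------------------------------
# sample sheet


def write_sample_sheet(subjects: Sequence[SubjectRecord], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(SHEET_COLUMNS) + "\n")
        for s in subjects:
            fh.write("\t".join([
                s.subject_id, s.genotype, f"{s.age:g}", s.sex, str(s.stage),
                s.msi_class,
                "true" if s.island_methylated else "false",
                "true" if s.mmr_mutation else "false",
            ]) + "\n")


def read_sample_sheet(path) -> pd.DataFrame:
    """Validated subject sheet as a DataFrame (one row per subject)."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError("empty sample sheet", path)
    header = lines[0].split("\t")
    required = {"subject_id", "genotype", "age", "sex", "stage", "msi_class",
                "island_methylated"}
    missing = required - set(header)
    if missing:
        raise ParseError(f"missing columns {sorted(missing)}", path, 1)
    if len(lines) == 1:
        raise ParseError("sample sheet has a header but no subjects", path)
    rows = []
    seen: set[str] = set()
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = dict(zip(header, line.split("\t")))
        g = fields["genotype"]
        if g not in ("GG", "GA", "AA"):
            raise ParseError(f"invalid genotype {g!r}", path, ln)
        sid = fields["subject_id"]
        if sid in seen:
            raise ParseError(f"duplicate subject_id {sid!r}", path, ln)
        seen.add(sid)
        stage_raw = fields["stage"]
        stage = int(stage_raw) if stage_raw.isdigit() else stage_raw
        if stage not in (1, 2, 3, 4, "unavailable"):
            raise ParseError(f"invalid stage {stage_raw!r}", path, ln)
        row = {
            "subject_id": sid, "genotype": g, "age": float(fields["age"]),
            "sex": fields["sex"], "stage": stage,
            "msi_class": fields["msi_class"],
            "island_methylated": fields["island_methylated"] == "true",
        }
        if "mmr_mutation" in fields:
            row["mmr_mutation"] = fields["mmr_mutation"] == "true"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR wells


def write_wells_csv(wells: Sequence[QPCRWell], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(",".join(WELL_COLUMNS) + "\n")
        for w in wells:
            ct = UNDETERMINED if w.ct is None else f"{w.ct:.6f}"
            fh.write(f"{w.plate_id},{w.well},{w.sample_id},{w.tissue},"
                     f"{w.assay},{w.replicate},{ct}\n")


def read_wells_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str,
                                  "sample_id": str})
    missing = set(WELL_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"missing columns {sorted(missing)}", path, 1)
    df["ct"] = pd.to_numeric(
        df["ct"].replace({UNDETERMINED: np.nan, MISSING: np.nan}),
        errors="raise")
    return df


def write_pmr_results(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING,
              float_format="%.6f", lineterminator="\n")


def read_pmr_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[MISSING], dtype={"sample_id": str})
    return df


# ---------------------------------------------------------------------------
# MSI


def write_msi_markers(rows: Iterable[tuple[str, str, str]], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("sample_id\tmarker\tstatus\n")
        for sid, marker, status in rows:
            fh.write(f"{sid}\t{marker}\t{status}\n")


def read_msi_markers(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "marker", "status"} - set(df.columns)
    if missing:
        raise ParseError(f"missing columns {sorted(missing)}", path, 1)
    return df


def classify_msi_table(markers: pd.DataFrame) -> pd.DataFrame:
    calls = []
    for sid, sub in markers.groupby("sample_id", sort=True):
        mk = [msimod.MarkerResult(sid, r.marker, r.status)
              for r in sub.itertuples()]
        call = msimod.classify_msi(mk)
        calls.append({
            "sample_id": sid,
            "n_evaluable": call.n_evaluable,
            "fraction_unstable": float(call.fraction_unstable),
            "msi_class": call.msi_class,
            "msi_binary": msimod.binarize_for_association(call),
        })
    return pd.DataFrame(calls)


def write_msi_calls(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f",
              lineterminator="\n")


# ---------------------------------------------------------------------------
# FASTA / BED


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 80) -> None:
    seq_records = [SeqRecord(Seq(seq), id=name, description="")
                   for name, seq in records]
    with open(path, "w", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_reference(ref: ReferenceRegion, fasta_path, bed_path) -> None:
    write_fasta([(ref.name, ref.sequence)], fasta_path)
    with open(bed_path, "w", newline="\n") as fh:
        for i, pos in enumerate(ref.cpg_sites, start=1):
            fh.write(f"{ref.name}\t{pos}\t{pos + 2}\tCpG_{i}\n")


def read_reference(fasta_path, bed_path) -> ReferenceRegion:
    records = read_fasta(fasta_path)
    if len(records) != 1:
        raise ParseError("reference FASTA must contain exactly one record",
                         fasta_path)
    name, seq = records[0]
    sites = []
    with open(bed_path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError("BED line needs >= 3 columns", bed_path, ln)
            if parts[0] != name:
                raise ParseError(f"BED chrom {parts[0]!r} does not match "
                                 f"reference {name!r}", bed_path, ln)
            sites.append(int(parts[1]))
    return ReferenceRegion(name=name, sequence=seq, cpg_sites=tuple(sorted(sites)))


# ---------------------------------------------------------------------------
# clone outputs


def write_clone_matrix(matrices: Sequence[cl.MethylationMatrix], path) -> None:
    if not matrices:
        raise ValueError("no matrices to write")
    k = matrices[0].n_sites
    cols = [f"cpg_{i}" for i in range(1, k + 1)]
    with open(path, "w", newline="\n") as fh:
        fh.write("sample_id\ttissue\tgenotype\tclone_id\t" + "\t".join(cols) + "\n")
        for m in matrices:
            for cid, row in zip(m.clone_ids, m.calls):
                fh.write(f"{m.sample_id}\t{m.tissue}\t{m.genotype}\t{cid}\t"
                         + "\t".join(row) + "\n")


def write_site_summary(matrices: Sequence[cl.MethylationMatrix], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("sample_id\ttissue\tgenotype\tsite\tn_methylated\t"
                 "n_unmethylated\tn_missing\tpercent_methylated\n")
        for m in matrices:
            nm, nu, nx = m.site_counts()
            pct = m.percent_methylated()
            for s in range(m.n_sites):
                p = MISSING if np.isnan(pct[s]) else f"{pct[s]:.1f}"
                fh.write(f"{m.sample_id}\t{m.tissue}\t{m.genotype}\t{s + 1}\t"
                         f"{nm[s]}\t{nu[s]}\t{nx[s]}\t{p}\n")


def write_site_tests(tests: Sequence[cl.SiteTest], path, label: str = "") -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("group\tsite\tgenotypes\tstatistic\tdf\tp_value\tcomputable\n")
        for t in tests:
            stat = MISSING if t.statistic is None else f"{t.statistic:.6f}"
            df = MISSING if t.df is None else str(t.df)
            p = MISSING if t.p_value is None else f"{t.p_value:.6g}"
            fh.write(f"{label or MISSING}\t{t.site}\t{','.join(t.genotypes)}\t"
                     f"{stat}\t{df}\t{p}\t{str(t.computable).lower()}\n")


# ---------------------------------------------------------------------------
# JSON helpers


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_json(obj, path) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def parameter_hash(config: SimulationConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: SimulationConfig, outdir,
                 n_clone_subjects_per_genotype: int = 2,
                 clone_tissues: tuple[str, ...] = ("normal_colon", "tumour"),
                 efficiency: Optional[float] = None,
                 max_delta_ct: float = 1.5) -> dict:
    """Simulate a cohort and run every analysis stage, writing all outputs.

    Bisulfite cloning is performed for the first
    ``n_clone_subjects_per_genotype`` subjects of each genotype in the
    configured tissues (the study design: two cases per genotype, tumour
    plus matched normal).  Re-running with an identical config reproduces
    identical outputs byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    report: dict = {}

    def stage(name):
        log.info("stage %-10s %6.1fs", name, time.time() - t0)

    # --- simulate ---------------------------------------------------------
    try:
        config.validate()
        cohort = generate_cohort(config)
        write_sample_sheet(cohort, outdir / "sample_sheet.tsv")
        wells = simulate_plates(cohort, config)
        write_wells_csv(wells, outdir / "qpcr_wells.csv")
        msi_rows: list[tuple[str, str, str]] = []
        msi_rng = stream_rng(config.seed, 3)
        for s in cohort:
            msi_rows.extend(simulate_msi_markers(s, config, rng=msi_rng))
        write_msi_markers(msi_rows, outdir / "msi_markers.tsv")
        ref = default_reference()
        write_reference(ref, outdir / "reference.fasta", outdir / "cpg_sites.bed")
        clone_rng = stream_rng(config.seed, 2)
        clone_sets = []
        for g in ("GG", "GA", "AA"):
            chosen = [s for s in cohort if s.genotype == g][
                :n_clone_subjects_per_genotype]
            for subj in chosen:
                for tissue in clone_tissues:
                    clone_sets.append(simulate_clones(subj, tissue, ref, config,
                                                      rng=clone_rng))
        clones_dir = outdir / "clones"
        clones_dir.mkdir(exist_ok=True)
        for cs in clone_sets:
            write_fasta(zip(cs.names, cs.sequences),
                        clones_dir / f"{cs.sample_id}_{cs.tissue}.fasta")
        truth = {
            "seed": config.seed,
            "parameter_hash": parameter_hash(config),
            "subjects": {s.subject_id: {
                "genotype": s.genotype, "stage": str(s.stage),
                "msi_class": s.msi_class,
                "true_shore_methylation": s.true_shore_methylation,
            } for s in cohort},
            "clone_truth": {f"{cs.sample_id}|{cs.tissue}": cs.truth.astype(int).tolist()
                            for cs in clone_sets},
        }
        write_json(truth, outdir / "truth.json")
        stage("simulate")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", str(e)) from e

    # --- pmr --------------------------------------------------------------
    try:
        wells_df = read_wells_csv(outdir / "qpcr_wells.csv")
        eff = efficiency if efficiency is not None else config.qpcr_params.efficiency
        pmr_df = ml.pmr_from_wells(wells_df, efficiency=eff,
                                   max_delta_ct=max_delta_ct)
        write_pmr_results(pmr_df, outdir / "pmr_results.tsv")
        stage("pmr")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("pmr", str(e)) from e

    # --- clones -----------------------------------------------------------
    try:
        matrices = []
        genotype_of = {s.subject_id: s.genotype for s in cohort}
        for cs in clone_sets:
            fasta = clones_dir / f"{cs.sample_id}_{cs.tissue}.fasta"
            calls = cl.process_clones(read_fasta(fasta), ref)
            matrices.append(cl.build_matrix(calls, cs.sample_id, cs.tissue,
                                            genotype_of[cs.sample_id],
                                            ref.n_sites))
        write_clone_matrix(matrices, outdir / "clone_matrix.tsv")
        write_site_summary(matrices, outdir / "site_summary.tsv")
        all_tests = []
        labels = []
        for tissue in clone_tissues:
            mats = [m for m in matrices if m.tissue == tissue]
            if len({m.genotype for m in mats}) >= 2:
                tests = cl.compare_sites_by_genotype(mats)
                all_tests.extend(tests)
                labels.extend([tissue] * len(tests))
        with open(outdir / "site_tests.tsv", "w", newline="\n") as fh:
            fh.write("group\tsite\tgenotypes\tstatistic\tdf\tp_value\tcomputable\n")
            for label, t in zip(labels, all_tests):
                stat = MISSING if t.statistic is None else f"{t.statistic:.6f}"
                dfv = MISSING if t.df is None else str(t.df)
                p = MISSING if t.p_value is None else f"{t.p_value:.6g}"
                fh.write(f"{label}\t{t.site}\t{','.join(t.genotypes)}\t"
                         f"{stat}\t{dfv}\t{p}\t{str(t.computable).lower()}\n")
        with open(outdir / "lollipops.txt", "w", newline="\n") as fh:
            for m in matrices:
                fh.write(cl.lollipop(m) + "\n\n")
        stage("clones")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("clones", str(e)) from e

    # --- msi --------------------------------------------------------------
    try:
        markers = read_msi_markers(outdir / "msi_markers.tsv")
        msi_calls = classify_msi_table(markers)
        write_msi_calls(msi_calls, outdir / "msi_calls.tsv")
        stage("msi")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("msi", str(e)) from e

    # --- associate --------------------------------------------------------
    try:
        subjects_df = read_sample_sheet(outdir / "sample_sheet.tsv")
        # MSI class from the classifier (round-tripped through marker calls)
        subjects_df = subjects_df.drop(columns=["msi_class"]).merge(
            msi_calls[["sample_id", "msi_binary"]].rename(
                columns={"sample_id": "subject_id", "msi_binary": "msi_class"}),
            on="subject_id", how="left")
        cohort_table = ss.make_cohort_table(
            subjects_df, pmr_df[["sample_id", "tissue", "pmr"]])
        results = ShoreAssociationModel(cohort_table).fit()
        report = results.to_dict()
        table1 = ss.summarize_cohort(subjects_df)
        table1.to_csv(outdir / "summary_table1.tsv", sep="\t", index=False,
                      na_rep=MISSING, lineterminator="\n")
        write_json(report, outdir / "association_report.json")
        with open(outdir / "association_summary.txt", "w", newline="\n") as fh:
            fh.write(results.summary() + "\n")
        stage("associate")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("associate", str(e)) from e

    manifest = {
        "package": "shoremeth",
        "version": __version__,
        "seed": config.seed,
        "parameter_hash": parameter_hash(config),
        "python": sys.version.split()[0],
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    write_json(manifest, outdir / "manifest.json")
    return report
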