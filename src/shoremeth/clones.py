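"""Per-CpG methylation calling from Sanger bisulfite clone sequences.

Clones are globally aligned to the reference amplicon with a
bisulfite-aware scoring scheme (reference C aligned to read T scores as a
match, reflecting conversion of unmethylated cytosines), methylation is
called at each CpG C position (C = methylated, T = unmethylated, anything
else = missing), and conversion efficiency over non-CpG cytosines gates
clone QC.  Matrices of calls feed per-site genotype contingency tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from scipy import stats as sps

from .errors import DegenerateTableError, LowIdentityError
from .simulate import ReferenceRegion

MET, UNMET, MISSING = "M", "U", "."

DEFAULT_MIN_CONVERSION = 0.95
DEFAULT_MIN_IDENTITY = 0.90
IDENTITY_FLOOR = 0.6  # below this the clone is not the target amplicon


def _bisulfite_aligner(match: float = 1.0, mismatch: float = -1.0,
                       open_gap: float = -2.0, extend_gap: float = -0.5
                       ) -> Align.PairwiseAligner:
    m = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            m[a, b] = match if a == b else mismatch
    m["C", "T"] = match  # reference C vs converted read T
    for x in "ACGTN":
        m["N", x] = 0.0
        m[x, "N"] = 0.0
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = m
    al.open_gap_score = open_gap
    al.extend_gap_score = extend_gap
    return al


@dataclass
class CloneAlignment:
    """Global alignment of one clone to the reference.

    ``ref_to_read`` maps every reference position covered by the
    alignment to the read base (or None at a read gap).  Identity counts
    bisulfite-equivalent matches (incl. ref C : read T) over alignment
    columns.
    """

    clone_id: str
    ref_to_read: dict[int, Optional[str]]
    identity: float
    n_columns: int
    orientation: str  # "forward" | "reverse"


@dataclass
class CloneCall:
    clone_id: str
    calls: tuple[str, ...]  # M / U / . per CpG site
    conversion_efficiency: Optional[float]
    identity: float
    qc_pass: bool


@dataclass
class MethylationMatrix:
    """QC-passing clones x CpG sites for one sample+tissue."""

    sample_id: str
    tissue: str
    genotype: str
    clone_ids: list[str]
    calls: np.ndarray = field(repr=False)  # dtype '<U1', rows x sites

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    def site_counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(n methylated, n unmethylated, n missing) per site."""
        return ((self.calls == MET).sum(axis=0),
                (self.calls == UNMET).sum(axis=0),
                (self.calls == MISSING).sum(axis=0))

    def percent_methylated(self) -> np.ndarray:
        """Per-site percent methylated over non-missing calls (NaN if none)."""
        m, u, _ = self.site_counts()
        denom = m + u
        with np.errstate(invalid="ignore"):
            return np.where(denom > 0, 100.0 * m / np.maximum(denom, 1), np.nan)


def bisulfite_convert_reference(ref: ReferenceRegion,
                                methylation_state: Sequence[bool]) -> str:
    """Expected bisulfite image of the reference for a methylation state.

    Every non-CpG C reads T; a CpG C reads C if methylated else T.
    """
    if len(methylation_state) != ref.n_sites:
        raise ValueError("state vector length must equal number of CpG sites")
    by_site = dict(zip(ref.cpg_sites, methylation_state))
    out = []
    for i, b in enumerate(ref.sequence):
        if b != "C":
            out.append(b)
        elif i in by_site:
            out.append("C" if by_site[i] else "T")
        else:
            out.append("T")
    return "".join(out)


def _alignment_maps(aln) -> tuple[dict[int, Optional[str]], float, int]:
    tpos, qpos = aln.indices
    target, query = str(aln.target), str(aln.query)
    ref_to_read: dict[int, Optional[str]] = {}
    matches = 0
    n_cols = len(tpos)
    for t, q in zip(tpos, qpos):
        t, q = int(t), int(q)
        if t >= 0:
            ref_to_read[t] = query[q] if q >= 0 else None
        if t >= 0 and q >= 0:
            tb, qb = target[t], query[q]
            if tb == qb or (tb == "C" and qb == "T"):
                matches += 1
    return ref_to_read, matches / n_cols if n_cols else 0.0, n_cols


def align_clone(clone_seq: str, ref: ReferenceRegion, clone_id: str = "clone",
                identity_floor: float = IDENTITY_FLOOR,
                aligner: Optional[Align.PairwiseAligner] = None) -> CloneAlignment:
    """Bisulfite-aware global alignment; tries both orientations.

    The orientation with the higher identity wins (forward on ties).
    Raises LowIdentityError when the best identity is below the
    non-target floor.
    """
    if not clone_seq or not ref.sequence:
        raise ValueError("empty sequence")
    if aligner is None:
        aligner = _bisulfite_aligner()
    clone_seq = clone_seq.upper()
    best = None
    for orientation, seq in (("forward", clone_seq),
                             ("reverse", str(Seq(clone_seq).reverse_complement()))):
        aln = aligner.align(ref.sequence, seq)[0]  # leftmost-gap convention
        ref_to_read, identity, n_cols = _alignment_maps(aln)
        cand = CloneAlignment(clone_id, ref_to_read, identity, n_cols, orientation)
        if best is None or cand.identity > best.identity:
            best = cand
    if best.identity < identity_floor:
        raise LowIdentityError(best.identity, identity_floor)
    return best


def call_cpgs(alignment: CloneAlignment, ref: ReferenceRegion) -> tuple[str, ...]:
    """Per-site call: read C = methylated, T = unmethylated, else missing."""
    calls = []
    for pos in ref.cpg_sites:
        base = alignment.ref_to_read.get(pos)
        if base == "C":
            calls.append(MET)
        elif base == "T":
            calls.append(UNMET)
        else:
            calls.append(MISSING)
    return tuple(calls)


def conversion_efficiency(alignment: CloneAlignment,
                          ref: ReferenceRegion) -> Optional[float]:
    """Fraction of covered non-CpG reference cytosines read as T.

    Returns None (clone flagged) if the alignment covers no non-CpG C.
    """
    covered = 0
    converted = 0
    for pos in ref.non_cpg_c_positions():
        base = alignment.ref_to_read.get(pos)
        if base is None:
            continue
        covered += 1
        if base == "T":
            converted += 1
    if covered == 0:
        return None
    return converted / covered


def process_clone(clone_id: str, clone_seq: str, ref: ReferenceRegion,
                  min_conversion: float = DEFAULT_MIN_CONVERSION,
                  min_identity: float = DEFAULT_MIN_IDENTITY,
                  aligner: Optional[Align.PairwiseAligner] = None) -> CloneCall:
    """Align, call and QC one clone; non-target clones fail QC outright."""
    try:
        aln = align_clone(clone_seq, ref, clone_id, aligner=aligner)
    except LowIdentityError as e:
        return CloneCall(clone_id, (MISSING,) * ref.n_sites, None, e.identity, False)
    calls = call_cpgs(aln, ref)
    eff = conversion_efficiency(aln, ref)
    qc = (eff is not None and eff >= min_conversion
          and aln.identity >= min_identity)
    return CloneCall(clone_id, calls, eff, aln.identity, qc)


def process_clones(records: Iterable[tuple[str, str]], ref: ReferenceRegion,
                   min_conversion: float = DEFAULT_MIN_CONVERSION,
                   min_identity: float = DEFAULT_MIN_IDENTITY) -> list[CloneCall]:
    aligner = _bisulfite_aligner()
    return [process_clone(name, seq, ref, min_conversion, min_identity, aligner)
            for name, seq in records]


def build_matrix(calls: Sequence[CloneCall], sample_id: str, tissue: str,
                 genotype: str, n_sites: int) -> MethylationMatrix:
    """Matrix over QC-passing clones only; errors if none pass."""
    passing = [c for c in calls if c.qc_pass]
    if not passing:
        n_lowconv = sum(1 for c in calls
                        if c.conversion_efficiency is not None
                        and not c.qc_pass)
        n_nontarget = sum(1 for c in calls if c.conversion_efficiency is None)
        raise ValueError(
            f"no QC-passing clones for {sample_id}/{tissue}: "
            f"{n_lowconv} failed conversion/identity thresholds, "
            f"{n_nontarget} rejected as non-target or unconvertible")
    arr = np.array([list(c.calls) for c in passing], dtype="<U1")
    if arr.shape[1] != n_sites:
        raise ValueError("call vector length mismatch")
    return MethylationMatrix(sample_id, tissue, genotype,
                             [c.clone_id for c in passing], arr)


# ---------------------------------------------------------------------------
# genotype comparisons


@dataclass
class SiteTest:
    """Per-CpG-site methylated/unmethylated x genotype chi-square test."""

    site: int  # 1-based, 5'->3'
    genotypes: tuple[str, ...]
    table: np.ndarray  # 2 x G: methylated / unmethylated counts
    statistic: Optional[float]
    df: Optional[int]
    p_value: Optional[float]
    computable: bool


def _chi_square(table: np.ndarray) -> tuple[float, int, float]:
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero margin")
    stat, p, df, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def compare_sites_by_genotype(matrices: Sequence[MethylationMatrix]) -> list[SiteTest]:
    """Per-site Pearson chi-square of methylated counts across genotypes.

    Clone calls are pooled over samples within genotype; missing calls are
    excluded.  Degenerate tables (zero margin) are marked not computable.
    """
    if not matrices:
        raise ValueError("no matrices")
    genotypes = tuple(sorted({m.genotype for m in matrices},
                             key=["GG", "GA", "AA"].index))
    if len(genotypes) < 2:
        raise ValueError("need >= 2 genotype groups")
    n_sites = matrices[0].n_sites
    out = []
    for s in range(n_sites):
        table = np.zeros((2, len(genotypes)), dtype=int)
        for m in matrices:
            gi = genotypes.index(m.genotype)
            col = m.calls[:, s]
            table[0, gi] += int((col == MET).sum())
            table[1, gi] += int((col == UNMET).sum())
        try:
            stat, df, p = _chi_square(table)
            out.append(SiteTest(s + 1, genotypes, table, stat, df, p, True))
        except DegenerateTableError:
            out.append(SiteTest(s + 1, genotypes, table, None, None, None, False))
    return out


def clone_sum_contingency(matrices: Sequence[MethylationMatrix],
                          bins: Optional[Sequence[Sequence[int]]] = None):
    """Clone-level methylated-CpG-sum x genotype contingency table.

    Each clone contributes its count of methylated CpGs (0..k).  ``bins``
    optionally groups sums into categories (e.g. [[0], [1, 2], [3, 4],
    [5, 6]]); default is one row per observed sum.  Returns (table as
    rows x genotypes ndarray, row labels, SiteTest-like result).
    """
    genotypes = tuple(sorted({m.genotype for m in matrices},
                             key=["GG", "GA", "AA"].index))
    sums_by_g: dict[str, list[int]] = {g: [] for g in genotypes}
    for m in matrices:
        sums_by_g[m.genotype].extend(
            int(x) for x in (m.calls == MET).sum(axis=1))
    k = matrices[0].n_sites
    if bins is None:
        observed = sorted({s for v in sums_by_g.values() for s in v})
        bins = [[s] for s in observed]
    labels = ["+".join(str(s) for s in b) for b in bins]
    table = np.zeros((len(bins), len(genotypes)), dtype=int)
    for gi, g in enumerate(genotypes):
        for s in sums_by_g[g]:
            for bi, b in enumerate(bins):
                if s in b:
                    table[bi, gi] += 1
                    break
    try:
        stat, df, p = _chi_square(table)
        res = SiteTest(0, genotypes, table, stat, df, p, True)
    except DegenerateTableError:
        res = SiteTest(0, genotypes, table, None, None, None, False)
    return table, labels, res


def lollipop(matrix: MethylationMatrix, filled: str = "●",
             empty: str = "○", missing: str = "·") -> str:
    """Text lollipop diagram: one row per clone, filled = methylated."""
    lines = [f"{matrix.sample_id} {matrix.tissue} ({matrix.genotype})"]
    for cid, row in zip(matrix.clone_ids, matrix.calls):
        glyphs = "".join(filled if c == MET else empty if c == UNMET else missing
                         for c in row)
        lines.append(f"  {glyphs}  {cid}")
    return "\n".join(lines)
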