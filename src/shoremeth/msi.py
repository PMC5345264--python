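"""Microsatellite instability classification (NCI fraction rule).

A tumour is MSI-high when >= 30% of evaluable markers are unstable,
MSI-low when 1-29% are unstable, and microsatellite stable when none
are.  At least four evaluable markers are required.  Fractions are
compared as exact rationals so the 30% boundary is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable

from .errors import InsufficientPanelError

MIN_EVALUABLE = 4
MSI_H_THRESHOLD = Fraction(3, 10)  # >= 30% unstable

MSS = "MSS"
MSI_L = "MSI-L"
MSI_H = "MSI-H"
STABLE_LOW = "MSS/MSI-L"  # binarized grouping for association analyses


@dataclass(frozen=True)
class MarkerResult:
    sample_id: str
    marker_name: str
    status: str  # stable | unstable | failed

    def __post_init__(self):
        if self.status not in ("stable", "unstable", "failed"):
            raise ValueError(f"unknown marker status {self.status!r}")


@dataclass(frozen=True)
class MSICall:
    sample_id: str
    n_evaluable: int
    fraction_unstable: Fraction
    msi_class: str


def classify_msi(markers: Iterable[MarkerResult]) -> MSICall:
    """Classify one sample's marker panel; failed markers are excluded."""
    markers = list(markers)
    if not markers:
        raise InsufficientPanelError("no markers provided")
    sample_ids = {m.sample_id for m in markers}
    if len(sample_ids) != 1:
        raise ValueError(f"markers span multiple samples: {sorted(sample_ids)}")
    names = [m.marker_name for m in markers]
    if len(names) != len(set(names)):
        raise ValueError("duplicate marker names for sample")
    evaluable = [m for m in markers if m.status != "failed"]
    if len(evaluable) < MIN_EVALUABLE:
        raise InsufficientPanelError(
            f"only {len(evaluable)} evaluable markers (< {MIN_EVALUABLE})")
    frac = Fraction(sum(m.status == "unstable" for m in evaluable), len(evaluable))
    if frac >= MSI_H_THRESHOLD:
        cls = MSI_H
    elif frac == 0:
        cls = MSS
    else:
        cls = MSI_L
    return MSICall(markers[0].sample_id, len(evaluable), frac, cls)


def binarize_for_association(call: MSICall) -> str:
    """Merge MSS with MSI-L, keeping MSI-H distinct."""
    return MSI_H if call.msi_class == MSI_H else STABLE_LOW
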