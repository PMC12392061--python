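"""Detection, group-completeness and expressed/non-expressed exclusivity calls.

An assay is *detected* in a sample when its Cq is numeric and falls inside the
reliable quantification window (inclusive at both ends; 15-30 cycles by
default).  Group statistics are only trusted when every replicate of the
group is detected: any failed read discards the assay from that group.  An
assay is *exclusively expressed* in one group of a comparison when every
replicate amplifies strongly (Cq below the expressed cut-off, 28 by default)
while every replicate of the other group is non-detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from evmir.cq_io import CqMatrix, SampleSheet

DEFAULT_LOWER_CQ = 15.0
DEFAULT_UPPER_CQ = 30.0
DEFAULT_EXPRESSED_CQ = 28.0

EXCLUSIVE_A = "exclusive_A"
EXCLUSIVE_B = "exclusive_B"
BOTH_EVALUABLE = "both_evaluable"
NEITHER = "neither"


@dataclass
class DetectionTable:
    """Per-cell detection flags plus per-group completeness and means."""

    cq: CqMatrix
    detected: pd.DataFrame  # bool, assays x samples
    lower_cq: float
    upper_cq: float
    # group-level fields, filled by group_complete()
    complete: pd.DataFrame | None = None  # bool, assays x groups
    group_mean: pd.DataFrame | None = None  # float, assays x groups (NaN if incomplete)
    n_detected: pd.DataFrame | None = None  # int, assays x groups
    sheet: SampleSheet | None = field(default=None, repr=False)

    @property
    def assay_ids(self) -> list[str]:
        return self.cq.assay_ids

    @property
    def sample_ids(self) -> list[str]:
        return self.cq.sample_ids

    def require_groups(self) -> None:
        if self.complete is None:
            raise ValueError("group-level fields not computed; run group_complete()")


def detection_call(
    cq: CqMatrix,
    lower_cq: float = DEFAULT_LOWER_CQ,
    upper_cq: float = DEFAULT_UPPER_CQ,
) -> DetectionTable:
    """Flag each (assay, sample) cell as detected or not.

    Detected iff the Cq is numeric and ``lower_cq <= Cq <= upper_cq``; the
    non-detection sentinel is always non-detected.  Total function: never
    raises on data content.
    """
    if not (0 < lower_cq < upper_cq <= 40):
        raise ValueError("need 0 < lower_cq < upper_cq <= 40")
    return DetectionTable(
        cq=cq,
        detected=cq.detected_mask(lower_cq, upper_cq),
        lower_cq=lower_cq,
        upper_cq=upper_cq,
    )


def group_complete(det: DetectionTable, sheet: SampleSheet) -> DetectionTable:
    """Fill group-level completeness, mean Cq and detected counts.

    An assay is complete in a (cell_type, compartment) group iff *all* its
    replicates are detected; the group mean Cq is computed only then.
    """
    sheet.validate_against(det.cq)
    groups = sheet.groups()
    complete = {}
    means = {}
    counts = {}
    for g in groups:
        members = sheet.group_members(g)
        if len(members) < 1:
            raise ValueError(f"group {g} has no samples")
        d = det.detected[members]
        v = det.cq.values[members]
        comp = d.all(axis=1)
        complete[g] = comp
        counts[g] = d.sum(axis=1).astype(int)
        means[g] = v.mean(axis=1).where(comp)
    det.complete = pd.DataFrame(complete)
    det.group_mean = pd.DataFrame(means)
    det.n_detected = pd.DataFrame(counts)
    det.sheet = sheet
    return det


@dataclass
class ExclusivityCall:
    """Expressed/non-expressed outcome of one assay in a two-group comparison."""

    assay_id: str
    group_a: str
    group_b: str
    status: str  # EXCLUSIVE_A | EXCLUSIVE_B | BOTH_EVALUABLE | NEITHER


def exclusivity_call(
    det: DetectionTable,
    group_a: str,
    group_b: str,
    expressed_cq: float = DEFAULT_EXPRESSED_CQ,
    per_replicate: bool = True,
) -> list[ExclusivityCall]:
    """Classify every assay of a comparison as exclusive to one group or not.

    Default (``per_replicate=True``) applies the strict reading: exclusive to
    A iff every A replicate has Cq < ``expressed_cq`` and every B replicate is
    non-detected.  ``per_replicate=False`` evaluates the Cq criterion on the
    group mean instead (the group must still be complete and the other group
    fully non-detected).
    """
    det.require_groups()
    if expressed_cq >= det.upper_cq:
        raise ValueError("expressed_cq must be below the detection upper bound")
    sheet = det.sheet
    mem_a = sheet.group_members(group_a)
    mem_b = sheet.group_members(group_b)
    if not mem_a or not mem_b:
        raise ValueError("both groups must have annotated samples")

    cq_a = det.cq.values[mem_a].to_numpy()
    cq_b = det.cq.values[mem_b].to_numpy()
    det_a = det.detected[mem_a].to_numpy()
    det_b = det.detected[mem_b].to_numpy()
    none_det_a = ~det_a.any(axis=1)
    none_det_b = ~det_b.any(axis=1)
    if per_replicate:
        with np.errstate(invalid="ignore"):
            strong_a = np.all(np.nan_to_num(cq_a, nan=np.inf) < expressed_cq, axis=1)
            strong_b = np.all(np.nan_to_num(cq_b, nan=np.inf) < expressed_cq, axis=1)
    else:
        comp_a = det.complete[group_a].to_numpy()
        comp_b = det.complete[group_b].to_numpy()
        mean_a = det.group_mean[group_a].to_numpy()
        mean_b = det.group_mean[group_b].to_numpy()
        with np.errstate(invalid="ignore"):
            strong_a = comp_a & (np.nan_to_num(mean_a, nan=np.inf) < expressed_cq)
            strong_b = comp_b & (np.nan_to_num(mean_b, nan=np.inf) < expressed_cq)
    exc_a = strong_a & none_det_b
    exc_b = strong_b & none_det_a
    both = (
        det.complete[group_a].to_numpy() & det.complete[group_b].to_numpy()
    )
    status = np.where(exc_a, EXCLUSIVE_A,
                      np.where(exc_b, EXCLUSIVE_B,
                               np.where(both, BOTH_EVALUABLE, NEITHER)))
    return [
        ExclusivityCall(assay, group_a, group_b, st)
        for assay, st in zip(det.assay_ids, status, strict=True)
    ]


def detected_in_all(det: DetectionTable) -> set[str]:
    """Assays detected in every sample of the dataset."""
    mask = det.detected.all(axis=1)
    return set(det.detected.index[mask])


def detection_fraction(det: DetectionTable, sample_ids=None) -> float:
    """Fraction of (assay, sample) cells detected, over the given samples."""
    d = det.detected if sample_ids is None else det.detected[list(sample_ids)]
    return float(np.mean(d.to_numpy())) if d.size else float("nan")
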