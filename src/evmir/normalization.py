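"""Global-mean normalization of Cq values.

Each sample's mean Cq over a normalizer set — the assays detected in every
sample of the dataset — is subtracted from that sample's Cq values:

    expr(g, j) = mean_{n in norm_set} Cq(n, j)  -  Cq(g, j)

One Cq cycle is one log2 unit of template abundance, so ``expr`` is log2
relative expression with the sign chosen so that larger means more abundant,
and log2 fold change between groups is a plain difference of group means.
Non-detected cells stay undefined (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from evmir.cq_io import CqMatrix
from evmir.detection import DetectionTable, detected_in_all


@dataclass
class NormalizedMatrix:
    """Log2 relative expression per (assay, sample); NaN where non-detected."""

    expr: pd.DataFrame
    normalizer_set: set[str]
    sample_means: pd.Series  # per-sample mean Cq over the normalizer set

    @property
    def assay_ids(self) -> list[str]:
        return list(self.expr.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expr.columns)


def normalizer_set(det: DetectionTable) -> set[str]:
    """Assays detected in all samples; hard error if there are none."""
    s = detected_in_all(det)
    if not s:
        raise ValueError("no consistently detected assays; cannot normalize")
    return s


def global_mean_normalize(
    cq: CqMatrix, det: DetectionTable, norm_set: set[str] | None = None
) -> NormalizedMatrix:
    """Subtract each sample's normalizer-set mean Cq from its Cq values.

    ``norm_set`` defaults to the assays detected in all samples.  Every
    normalizer assay must be detected in every sample (hard error otherwise).
    """
    if norm_set is None:
        norm_set = normalizer_set(det)
    norm_ids = [a for a in cq.assay_ids if a in norm_set]
    if not norm_ids:
        raise ValueError("normalizer set is empty")
    missing = set(norm_set) - set(norm_ids)
    if missing:
        raise ValueError(f"normalizer assays not in matrix: {sorted(missing)}")
    nd = ~det.detected.loc[norm_ids]
    if nd.any().any():
        bad = [
            (a, s)
            for a in norm_ids
            for s in det.sample_ids
            if nd.loc[a, s]
        ]
        raise ValueError(f"normalizer assay non-detected in some sample: {bad[:5]}")
    sample_means = cq.values.loc[norm_ids].mean(axis=0)
    expr = sample_means - cq.values  # broadcast over rows
    expr = expr.where(det.detected)  # undefined where non-detected
    return NormalizedMatrix(expr=expr, normalizer_set=set(norm_ids),
                            sample_means=sample_means)
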