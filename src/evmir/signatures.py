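"""Comparison catalog, Venn partitions and EV-enrichment signatures.

The profiling design yields nine ordered two-group comparisons: the three
intracellular cell-type pairs, the three EV cell-type pairs, and the three
EV-vs-intracellular contrasts within each cell type.  From the within-type
EV contrasts, assays are classified into EV signature sets:

* per-type EV-enriched (statistically up in EV vs own intracellular),
* per-type EV-exclusive (expressed in EV, non-detected intracellularly),
* population-specific (EV-associated in exactly one cell type),
* shared-neural (EV-associated in both NSC and FPP but not PSC), and
* universal (EV-associated in all three cell types).

"EV-associated" counts either statistical enrichment or exclusivity, since
categorical exclusivity is the stronger form of the same loading pattern.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from evmir.cq_io import SampleSheet
from evmir.detection import (
    EXCLUSIVE_A,
    EXCLUSIVE_B,
    DetectionTable,
    exclusivity_call,
)
from evmir.diffexp import (
    DEFAULT_ALPHA,
    DEFAULT_FC,
    UP_A,
    UP_B,
    ContrastResult,
    ModerationParams,
    run_contrast,
)
from evmir.normalization import NormalizedMatrix

CELL_TYPES = ("PSC", "NSC", "FPP")

#: The nine ordered comparisons of the profiling design.
STANDARD_COMPARISONS = (
    ("PSC:IN", "NSC:IN"),
    ("PSC:IN", "FPP:IN"),
    ("NSC:IN", "FPP:IN"),
    ("PSC:EV", "NSC:EV"),
    ("PSC:EV", "FPP:EV"),
    ("NSC:EV", "FPP:EV"),
    ("PSC:EV", "PSC:IN"),
    ("NSC:EV", "NSC:IN"),
    ("FPP:EV", "FPP:IN"),
)


@dataclass
class ComparisonCatalog:
    """All pairwise contrasts of the design, keyed by ``"A|B"`` labels."""

    contrasts: dict[str, ContrastResult]

    @staticmethod
    def key(group_a: str, group_b: str) -> str:
        return f"{group_a}|{group_b}"

    def get(self, group_a: str, group_b: str) -> ContrastResult:
        return self.contrasts[self.key(group_a, group_b)]

    def counts(self) -> dict[str, dict[str, int]]:
        return {k: c.status_counts() for k, c in self.contrasts.items()}


@dataclass
class SignatureSets:
    """Named EV-signature miRNA sets across the three cell populations."""

    ev_enriched: dict[str, set[str]]  # statistically up in EV vs own IN
    ev_exclusive: dict[str, set[str]]  # expressed in EV, non-detected in IN
    population_specific: dict[str, set[str]] = field(default_factory=dict)
    shared_neural: set[str] = field(default_factory=set)
    universal: set[str] = field(default_factory=set)
    universal_enriched: set[str] = field(default_factory=set)

    def ev_associated(self, cell_type: str) -> set[str]:
        return self.ev_enriched[cell_type] | self.ev_exclusive[cell_type]

    def sizes(self) -> dict[str, int]:
        out = {f"ev_enriched_{ct}": len(self.ev_enriched[ct]) for ct in self.ev_enriched}
        out.update(
            {f"ev_exclusive_{ct}": len(self.ev_exclusive[ct]) for ct in self.ev_exclusive}
        )
        out.update(
            {f"specific_{ct}": len(s) for ct, s in self.population_specific.items()}
        )
        out["shared_neural"] = len(self.shared_neural)
        out["universal"] = len(self.universal)
        out["universal_enriched"] = len(self.universal_enriched)
        return out


def build_catalog(
    norm: NormalizedMatrix,
    det: DetectionTable,
    sheet: SampleSheet,
    comparisons=STANDARD_COMPARISONS,
    expressed_cq: float = 28.0,
    fc_threshold: float = DEFAULT_FC,
    alpha: float = DEFAULT_ALPHA,
    moderation: ModerationParams | None = None,
) -> ComparisonCatalog:
    """Run exclusivity + differential expression for every ordered comparison."""
    contrasts: dict[str, ContrastResult] = {}
    seen = set()
    for group_a, group_b in comparisons:
        pair = (group_a, group_b)
        if pair in seen:
            raise ValueError(f"duplicate comparison {pair}")
        seen.add(pair)
        excl = exclusivity_call(det, group_a, group_b, expressed_cq=expressed_cq)
        res = run_contrast(
            norm,
            sheet,
            group_a,
            group_b,
            exclusivity=excl,
            moderation=moderation,
            fc_threshold=fc_threshold,
            alpha=alpha,
        )
        contrasts[ComparisonCatalog.key(group_a, group_b)] = res
    return ComparisonCatalog(contrasts)


def venn_partition(set_a: set, set_b: set) -> tuple[int, int, int]:
    """Sizes of (A only, B only, A and B); they sum to ``|A | B|``."""
    set_a, set_b = set(set_a), set(set_b)
    both = set_a & set_b
    return len(set_a - both), len(set_b - both), len(both)


_MIR_PREFIX = re.compile(r"^hsa-", flags=re.IGNORECASE)


def canonical_mirna(name: str) -> str:
    """Canonical miRNA name: lowercase, optional "hsa-" prefix stripped.

    Arm suffixes (-5p/-3p) are preserved; "hsa-miR-137" and "miR-137" map to
    the same key.
    """
    return _MIR_PREFIX.sub("", name.strip()).lower()


def intersect_named_sets(list1, list2) -> set[str]:
    """Exact intersection of two miRNA name collections after canonicalization."""
    return {canonical_mirna(n) for n in list1} & {canonical_mirna(n) for n in list2}


def classify_ev_signatures(
    catalog: ComparisonCatalog,
    cell_types=CELL_TYPES,
    shared_neural_definition: str = "ev_vs_in",
) -> SignatureSets:
    """Classify EV cargo signatures from the within-type EV-vs-IN contrasts.

    Requires the three contrasts ``CT:EV`` vs ``CT:IN``; raises if any is
    missing.  Universal membership counts enrichment or exclusivity in all
    three types; ``universal_enriched`` is the stricter enrichment-only set.
    Population-specific sets contain assays EV-associated in exactly one type.

    The shared-neural set has two readings and both are exposed:
    ``"ev_vs_in"`` (default) takes assays EV-associated vs their own cells in
    both neural types but not in PSC; ``"vs_psc_ev"`` takes assays up or
    exclusive in both NSC EVs and FPP EVs relative to PSC EVs (requires the
    ``PSC:EV`` vs ``NSC:EV``/``FPP:EV`` contrasts in the catalog).
    """
    enriched: dict[str, set[str]] = {}
    exclusive: dict[str, set[str]] = {}
    for ct in cell_types:
        key = ComparisonCatalog.key(f"{ct}:EV", f"{ct}:IN")
        if key not in catalog.contrasts:
            raise ValueError(f"missing EV-vs-IN comparison for {ct}")
        res = catalog.contrasts[key]
        enriched[ct] = res.assays_with_status(UP_A)
        exclusive[ct] = res.assays_with_status(EXCLUSIVE_A)
    associated = {ct: enriched[ct] | exclusive[ct] for ct in cell_types}
    universal = set.intersection(*associated.values())
    universal_enriched = set.intersection(*(enriched[ct] for ct in cell_types))
    neural = [ct for ct in cell_types if ct != "PSC"]
    if shared_neural_definition == "ev_vs_in":
        shared_neural = (
            set.intersection(*(associated[ct] for ct in neural))
            - associated["PSC"]
        )
    elif shared_neural_definition == "vs_psc_ev":
        per_type = []
        for ct in neural:
            key = ComparisonCatalog.key("PSC:EV", f"{ct}:EV")
            if key not in catalog.contrasts:
                raise ValueError(f"missing PSC:EV vs {ct}:EV comparison")
            res = catalog.contrasts[key]
            per_type.append(res.assays_with_status(UP_B, EXCLUSIVE_B))
        shared_neural = set.intersection(*per_type)
    else:
        raise ValueError(
            f"unknown shared_neural_definition {shared_neural_definition!r}"
        )
    specific = {}
    for ct in cell_types:
        others = set().union(*(associated[o] for o in cell_types if o != ct))
        specific[ct] = associated[ct] - others
    return SignatureSets(
        ev_enriched=enriched,
        ev_exclusive=exclusive,
        population_specific=specific,
        shared_neural=shared_neural,
        universal=universal,
        universal_enriched=universal_enriched,
    )
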