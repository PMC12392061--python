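"""Over-representation analysis of predicted miRNA targets.

Targets of a query miRNA set are pooled (set union) from a user-supplied
miRNA-to-gene mapping table and tested against gene-to-pathway sets with the
one-sided hypergeometric tail: for a universe of N genes, a pathway of K
genes and a query of n genes overlapping in k,

    p = sum_{i=k..min(K,n)} C(K,i) C(N-K, n-i) / C(N, n)

with Benjamini-Hochberg adjustment across pathways.  Only over-representation
is tested (no depletion).
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy import stats

from evmir.diffexp import bh_adjust


def mirna_target_union(mirnas, targets: pd.DataFrame) -> set[str]:
    """Union of predicted target genes over a set of query miRNAs.

    ``targets`` has the miRNA id in its first column and the gene id in its
    second.  Query miRNAs absent from the table are reported with a warning,
    not an error.  An empty mapping table is a hard error.
    """
    if targets.empty:
        raise ValueError("empty miRNA-target mapping table")
    mir_col, gene_col = targets.columns[:2]
    by_mirna = targets.groupby(targets[mir_col].astype(str))[gene_col]
    index = {m: set(g.astype(str)) for m, g in by_mirna}
    union: set[str] = set()
    missing = []
    for m in mirnas:
        if m in index:
            union |= index[m]
        else:
            missing.append(m)
    if missing:
        warnings.warn(
            f"miRNAs absent from target table: {sorted(missing)}", stacklevel=2
        )
    return union


def hypergeometric_ora(
    query: set[str],
    pathways: pd.DataFrame,
    universe: set[str] | None = None,
    min_score: float | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene set against pathway sets.

    ``pathways`` has gene id in its first column and pathway id in its
    second; an optional third column carries the pathway name, and a numeric
    ``score`` column, when present, can be filtered with ``min_score``.
    ``universe`` defaults to all genes in the pathway table; query genes
    outside it are dropped with a warning.  Results are sorted by adjusted p.
    """
    if pathways.empty:
        raise ValueError("empty pathway table")
    if min_score is not None and "score" in pathways.columns:
        pathways = pathways[pathways["score"] >= min_score]
    gene_col, pw_col = pathways.columns[:2]
    name_col = None
    extra = [c for c in pathways.columns[2:] if c != "score"]
    if extra:
        name_col = extra[0]
    if universe is None:
        universe = set(pathways[gene_col].astype(str))
    universe = set(universe)
    n_universe = len(universe)
    query = set(query)
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped",
            stacklevel=2,
        )
    query &= universe
    rows = []
    for pw, sub in pathways.groupby(pathways[pw_col].astype(str)):
        genes = set(sub[gene_col].astype(str)) & universe
        if len(genes) > n_universe:
            raise ValueError(f"pathway {pw} larger than universe")
        overlap = sorted(query & genes)
        k, big_k, n = len(overlap), len(genes), len(query)
        if big_k == 0 or n == 0:
            continue
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n))
        rows.append(
            {
                "pathway_id": pw,
                "pathway_name": str(sub[name_col].iloc[0]) if name_col else pw,
                "universe_size": n_universe,
                "pathway_size": big_k,
                "query_size": n,
                "overlap": k,
                "p": min(p, 1.0),
                "overlap_genes": ",".join(overlap),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("adj_p", kind="mergesort").reset_index(drop=True)
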