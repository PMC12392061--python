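"""ddCt relative quantification of validation mRNA targets.

Per sample, the target Ct is referenced to the arithmetic mean of the two
housekeeping genes (ACTB and GUSB by default):

    dCt  = Ct_target - mean(Ct_ACTB, Ct_GUSB)
    ddCt = dCt - mean dCt of the calibrator group
    FC   = 2 ** (-ddCt)

The arithmetic mean of reference Ct values equals the geometric mean of
their linear quantities, the standard aggregation for multiple references.
Group comparisons are Welch (unequal-variance) t-tests on the log2 scale,
corrected across genes with the Holm-Sidak step-down procedure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_REFS = ("ACTB", "GUSB")


def _pivot_ct(ct: pd.DataFrame) -> pd.DataFrame:
    required = {"gene", "sample_id", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return ct.pivot_table(index="gene", columns="sample_id", values="ct",
                          aggfunc="mean")


def delta_delta_ct(
    ct: pd.DataFrame,
    groups: dict[str, str],
    calibrator: str,
    refs=DEFAULT_REFS,
) -> pd.DataFrame:
    """Per-(gene, sample) dCt, ddCt and fold change against a calibrator group.

    Parameters
    ----------
    ct : long-format table with columns gene, sample_id, ct (cycles).
    groups : sample_id -> group label; every sample must be mapped.
    calibrator : group whose mean dCt anchors ddCt = 0 (so its
        geometric-mean fold change is 1).
    refs : reference genes averaged per sample; both must be measured in
        every sample (hard error naming the sample otherwise).

    Returns a long-format table with columns gene, sample_id, group, ct,
    ref_mean_ct, dct, ddct, fold_change.
    """
    wide = _pivot_ct(ct)
    missing_refs = [r for r in refs if r not in wide.index]
    if missing_refs:
        raise ValueError(f"reference genes missing from Ct table: {missing_refs}")
    ref_block = wide.loc[list(refs)]
    bad = ref_block.columns[ref_block.isna().any(axis=0)].tolist()
    if bad:
        raise ValueError(f"missing reference Ct in samples: {bad}")
    unmapped = [s for s in wide.columns if s not in groups]
    if unmapped:
        raise ValueError(f"samples without a group label: {unmapped}")
    group_of = pd.Series({s: groups[s] for s in wide.columns})
    if calibrator not in set(group_of):
        raise ValueError(f"calibrator group {calibrator!r} has no samples")

    ref_mean = ref_block.mean(axis=0)
    targets = [g for g in wide.index if g not in refs]
    dct = wide.loc[targets] - ref_mean  # broadcast per sample
    cal_samples = group_of.index[group_of == calibrator]
    cal_mean_dct = dct[cal_samples].mean(axis=1)
    ddct = dct.sub(cal_mean_dct, axis=0)
    fc = np.exp2(-ddct)

    frames = {"ct": wide.loc[targets], "dct": dct, "ddct": ddct,
              "fold_change": fc}
    parts = [df.stack(future_stack=True).rename(name) for name, df in frames.items()]
    long = pd.concat(parts, axis=1).reset_index()
    long = long.rename(columns={long.columns[0]: "gene",
                                long.columns[1]: "sample_id"})
    long["ref_mean_ct"] = long["sample_id"].map(ref_mean)
    long["group"] = long["sample_id"].map(group_of)
    cols = ["gene", "sample_id", "group", "ct", "ref_mean_ct", "dct", "ddct",
            "fold_change"]
    return long[cols]


def compare_groups(
    ddct: pd.DataFrame, group_a: str, group_b: str
) -> pd.DataFrame:
    """Per-gene Welch t-test on log2 fold change (= -ddCt) between two groups.

    Requires >= 2 samples per group per gene.  Degenerate genes with zero
    variance in both groups and equal means get p = 1.  Returns a table with
    per-group mean fold change +/- SEM and the raw two-sided p-value.
    """
    rows = []
    for gene, sub in ddct.groupby("gene", sort=False):
        xa = -sub.loc[sub["group"] == group_a, "ddct"].to_numpy(dtype=float)
        xb = -sub.loc[sub["group"] == group_b, "ddct"].to_numpy(dtype=float)
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"gene {gene}: need >= 2 samples per group")
        if np.var(xa) == 0 and np.var(xb) == 0:
            p = 1.0 if np.mean(xa) == np.mean(xb) else 0.0
        else:
            p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
        fca = np.exp2(xa)
        fcb = np.exp2(xb)
        rows.append(
            {
                "gene": gene,
                f"mean_fc_{group_a}": float(np.mean(fca)),
                f"sem_fc_{group_a}": float(stats.sem(fca)) if len(fca) > 1 else np.nan,
                f"mean_fc_{group_b}": float(np.mean(fcb)),
                f"sem_fc_{group_b}": float(stats.sem(fcb)) if len(fcb) > 1 else np.nan,
                "log2fc_diff": float(np.mean(xa) - np.mean(xb)),
                "p": p,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def holm_sidak_adjust(p, alpha: float = 0.05) -> pd.DataFrame:
    """Holm-Sidak step-down adjusted p-values and reject flags.

    Sort ascending; at rank i (1-based) of m tests the Sidak-adjusted value
    is 1 - (1 - p_(i))^(m - i + 1), made monotone by a running maximum, then
    clipped at 1.  Rejection: adjusted p <= alpha, mapped back to input order.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    adj_sorted = 1.0 - (1.0 - sorted_p) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj = np.empty(m)
    adj[order] = np.clip(adj_sorted, 0.0, 1.0)
    return pd.DataFrame({"p": p, "adj_p": adj, "reject": adj <= alpha})
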