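"""Two-group differential expression with an empirical-Bayes moderated t.

Per assay g, with group sizes n_A and n_B and residual degrees of freedom
d_g = n_A + n_B - 2, the pooled variance s_g^2 (log2^2 units) is shrunk
toward a prior variance s0^2 with prior degrees of freedom d0:

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t_g    = log2FC_g / sqrt(s~_g^2 * (1/n_A + 1/n_B))

with a two-sided p-value from Student's t on d0 + d_g degrees of freedom.
(d0, s0^2) are estimated by marginal moment matching: under the scaled-F
model s_g^2 ~ s0^2 F(d_g, d0), the mean and variance of log s_g^2 have
closed forms in digamma/trigamma, and the trigamma equation for d0 is solved
with a Newton iteration.  d0 = 0 recovers the classical pooled two-sample t;
d0 = +inf fixes every variance at s0^2.

Assays that are not complete (per detection) in both groups are excluded
from the test and routed to the exclusivity call or flagged not evaluable.
Multiple testing uses step-up Benjamini-Hochberg FDR, and the final call
combines adjusted p <= alpha with a linear fold-change threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from evmir.cq_io import SampleSheet
from evmir.detection import (
    BOTH_EVALUABLE,
    EXCLUSIVE_A,
    EXCLUSIVE_B,
    ExclusivityCall,
)
from evmir.normalization import NormalizedMatrix

UP_A = "up_A"
UP_B = "up_B"
NS = "ns"
NOT_EVALUABLE = "not_evaluable"

DEFAULT_FC = 1.5
DEFAULT_ALPHA = 0.05


@dataclass
class GroupStats:
    """Per-assay two-group summaries for one ordered contrast (A minus B)."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    table: pd.DataFrame  # index assay; mean_a, mean_b, log2fc, var_a, var_b, s2
    tested: list[str]  # assays complete in both groups (rows of `table`)
    untested: list[str]  # assays excluded from the statistical test

    @property
    def residual_df(self) -> int:
        return self.n_a + self.n_b - 2


@dataclass
class ModerationParams:
    """Empirical-Bayes prior: d0 degrees of freedom and prior variance s0^2."""

    d0: float  # may be math.inf
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0")
        if not (self.s0_sq > 0) and self.d0 != 0:
            raise ValueError("s0_sq must be positive")


@dataclass
class ContrastResult:
    """Full outcome of one two-group comparison.

    ``table`` holds one row per assay with columns log2fc, fc_linear, t, df,
    p, adj_p and status in {up_A, up_B, ns, exclusive_A, exclusive_B,
    not_evaluable}.  Exclusive statuses carry no t/p.
    """

    group_a: str
    group_b: str
    table: pd.DataFrame
    moderation: ModerationParams | None = None

    def status_counts(self) -> dict[str, int]:
        return self.table["status"].value_counts().to_dict()

    def assays_with_status(self, *statuses: str) -> set[str]:
        sel = self.table["status"].isin(statuses)
        return set(self.table.index[sel])


def fit_group_stats(
    norm: NormalizedMatrix, sheet: SampleSheet, group_a: str, group_b: str
) -> GroupStats:
    """Group means, pooled variances and log2FC for assays complete in both groups.

    Completeness is read off the missingness pattern of the normalized
    matrix: an assay is complete in a group iff every replicate has a defined
    expression value.
    """
    mem_a = sheet.group_members(group_a)
    mem_b = sheet.group_members(group_b)
    if len(mem_a) < 2 or len(mem_b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    ea = norm.expr[mem_a]
    eb = norm.expr[mem_b]
    complete = ea.notna().all(axis=1) & eb.notna().all(axis=1)
    tested = list(norm.expr.index[complete])
    untested = list(norm.expr.index[~complete])
    n_a, n_b = len(mem_a), len(mem_b)
    dg = n_a + n_b - 2
    sub_a = ea.loc[tested]
    sub_b = eb.loc[tested]
    mean_a = sub_a.mean(axis=1)
    mean_b = sub_b.mean(axis=1)
    var_a = sub_a.var(axis=1, ddof=1)
    var_b = sub_b.var(axis=1, ddof=1)
    s2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / dg
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": mean_a - mean_b,
            "var_a": var_a,
            "var_b": var_b,
            "s2": s2,
        }
    )
    return GroupStats(group_a, group_b, n_a, n_b, table, tested, untested)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    if y <= 0:
        raise ValueError("trigamma_inverse needs y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < 1e-10:
            break
    return x


def estimate_moderation(s2, d_g: float, min_assays: int = 10) -> ModerationParams:
    """Moment-match the scaled-F model to observed log variances.

    ``s2`` are per-assay pooled variances sharing residual df ``d_g``.  Zero
    variances are excluded from the fit (they carry no information about the
    prior on the log scale); all-zero input is a hard error.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size == 0:
        raise ValueError("all variances are zero; cannot estimate a prior")
    if pos.size < min_assays:
        raise ValueError(f"need at least {min_assays} positive variances")
    half = d_g / 2.0
    e = np.log(pos) - special.digamma(half) + math.log(half)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, half))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        # no excess spread beyond sampling noise: variances are exchangeable
        # and the prior is their plain average
        d0 = math.inf
        s0_sq = float(np.mean(s2))
    return ModerationParams(d0=d0, s0_sq=s0_sq)


def _posterior_s2(s2: np.ndarray, d_g: float, mod: ModerationParams) -> np.ndarray:
    if math.isinf(mod.d0):
        return np.full_like(s2, mod.s0_sq)
    if mod.d0 == 0:
        return s2.copy()
    return (mod.d0 * mod.s0_sq + d_g * s2) / (mod.d0 + d_g)


def moderated_t_arrays(
    log2fc, s2, n_a: int, n_b: int, mod: ModerationParams
) -> tuple[np.ndarray, np.ndarray, float]:
    """Vectorized moderated t and two-sided p; returns (t, p, total_df)."""
    log2fc = np.asarray(log2fc, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    d_g = n_a + n_b - 2
    s2_post = _posterior_s2(s2, d_g, mod)
    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / se
    df_total = mod.d0 + d_g
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), df=df_total), np.nan)
    # zero fold change over zero spread is a well-defined null point
    p = np.where((log2fc == 0) & (se == 0), 1.0, p)
    t = np.where((log2fc == 0) & (se == 0), 0.0, t)
    return t, p, df_total


def moderated_t_contrast(stats_: GroupStats, mod: ModerationParams) -> ContrastResult:
    """Apply the moderated t to every tested assay of a contrast."""
    tab = stats_.table
    t, p, df_total = moderated_t_arrays(
        tab["log2fc"].to_numpy(), tab["s2"].to_numpy(), stats_.n_a, stats_.n_b, mod
    )
    out = pd.DataFrame(index=tab.index)
    out["log2fc"] = tab["log2fc"]
    out["fc_linear"] = np.exp2(np.abs(tab["log2fc"])) * np.sign(tab["log2fc"]).replace(0, 1)
    out["t"] = t
    out["df"] = df_total
    out["p"] = p
    out["adj_p"] = np.nan
    out["status"] = pd.NA
    valid = out["p"].notna()
    if valid.any():
        out.loc[valid, "adj_p"] = bh_adjust(out.loc[valid, "p"].to_numpy())
    # extend with untested assays so every assay appears exactly once
    if stats_.untested:
        extra = pd.DataFrame(index=pd.Index(stats_.untested, name=tab.index.name))
        out = pd.concat([out, extra])
    return ContrastResult(stats_.group_a, stats_.group_b, out, moderation=mod)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.clip(adj_sorted, 0.0, 1.0)
    return adj


def call_de(
    res: ContrastResult,
    exclusivity: list[ExclusivityCall] | None = None,
    fc_threshold: float = DEFAULT_FC,
    alpha: float = DEFAULT_ALPHA,
) -> ContrastResult:
    """Fill the status column from thresholds and exclusivity calls.

    up_A iff adjusted p <= alpha and log2FC >= log2(fc_threshold); up_B is
    symmetric.  An exclusivity pattern overrides any statistical status and
    clears t/p (the assay was never a valid test).  Assays that are neither
    testable nor exclusive are not evaluable.
    """
    if fc_threshold <= 0 or alpha <= 0:
        raise ValueError("thresholds must be positive")
    lfc = math.log2(fc_threshold)
    tab = res.table
    status = pd.Series(NOT_EVALUABLE, index=tab.index, dtype=object)
    testable = tab["p"].notna()
    status[testable] = NS
    sig = testable & (tab["adj_p"] <= alpha)
    status[sig & (tab["log2fc"] >= lfc)] = UP_A
    status[sig & (tab["log2fc"] <= -lfc)] = UP_B
    if exclusivity:
        for call in exclusivity:
            if call.assay_id not in tab.index:
                continue
            if call.status == EXCLUSIVE_A:
                status[call.assay_id] = EXCLUSIVE_A
            elif call.status == EXCLUSIVE_B:
                status[call.assay_id] = EXCLUSIVE_B
        excl = status.isin([EXCLUSIVE_A, EXCLUSIVE_B])
        tab.loc[excl, ["t", "p", "adj_p", "df"]] = np.nan
    tab["status"] = status
    return res


def run_contrast(
    norm: NormalizedMatrix,
    sheet: SampleSheet,
    group_a: str,
    group_b: str,
    exclusivity: list[ExclusivityCall] | None = None,
    moderation: ModerationParams | None = None,
    fc_threshold: float = DEFAULT_FC,
    alpha: float = DEFAULT_ALPHA,
) -> ContrastResult:
    """Fit, moderate, test, adjust and call one ordered two-group contrast."""
    gstats = fit_group_stats(norm, sheet, group_a, group_b)
    if moderation is None:
        moderation = estimate_moderation(
            gstats.table["s2"].to_numpy(), gstats.residual_df
        )
    res = moderated_t_contrast(gstats, moderation)
    return call_de(res, exclusivity, fc_threshold=fc_threshold, alpha=alpha)
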