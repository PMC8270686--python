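"""Moderated two-group differential expression and the five-level gene status.

The moderated t follows the empirical-Bayes formulation: gene-wise residual
variances s_g^2 (pooled two-sample, df = n_a + n_b - 2) are assumed to be
drawn from a scaled-inverse-chi-square prior with d0 degrees of freedom and
scale s0^2.  The prior is fitted by method of moments on log s^2 using the
digamma/trigamma moments of the log chi-square distribution, the posterior
variance is the precision-weighted blend

    s~_g^2 = (d0 s0^2 + df s_g^2) / (d0 + df),

and the moderated t = logFC / (s~ sqrt(1/n_a + 1/n_b)) is referred to a t
distribution on df + d0 degrees of freedom.

Status calls per gene and comparison use the thresholds adjusted p < 0.05
("significant"), |log2 fold change| >= 1 on top of significance
("differentially expressed", split by sign), and local FDR > 0.95
("unchanged"); everything else is the "uncertain" gray area.  Precedence is
DE > SIGNIFICANT > UNCHANGED > UNCERTAIN, and rule conflicts (a gene both
DE/significant and lfdr-unchanged) are counted rather than silently
resolved.

The local FDR estimator is pi0 (Storey, lambda = 0.5) over the Grenander
(decreasing-density) estimate of the p-value density:
lfdr(p) = min(1, pi0 / f_hat(p)), which is non-decreasing in p.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ExpressionMatrix, ProbeAnnotation, ValidationError

logger = logging.getLogger("thydex")

STATUS_LEVELS = ("DE_UP", "DE_DOWN", "SIGNIFICANT", "UNCHANGED", "UNCERTAIN")

DEFAULT_ALPHA = 0.05
DEFAULT_LFC_MIN = 1.0      # log2 units: "at least twofold"
DEFAULT_LFDR_MIN = 0.95
MIN_FEATURES_FOR_MODERATION = 10
MIN_P_FOR_LFDR = 100


@dataclasses.dataclass
class ComparisonResult:
    """Per-feature statistics for one group-vs-group contrast.

    ``table`` is indexed by feature with columns logFC, mean_a, mean_b, s2,
    df, t, p, adj_p, lfdr, var_floored.  logFC is first-named group minus
    second-named.
    """

    comparison_id: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    table: pd.DataFrame
    d0: float
    s0sq: float
    pi0: float


# ---------------------------------------------------------------------------
# empirical-Bayes variance prior
# ---------------------------------------------------------------------------


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-8:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0sq) from gene-wise variances.

    Under the model, z = log s^2 has variance trigamma(df/2) +
    trigamma(d0/2) and a mean that pins down s0^2.  When the observed
    variance of z does not exceed trigamma(df/2) the prior is effectively
    degenerate and d0 = +inf is returned.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ValidationError("need at least 2 positive variances to fit the prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0sq = float(np.exp(emean))
    return d0, s0sq


# ---------------------------------------------------------------------------
# the moderated two-group test
# ---------------------------------------------------------------------------


def differential_expression(
    matrix: ExpressionMatrix,
    samples: pd.DataFrame,
    group_a: str,
    group_b: str,
    comparison_id: str | None = None,
    moderation: bool = True,
    d0_override: float | None = None,
    s0sq_override: float | None = None,
    compute_lfdr: bool = True,
) -> ComparisonResult:
    """Moderated differential expression of ``group_a`` minus ``group_b``.

    ``d0_override``/``s0sq_override`` pin the prior instead of fitting it
    (0 disables shrinkage entirely; numpy.inf shrinks every variance to
    s0sq), which exposes the classical-t and full-shrinkage limits.
    """
    for g in (group_a, group_b):
        if g not in set(samples["group"]):
            raise ValidationError(f"group {g!r} absent from sample sheet")
    ids_a = [s for s in matrix.sample_ids if samples.loc[s, "group"] == group_a]
    ids_b = [s for s in matrix.sample_ids if samples.loc[s, "group"] == group_b]
    n_a, n_b = len(ids_a), len(ids_b)
    if n_a < 2 or n_b < 2:
        raise ValidationError(
            f"both groups need >= 2 samples in the matrix (got {n_a} vs {n_b})"
        )

    A = matrix.values[ids_a].to_numpy(dtype=float)
    B = matrix.values[ids_b].to_numpy(dtype=float)
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    logfc = mean_a - mean_b
    df = n_a + n_b - 2
    ss = ((A - mean_a[:, None]) ** 2).sum(axis=1) + ((B - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df

    if not np.any(s2 > 0):
        raise ValidationError("zero within-group variance for all features")
    var_floored = s2 <= 0
    if var_floored.any():
        floor = s2[s2 > 0].min()
        logger.warning("flooring %d zero residual variances to %.3g",
                       int(var_floored.sum()), floor)
        s2 = np.where(var_floored, floor, s2)

    n_features = matrix.shape[0]
    if moderation and n_features < MIN_FEATURES_FOR_MODERATION:
        logger.warning("fewer than %d features: moderation disabled",
                       MIN_FEATURES_FOR_MODERATION)
        moderation = False

    if d0_override is not None:
        d0 = float(d0_override)
        s0sq = float(s0sq_override) if s0sq_override is not None else float(np.median(s2))
    elif moderation:
        d0, s0sq = fit_variance_prior(s2, df)
    else:
        d0, s0sq = 0.0, float("nan")

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.inf
    elif d0 > 0:
        s2_post = (d0 * s0sq + df * s2) / (d0 + df)
        df_total = df + d0
    else:
        s2_post = s2
        df_total = df

    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    t = logfc / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    adj_p = adjust_bh(p)
    if compute_lfdr:
        pi0, lfdr = local_fdr(p)
    else:
        pi0, lfdr = float("nan"), np.full_like(p, np.nan)

    table = pd.DataFrame(
        {
            "logFC": logfc,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "s2": s2,
            "df": float(df),
            "t": t,
            "p": p,
            "adj_p": adj_p,
            "lfdr": lfdr,
            "var_floored": var_floored,
        },
        index=matrix.values.index,
    )
    return ComparisonResult(
        comparison_id=comparison_id or f"{group_a}_vs_{group_b}",
        group_a=group_a, group_b=group_b, n_a=n_a, n_b=n_b,
        table=table, d0=d0, s0sq=s0sq, pi0=pi0,
    )


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("adjust_bh expects a 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def local_fdr(p: np.ndarray) -> tuple[float, np.ndarray]:
    """Local false discovery rates from raw p-values.

    pi0 is the Storey estimate #{p > 0.5} / (0.5 n), capped at 1 and floored
    at 1/n; the p-value density is the Grenander estimator (left derivative
    of the least concave majorant of the empirical CDF, computed by
    pool-adjacent-violators on the ECDF slopes); lfdr = min(1, pi0/f_hat),
    which is non-decreasing in p.  With fewer than 100 p-values the density
    estimate is unstable and lfdr = min(1, pi0) is returned for every
    feature, with a warning.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("local_fdr requires at least one p-value")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    pi0 = min(1.0, max(1.0 / n, np.sum(p > 0.5) / (0.5 * n)))
    if n < MIN_P_FOR_LFDR:
        logger.warning("local_fdr: only %d p-values; returning lfdr = min(1, pi0)", n)
        return pi0, np.full(n, min(1.0, pi0))
    f_hat = grenander_density(p)
    lfdr = np.minimum(1.0, pi0 / np.maximum(f_hat, 1e-300))
    return pi0, lfdr


def grenander_density(p: np.ndarray) -> np.ndarray:
    """Grenander (non-increasing) density estimate evaluated at each p.

    The estimator is the slope of the least concave majorant of the ECDF,
    obtained by a weighted pool-adjacent-violators pass over the raw ECDF
    slopes; the support is extended to [0, 1].
    """
    p = np.asarray(p, dtype=float)
    uniq, counts = np.unique(p, return_counts=True)
    F = np.cumsum(counts) / p.size
    x = np.concatenate([[0.0], uniq])
    y = np.concatenate([[0.0], F])
    if x[-1] < 1.0:
        x = np.append(x, 1.0)
        y = np.append(y, 1.0)
    dx = np.diff(x)
    slopes = np.diff(y) / dx
    # weighted PAVA enforcing non-increasing slopes (weights = segment widths)
    vals: list[float] = []
    wts: list[float] = []
    for v, w in zip(slopes, dx):
        vals.append(v)
        wts.append(w)
        while len(vals) > 1 and vals[-2] < vals[-1]:
            v2 = (vals[-1] * wts[-1] + vals[-2] * wts[-2]) / (wts[-1] + wts[-2])
            w2 = wts[-1] + wts[-2]
            vals.pop(); wts.pop()
            vals[-1] = v2
            wts[-1] = w2
    breaks = np.concatenate([[x[0]], x[0] + np.cumsum(wts)])
    seg_vals = np.asarray(vals)
    idx = np.clip(np.searchsorted(breaks, p, side="left") - 1, 0, seg_vals.size - 1)
    return seg_vals[idx]


# ---------------------------------------------------------------------------
# status classification and gene collapsing
# ---------------------------------------------------------------------------


def classify_status(
    result: ComparisonResult,
    alpha: float = DEFAULT_ALPHA,
    lfc_min: float = DEFAULT_LFC_MIN,
    lfdr_min: float = DEFAULT_LFDR_MIN,
) -> tuple[pd.DataFrame, int]:
    """Five-level status per feature for one comparison.

    Returns (status table, conflict count).  Conflicts are features that
    satisfy both a DE/significant rule and the lfdr-unchanged rule; the
    precedence DE > SIGNIFICANT > UNCHANGED > UNCERTAIN resolves them.
    """
    t = result.table
    if t["lfdr"].isna().any():
        raise ValidationError("classify_status requires local fdr values")
    sig = t["adj_p"].to_numpy() < alpha
    de = sig & (np.abs(t["logFC"].to_numpy()) >= lfc_min)
    unchanged = t["lfdr"].to_numpy() > lfdr_min
    up = t["logFC"].to_numpy() > 0

    status = np.full(len(t), "UNCERTAIN", dtype=object)
    status[unchanged] = "UNCHANGED"
    status[sig] = "SIGNIFICANT"
    status[de & up] = "DE_UP"
    status[de & ~up] = "DE_DOWN"
    conflicts = int(np.sum(sig & unchanged))

    out = pd.DataFrame(
        {
            "status": status,
            "logFC": t["logFC"],
            "p": t["p"],
            "adj_p": t["adj_p"],
            "lfdr": t["lfdr"],
        },
        index=t.index,
    )
    return out, conflicts


def collapse_to_genes(
    status: pd.DataFrame,
    annotation: ProbeAnnotation,
) -> pd.DataFrame:
    """Collapse a feature-level status table to gene level.

    The representative feature per gene has the smallest adjusted p, ties
    broken by the largest |logFC|, then by lexicographic feature id; the
    gene inherits its full record.  Unannotated features are dropped (count
    logged).
    """
    genes = [annotation.gene_of(f) for f in status.index]
    keep = [g is not None for g in genes]
    n_dropped = len(keep) - sum(keep)
    if n_dropped:
        logger.info("collapse_to_genes: dropped %d unannotated features", n_dropped)
    df = status.loc[keep].copy()
    df["gene_symbol"] = [g for g in genes if g is not None]
    df["probe_id"] = df.index
    df["_abs_lfc"] = df["logFC"].abs()
    df = df.sort_values(["adj_p", "_abs_lfc", "probe_id"],
                        ascending=[True, False, True], kind="mergesort")
    rep = df.groupby("gene_symbol", sort=True).head(1).set_index("gene_symbol")
    rep = rep.drop(columns=["_abs_lfc"]).sort_index()
    return rep[["status", "probe_id", "logFC", "p", "adj_p", "lfdr"]]


# ---------------------------------------------------------------------------
# qPCR relative expression (ddCt)
# ---------------------------------------------------------------------------


def qpcr_relative_expression(
    ct: pd.DataFrame,
    targets: list[str],
    refs: tuple[str, str],
    calibrator: str,
) -> pd.DataFrame:
    """ddCt relative expression against a calibrator sample or group.

    ``ct`` is long-format with columns sample_id, gene, ct (and optionally
    group and replicate; replicates per sample/gene are averaged first).
    dCt = Ct_target - mean(Ct of the two reference genes);
    ddCt = dCt_sample - dCt_calibrator; ratio = 2^(-ddCt).  When
    ``calibrator`` names a group, its dCt is the mean over that group's
    samples.
    """
    required = {"sample_id", "gene", "ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"ct table needs columns {sorted(required)}")
    mean_ct = ct.groupby(["sample_id", "gene"])["ct"].mean().unstack("gene")
    for ref in refs:
        if ref not in mean_ct.columns or mean_ct[ref].isna().any():
            raise ValidationError(f"reference gene {ref!r} missing in some samples")
    ref_ct = mean_ct[list(refs)].mean(axis=1)
    dct = mean_ct[list(targets)].sub(ref_ct, axis=0)

    if calibrator in dct.index:
        cal = dct.loc[calibrator]
    elif "group" in ct.columns:
        members = ct.loc[ct["group"] == calibrator, "sample_id"].unique()
        if len(members) == 0:
            raise ValidationError(f"calibrator {calibrator!r} matches no sample or group")
        cal = dct.loc[list(members)].mean(axis=0)
    else:
        raise ValidationError(f"calibrator {calibrator!r} matches no sample")
    ddct = dct.sub(cal, axis=1)
    return 2.0 ** (-ddct)
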