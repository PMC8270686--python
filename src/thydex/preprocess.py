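"""Array quality gating and RMA-style normalization.

The normalization pipeline is the light-weight core of RMA: quantile
normalization across arrays followed by per-probeset two-way median-polish
summarization.  The convolution background model is deliberately not
implemented -- inputs are assumed background-handled; an optional
percentile-shift correction is available for linear-scale input.

Quality gating applies the scanner metric thresholds exactly as strict
inequalities (maxbg < 190, pp > 37.5 %, sf < 4, actin 3'/5' < 5,
GAPDH 3'/5' < 4), requires the spike-in quartet bioB < bioC < bioD < cre to
be strictly increasing, and windows the computed per-array medians of RLE
(relative log expression, -0.25..0.25) and NUSE (normalized unscaled
standard error, 0.8..1.2).  The scanner metrics are consumed, not computed;
RLE and NUSE are computed here.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ProbeAnnotation, ValidationError

logger = logging.getLogger("thydex")

MEDIAN_POLISH_TOL = 0.01     # relative change in total absolute residual
MEDIAN_POLISH_MAX_ITER = 10  # sweeps


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every array to the same value distribution (per-rank row means).

    After normalization every column holds the identical multiset of values
    and within-column rank order is preserved.  Tied values within a column
    receive the mean of the per-rank means over their tied span, which keeps
    the operation deterministic and idempotent.
    """
    X = matrix.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("quantile normalization requires finite values")
    n, m = X.shape
    if m < 2:
        logger.warning("quantile_normalize: single sample, returning input unchanged")
        return ExpressionMatrix(matrix.values.copy(), level=matrix.level)
    sorted_X = np.sort(X, axis=0)
    # per-rank row means, computed about the first column so that the mean
    # of identical values is exactly that value (keeps the operation
    # bit-exactly idempotent)
    base = sorted_X[:, 0]
    target = base + (sorted_X - base[:, None]).mean(axis=1)
    out = np.empty_like(X)
    for j in range(m):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty(n)
        # walk tied spans: every tied value gets the mean target over the span
        i = 0
        sorted_col = col[order]
        while i < n:
            k = i
            while k + 1 < n and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            span = target[i:k + 1]
            ranked[i:k + 1] = span[0] + (span - span[0]).mean()
            i = k + 1
        out[order, j] = ranked
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        level=matrix.level,
    )


# ---------------------------------------------------------------------------
# median polish summarization
# ---------------------------------------------------------------------------


def median_polish(z: np.ndarray,
                  tol: float = MEDIAN_POLISH_TOL,
                  max_iter: int = MEDIAN_POLISH_MAX_ITER,
                  ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Two-way Tukey median polish, row-first sweeps.

    Returns (overall, row_effects, col_effects, residuals).  Convergence when
    the total absolute residual changes by less than ``tol`` relative to its
    current value, or after ``max_iter`` sweeps.  Even-count medians are the
    mean of the two central values throughout.
    """
    r = np.asarray(z, dtype=float).copy()
    t = 0.0
    row = np.zeros(r.shape[0])
    col = np.zeros(r.shape[1])
    oldsum = 0.0
    for _ in range(max_iter):
        rdelta = np.median(r, axis=1)
        r -= rdelta[:, None]
        row += rdelta
        delta = np.median(col)
        col -= delta
        t += delta
        cdelta = np.median(r, axis=0)
        r -= cdelta[None, :]
        col += cdelta
        delta = np.median(row)
        row -= delta
        t += delta
        newsum = np.abs(r).sum()
        if newsum == 0.0 or abs(newsum - oldsum) < tol * newsum:
            break
        oldsum = newsum
    return t, row, col, r


def median_polish_summarize(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Summarize probe-level intensities into probeset expression.

    Probes are grouped into probesets by the annotation (probes of one gene
    form one probeset here); each probeset's probe x sample block is median
    polished and the summary per sample is overall + sample (column) effect,
    which removes probe affinity offsets.  The companion SE table holds, per
    probeset and sample, the residual scale of that sample's column
    (median absolute deviation x 1.4826) divided by sqrt(probe count);
    single-probe probesets have zero residuals and hence zero SE.
    """
    unmapped = [p for p in matrix.feature_ids if annotation.gene_of(p) is None]
    if unmapped:
        raise ValidationError(f"unmapped probes: {unmapped[:10]} ({len(unmapped)} total)")
    values = matrix.values
    probesets: dict[str, list[str]] = {}
    for p in matrix.feature_ids:
        probesets.setdefault(annotation.gene_of(p), []).append(p)

    X = values.to_numpy(dtype=float)
    index_of = {p: i for i, p in enumerate(matrix.feature_ids)}
    n_samples = X.shape[1]
    summaries = np.empty((len(probesets), n_samples))
    ses = np.empty((len(probesets), n_samples))
    names = []
    for k, (ps, probes) in enumerate(probesets.items()):
        rows = [index_of[p] for p in probes]
        block = X[rows, :]
        t, _row_eff, col_eff, resid = median_polish(block)
        summaries[k] = t + col_eff
        col_med = np.median(resid, axis=0)
        mad = np.median(np.abs(resid - col_med[None, :]), axis=0) * 1.4826
        ses[k] = mad / np.sqrt(block.shape[0])
        names.append(ps)

    idx = pd.Index(names, name="feature_id")
    out = ExpressionMatrix(
        pd.DataFrame(summaries, index=idx, columns=values.columns), level="probeset"
    )
    se = pd.DataFrame(ses, index=idx, columns=values.columns)
    return out, se


# ---------------------------------------------------------------------------
# RLE / NUSE
# ---------------------------------------------------------------------------


def compute_rle(matrix: ExpressionMatrix) -> tuple[pd.Series, pd.DataFrame]:
    """Relative log expression: value minus the across-sample gene median.

    Returns (per-sample RLE medians, full RLE matrix).  Location shifts of a
    whole array show up directly as a shifted RLE median.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("RLE undefined for a single sample")
    v = matrix.values
    rle = v.sub(v.median(axis=1), axis=0)
    return rle.median(axis=0), rle


def compute_nuse(se: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Normalized unscaled standard errors: SE over the across-sample median SE.

    Features whose median SE is zero (e.g. single-probe probesets, whose
    polish residuals vanish) carry no information and are dropped with a
    warning; an all-zero SE table is an error.
    """
    med = se.median(axis=1)
    keep = med > 0
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValidationError("all features have zero median SE; NUSE undefined")
    if n_dropped:
        logger.warning("compute_nuse: dropped %d features with zero median SE", n_dropped)
    nuse = se.loc[keep].div(med[keep], axis=0)
    return nuse.median(axis=0), nuse


# ---------------------------------------------------------------------------
# the QC gate
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class QCThresholds:
    """Strict-inequality windows for array retention."""

    maxbg: float = 190.0
    pp: float = 37.5
    sf: float = 4.0
    actin: float = 5.0
    gapdh: float = 4.0
    rle_window: tuple[float, float] = (-0.25, 0.25)
    nuse_window: tuple[float, float] = (0.8, 1.2)


SPIKE_COLUMNS = ("bioB", "bioC", "bioD", "cre")


def qc_gate(
    records: pd.DataFrame,
    rle_medians: pd.Series,
    nuse_medians: pd.Series,
    thresholds: QCThresholds | None = None,
) -> pd.DataFrame:
    """Apply every retention rule and report the verdict per array.

    ``records`` is indexed by sample id with columns bioB/bioC/bioD/cre,
    maxbg, pp, sf, actin_ratio, gapdh_ratio.  The verdict table has one row
    per sample with a boolean ``pass`` and the list of violated rule names;
    a missing metric fails the sample with rule ``missing_metric:<name>``.
    """
    th = thresholds or QCThresholds()
    rows = []
    for sid in records.index:
        rec = records.loc[sid]
        violated: list[str] = []

        spikes = [rec.get(c) for c in SPIKE_COLUMNS]
        if any(s is None or pd.isna(s) for s in spikes):
            missing = [c for c, s in zip(SPIKE_COLUMNS, spikes) if s is None or pd.isna(s)]
            violated.extend(f"missing_metric:{c}" for c in missing)
        elif not all(a < b for a, b in zip(spikes, spikes[1:])):
            violated.append("spike_order")

        for rule, col, ok in (
            ("maxbg", "maxbg", lambda x: x < th.maxbg),
            ("pp", "pp", lambda x: x > th.pp),
            ("sf", "sf", lambda x: x < th.sf),
            ("actin", "actin_ratio", lambda x: x < th.actin),
            ("gapdh", "gapdh_ratio", lambda x: x < th.gapdh),
        ):
            x = rec.get(col)
            if x is None or pd.isna(x):
                violated.append(f"missing_metric:{col}")
            elif not ok(float(x)):
                violated.append(rule)

        for rule, series, window in (
            ("rle_median", rle_medians, th.rle_window),
            ("nuse_median", nuse_medians, th.nuse_window),
        ):
            if sid not in series.index or pd.isna(series[sid]):
                violated.append(f"missing_metric:{rule}")
            elif not (window[0] < float(series[sid]) < window[1]):
                violated.append(rule)

        rows.append((sid, len(violated) == 0, violated))
    return pd.DataFrame(rows, columns=["sample_id", "pass", "violated_rules"]).set_index("sample_id")


def percentile_shift_correct(values: pd.DataFrame, percentile: float = 1.0,
                             epsilon: float = 1e-6) -> pd.DataFrame:
    """Optional simple background handling for linear-scale input: subtract the
    per-array low percentile and floor at a small epsilon before log transform."""
    shifted = values.sub(values.quantile(percentile / 100.0, axis=0), axis=1)
    return shifted.clip(lower=epsilon)
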