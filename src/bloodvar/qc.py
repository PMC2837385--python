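"""Sample/probe filtration, normalization and imputation cascade.

Order is fixed: flag masking -> technical-replicate resolution -> array
detection filter -> probe detection filter -> log2 -> quantile normalization
-> k-nearest-neighbour imputation.  Two detection comparators coexist on
purpose: the replicate rule and the probe filter count cells with S/N
strictly exceeding 3, while the array filter uses S/N >= 3.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import nan_euclidean_distances

from .containers import (
    FLAG_THRESHOLD,
    SNR_THRESHOLD,
    AnnotationTable,
    BloodvarError,
    ExpressionSet,
    QCReport,
)


def mask_flagged(expr: ExpressionSet, threshold: int = FLAG_THRESHOLD) -> ExpressionSet:
    """Set cells with flag strictly above ``threshold`` to missing."""
    if expr.flags is None:
        raise BloodvarError("expression set has no flag matrix")
    mask = expr.missing_mask | (expr.flags > threshold)
    return replace(expr, missing_mask=mask)


def _detected_counts(expr: ExpressionSet, *, strict: bool, axis: int) -> pd.Series:
    """Count detected cells (S/N above threshold, not missing) along an axis."""
    if expr.snr is None:
        raise BloodvarError("expression set has no S/N matrix")
    snr = expr.snr.to_numpy()
    ok = snr > SNR_THRESHOLD if strict else snr >= SNR_THRESHOLD
    ok &= ~expr.missing_mask.to_numpy()
    counts = ok.sum(axis=axis)
    labels = expr.sample_ids if axis == 0 else expr.probe_ids
    return pd.Series(counts, index=labels)


def resolve_replicates(
    expr: ExpressionSet, annotations: AnnotationTable
) -> tuple[ExpressionSet, QCReport]:
    """Keep, per subject, the array with the most probes at S/N > 3.

    Ties go to the array appearing first in input order; each resolution is
    recorded.  Requires ``annotations.subject``.
    """
    if annotations.subject is None:
        raise BloodvarError("annotations carry no subject identity")
    ann = annotations.aligned_to(expr.sample_ids)
    counts = _detected_counts(expr, strict=True, axis=0)

    keep: list[str] = []
    excluded: list[tuple[str, str]] = []
    resolutions: list[tuple[tuple[str, ...], str]] = []
    order = {s: i for i, s in enumerate(expr.sample_ids)}
    for _, grp in ann.data.groupby(ann.subject, sort=False):
        ids = sorted(grp.index, key=order.__getitem__)
        if len(ids) == 1:
            keep.append(ids[0])
            continue
        best = max(ids, key=lambda s: (counts[s], -order[s]))
        keep.append(best)
        resolutions.append((tuple(ids), best))
        for s in ids:
            if s != best:
                excluded.append((s, f"technical replicate of {best} with fewer detected probes"))
    keep.sort(key=order.__getitem__)
    out = expr.select_samples(keep)
    report = QCReport(
        n_arrays_in=expr.n_samples,
        n_arrays_out=out.n_samples,
        n_probes_in=expr.n_probes,
        n_probes_out=out.n_probes,
        excluded_arrays=excluded,
        replicate_resolutions=resolutions,
    )
    return out, report


def filter_arrays(
    expr: ExpressionSet, min_fraction: float = 0.40
) -> tuple[ExpressionSet, QCReport]:
    """Remove arrays where fewer than 40% of probes reach S/N >= 3."""
    counts = _detected_counts(expr, strict=False, axis=0)
    frac = counts / expr.n_probes
    drop = frac[frac < min_fraction].index
    keep = [s for s in expr.sample_ids if s not in set(drop)]
    out = expr.select_samples(keep)
    report = QCReport(
        n_arrays_in=expr.n_samples,
        n_arrays_out=out.n_samples,
        n_probes_in=expr.n_probes,
        n_probes_out=out.n_probes,
        excluded_arrays=[
            (s, f"detection fraction {frac[s]:.3f} < {min_fraction}") for s in drop
        ],
    )
    return out, report


def filter_probes(
    expr: ExpressionSet, min_fraction: float = 0.50
) -> tuple[ExpressionSet, QCReport]:
    """Drop probes whose S/N exceeds 3 in fewer than half the samples."""
    counts = _detected_counts(expr, strict=True, axis=1)
    frac = counts / expr.n_samples
    drop = frac[frac < min_fraction].index
    keep = [p for p in expr.probe_ids if p not in set(drop)]
    out = expr.select_probes(keep)
    report = QCReport(
        n_arrays_in=expr.n_samples,
        n_arrays_out=out.n_samples,
        n_probes_in=expr.n_probes,
        n_probes_out=out.n_probes,
        excluded_probes=list(drop),
    )
    return out, report


def log2_transform(expr: ExpressionSet) -> ExpressionSet:
    if expr.scale == "log2":
        return expr
    vals = expr.values.where(expr.values > 0)
    return replace(expr, values=np.log2(vals), scale="log2")


def quantile_normalize(expr: ExpressionSet) -> ExpressionSet:
    """Quantile-normalize arrays, missing-aware.

    With complete data each array's sorted values are replaced by the mean of
    order statistics across arrays (the classic scheme).  With missing cells,
    each array's observed empirical quantile function is linearly interpolated
    onto a common grid of quantile ranks; the reference distribution is the
    across-array mean on that grid, and each observed cell is mapped through
    its within-array rank.  Missing cells stay missing.
    """
    expr = log2_transform(expr)
    X = expr.masked_values().to_numpy(dtype=float)
    G, n = X.shape
    counts = np.sum(~np.isnan(X), axis=0)
    if np.any(counts == 0):
        bad = expr.sample_ids[counts == 0].tolist()
        raise BloodvarError(f"arrays with no observed values: {bad}")

    grid = np.linspace(0.0, 1.0, G)
    ref = np.zeros(G)
    for j in range(n):
        obs = np.sort(X[~np.isnan(X[:, j]), j])
        m = obs.size
        q = np.linspace(0.0, 1.0, m) if m > 1 else np.array([0.5])
        ref += np.interp(grid, q, obs)
    ref /= n

    out = X.copy()
    for j in range(n):
        col = X[:, j]
        idx = np.flatnonzero(~np.isnan(col))
        m = idx.size
        order = np.argsort(col[idx], kind="stable")
        ranks = np.empty(m, dtype=float)
        ranks[order] = np.arange(m)
        q = ranks / (m - 1) if m > 1 else np.full(m, 0.5)
        out[idx, j] = np.interp(q, grid, ref)

    values = pd.DataFrame(out, index=expr.probe_ids, columns=expr.sample_ids)
    # keep numeric NaN out of the values frame; missingness lives in the mask
    values = values.fillna(0.0).where(~expr.missing_mask, expr.values)
    return replace(expr, values=values)


def knn_impute(expr: ExpressionSet, k: int = 10) -> tuple[ExpressionSet, list[str]]:
    """Fill missing cells from the k nearest probes.

    Distance between probes is Euclidean over co-observed samples (scaled by
    the fraction observed, so probes with different missingness patterns are
    comparable); the imputed value is the inverse-distance-weighted mean of
    the neighbours' values at that sample, ties in distance broken by probe
    order.  Probes with no usable neighbour at a sample fall back to their own
    observed mean; those probe ids are returned for reporting.
    """
    X = expr.masked_values().to_numpy(dtype=float)
    G, n = X.shape
    miss_rows = np.flatnonzero(np.isnan(X).any(axis=1))
    if miss_rows.size == 0:
        return expr, []

    D = nan_euclidean_distances(X[miss_rows], X)
    out = X.copy()
    fallbacks: list[str] = []
    for r, i in enumerate(miss_rows):
        d = D[r].copy()
        d[i] = np.inf  # never self
        row_mean = np.nanmean(X[i]) if not np.all(np.isnan(X[i])) else np.nan
        for j in np.flatnonzero(np.isnan(X[i])):
            cand = np.flatnonzero(~np.isnan(X[:, j]) & np.isfinite(d))
            if cand.size == 0:
                out[i, j] = row_mean
                fallbacks.append(str(expr.probe_ids[i]))
                continue
            order = np.lexsort((cand, d[cand]))  # distance, then probe order
            nb = cand[order[:k]]
            dist = d[nb]
            if np.any(dist == 0.0):
                w = (dist == 0.0).astype(float)
            else:
                w = 1.0 / dist
            out[i, j] = float(np.average(X[nb, j], weights=w))

    if np.isnan(out).any():
        raise BloodvarError("imputation left missing values (all-missing probe?)")
    values = pd.DataFrame(out, index=expr.probe_ids, columns=expr.sample_ids)
    mask = pd.DataFrame(
        np.zeros_like(out, dtype=bool), index=expr.probe_ids, columns=expr.sample_ids
    )
    return replace(expr, values=values, missing_mask=mask), sorted(set(fallbacks))


def qc_pipeline(
    expr: ExpressionSet,
    annotations: AnnotationTable,
    *,
    flag_threshold: int = FLAG_THRESHOLD,
    array_fraction: float = 0.40,
    probe_fraction: float = 0.50,
    k: int = 10,
) -> tuple[ExpressionSet, AnnotationTable, QCReport]:
    """Run the full cascade and return the reconciled report."""
    expr = mask_flagged(expr, flag_threshold)
    expr, rep_report = resolve_replicates(expr, annotations)
    expr, arr_report = filter_arrays(expr, array_fraction)
    expr, probe_report = filter_probes(expr, probe_fraction)
    report = rep_report.merge(arr_report).merge(probe_report)
    expr = quantile_normalize(expr)
    expr, _ = knn_impute(expr, k=k)
    return expr, annotations.aligned_to(expr.sample_ids), report
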