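"""Eigen-R2: fraction of overall expression variation explained by covariates.

The probe-centered matrix is decomposed by SVD; each right-singular vector
("eigengene", a sample-space expression pattern) is regressed on the design
of the named variables by OLS, and the per-eigengene R2 values are averaged
with weights equal to the normalized squared singular values.  The weighted
average is a high-dimensional analogue of the classic R2: it equals the
proportion of total (probe-centered) variance captured by the projection of
the data onto the design space.

Small-sample note: each eigengene regression carries the usual positive R2
bias of roughly p/(n-1) under a null design (p = design columns).  No
correction is applied by default; callers comparing designs of different
sizes should keep this in mind.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import (
    AnnotationTable,
    BloodvarError,
    ExpressionSet,
    check_full_rank,
    design_matrix,
)


@dataclass
class EigenR2Result:
    eigenvalue_shares: np.ndarray
    per_eigengene_r2: np.ndarray
    eigen_r2: float
    variables: list[str]


def eigengenes(
    expr: ExpressionSet, *, center: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """SVD of the (probe-centered) matrix.

    Returns (V, shares): V has eigengenes as rows (each a vector over
    samples), shares are squared singular values normalized to sum to one.
    """
    Y = expr.masked_values().to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise BloodvarError("matrix has missing values; run knn_impute first")
    if center:
        Y = Y - Y.mean(axis=1, keepdims=True)
    _, s, Vt = np.linalg.svd(Y, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0.0:
        raise BloodvarError("matrix has no variation after centering")
    shares = s**2 / total
    return Vt, shares


def eigen_r2(
    expr: ExpressionSet,
    annotations: AnnotationTable,
    variables: list[str],
    *,
    center: bool = True,
    adjusted: bool = False,
) -> EigenR2Result:
    """Eigenvalue-share-weighted average of per-eigengene regression R2.

    With ``adjusted=True`` each eigengene uses the degrees-of-freedom
    adjusted R2, 1 - (1 - R2)(n - 1)/(n - p), removing the ~ (p-1)/(n-1)
    positive bias a null eigengene regression carries; individual adjusted
    values may be negative, the weighted total is clipped to [0, 1].
    """
    ann = annotations.aligned_to(expr.sample_ids)
    X, names = design_matrix(ann, variables)
    n, p = X.shape
    if p > n:
        raise BloodvarError("design has more columns than samples")
    check_full_rank(X, names)

    Vt, shares = eigengenes(expr, center=center)
    Q, _ = np.linalg.qr(X)
    r2 = np.empty(Vt.shape[0])
    for k, v in enumerate(Vt):
        vc = v - v.mean()
        tss = float(vc @ vc)
        if tss == 0.0:
            r2[k] = 0.0
            continue
        fit = Q @ (Q.T @ v)
        rss = float(np.sum((v - fit) ** 2))
        val = 1.0 - rss / tss
        if adjusted and n > p:
            val = 1.0 - (1.0 - val) * (n - 1) / (n - p)
        else:
            val = max(0.0, val)
        r2[k] = val
    value = float(np.clip(np.dot(shares, r2), 0.0, 1.0))
    return EigenR2Result(
        eigenvalue_shares=shares,
        per_eigengene_r2=r2,
        eigen_r2=value,
        variables=list(variables),
    )
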