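"""Global analysis of covariance over the whole expression matrix.

Association between the full probe x sample matrix and covariates is tested
by comparing nested per-probe ordinary-least-squares fits through the extra
sum of squares principle: the statistic pools the extra sum of squares over
all probes and normalizes by the pooled full-model residual sum of squares,

    T = sum_g (RSS_g^reduced - RSS_g^full) / sum_g RSS_g^full .

Calibration is by permutation: plain sample permutation when the reduced
model is intercept-only, Freedman-Lane residual permutation (permute the
reduced-model residuals, add back the reduced-model fit) when covariates are
adjusted for, so the null respects the adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import (
    AnnotationTable,
    BloodvarError,
    ExpressionSet,
    check_full_rank,
    design_matrix,
)


@dataclass
class AncovaResult:
    statistic: float
    perm_p: float
    n_perm: int
    tested_terms: list[str]
    adjusted_terms: list[str]
    seed: int
    encoding: list[str] = field(default_factory=list)


def _orthonormal_basis(X: np.ndarray) -> np.ndarray:
    """Thin orthonormal basis of the column space (stable via QR)."""
    if X.shape[1] == 0:
        return np.empty((X.shape[0], 0))
    Q, R = np.linalg.qr(X)
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(R).max())
    return Q[:, keep]


def _statistic_from_bases(Y: np.ndarray, Q_full: np.ndarray, Q_red: np.ndarray) -> float:
    """Pooled extra-SS ratio using thin hat-space bases.

    RSS = ||Y||^2 - ||Y Q||^2 per model, summed over probes, so the cost is
    G*n*p rather than G*n^2.
    """
    total = float(np.sum(Y * Y))
    rss_full = total - float(np.sum((Y @ Q_full) ** 2))
    rss_red = total - float(np.sum((Y @ Q_red) ** 2))
    if rss_full <= 0:
        raise BloodvarError("full model leaves zero residual variation")
    return (rss_red - rss_full) / rss_full


def extra_ss_statistic(
    expr: ExpressionSet,
    annotations: AnnotationTable,
    full_terms: list[str],
    reduced_terms: list[str],
) -> float:
    """Pooled extra-sum-of-squares ratio for reduced ⊂ full designs."""
    if not set(reduced_terms) <= set(full_terms):
        raise BloodvarError("reduced terms must be a subset of full terms")
    ann = annotations.aligned_to(expr.sample_ids)
    Xf, names_f = design_matrix(ann, full_terms)
    Xr, _ = design_matrix(ann, reduced_terms)
    check_full_rank(Xf, names_f)
    Y = expr.masked_values().to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise BloodvarError("matrix has missing values; run imputation first")
    return _statistic_from_bases(Y, _orthonormal_basis(Xf), _orthonormal_basis(Xr))


def permutation_test(
    expr: ExpressionSet,
    annotations: AnnotationTable,
    full_terms: list[str],
    reduced_terms: list[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> AncovaResult:
    """Permutation p-value for the extra-SS statistic (add-one rule).

    p = (1 + #{permuted T >= observed T}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise BloodvarError("n_perm must be >= 1")
    if not set(reduced_terms) <= set(full_terms):
        raise BloodvarError("reduced terms must be a subset of full terms")
    ann = annotations.aligned_to(expr.sample_ids)
    Xf, names_f = design_matrix(ann, full_terms)
    Xr, names_r = design_matrix(ann, reduced_terms)
    check_full_rank(Xf, names_f)
    Y = expr.masked_values().to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise BloodvarError("matrix has missing values; run imputation first")
    Q_full = _orthonormal_basis(Xf)
    Q_red = _orthonormal_basis(Xr)
    T_obs = _statistic_from_bases(Y, Q_full, Q_red)

    # Freedman-Lane: fitted reduced part + permuted reduced residuals.
    # With an intercept-only reduced model this reduces to permuting samples.
    fit_red = (Y @ Q_red) @ Q_red.T
    resid_red = Y - fit_red
    rng = np.random.default_rng(seed)
    n = Y.shape[1]
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Y_star = fit_red + resid_red[:, perm]
        if _statistic_from_bases(Y_star, Q_full, Q_red) >= T_obs:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return AncovaResult(
        statistic=T_obs,
        perm_p=p,
        n_perm=n_perm,
        tested_terms=sorted(set(full_terms) - set(reduced_terms)),
        adjusted_terms=list(reduced_terms),
        seed=seed,
        encoding=names_f,
    )


@dataclass
class ScreenResult:
    univariate: dict[str, AncovaResult]
    multivariate: dict[str, AncovaResult]
    passed: list[str]
    roles: dict[str, str]


def screen_variables(
    expr: ExpressionSet,
    annotations: AnnotationTable,
    candidate_technical: list[str],
    alpha: float = 0.001,
    n_perm: int = 1000,
    seed: int = 0,
) -> ScreenResult:
    """Screen technical covariates for downstream modelling.

    Each candidate is tested univariately (against intercept-only) and
    multivariately (drop-one from the joint technical design).  Variables
    whose multivariate permuted p falls below ``alpha`` pass, labelled with
    the role they take downstream: random intercept for categorical batch
    factors, fixed effect otherwise.
    """
    if not candidate_technical:
        raise BloodvarError("empty candidate list")
    ann = annotations.aligned_to(expr.sample_ids)
    uni: dict[str, AncovaResult] = {}
    multi: dict[str, AncovaResult] = {}
    for i, var in enumerate(candidate_technical):
        uni[var] = permutation_test(
            expr, ann, [var], [], n_perm=n_perm, seed=seed + 1000 + i
        )
        multi[var] = permutation_test(
            expr,
            ann,
            candidate_technical,
            [v for v in candidate_technical if v != var],
            n_perm=n_perm,
            seed=seed + 2000 + i,
        )
    passed = [v for v in candidate_technical if multi[v].perm_p < alpha]
    roles = {}
    import pandas as pd

    for v in passed:
        s = ann.data[v]
        categorical = not pd.api.types.is_numeric_dtype(s) or isinstance(
            s.dtype, pd.CategoricalDtype
        )
        roles[v] = "random" if categorical else "fixed"
    return ScreenResult(univariate=uni, multivariate=multi, passed=passed, roles=roles)


def interaction_test(
    expr: ExpressionSet,
    annotations: AnnotationTable,
    var_a: str,
    var_b: str,
    adjust: list[str] = (),
    n_perm: int = 1000,
    seed: int = 0,
) -> AncovaResult:
    """Test an interaction by dropping the product term from the full model."""
    base = list(adjust) + [var_a, var_b]
    return permutation_test(
        expr, annotations, base + [f"{var_a}:{var_b}"], base, n_perm=n_perm, seed=seed
    )
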