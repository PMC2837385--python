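"""Global-test scoring of probe sets and weighted core-probe selection.

The global test asks whether a set of probes jointly associates with an
outcome.  After residualizing outcome and probes on an adjustment design,
each probe contributes

    Q_i = ( sum_j x_ij * r_j )^2

with r the residualized (centered) outcome and x_i the residualized,
unit-variance probe; the set statistic is the mean of the per-probe
contributions.  A permutation null (re-shuffling the residualized outcome)
supplies means and SDs, hence z-scores, and permutation p-values with the
add-one rule.  For tiny two-level outcomes an exact mode enumerates all
distinct outcome arrangements instead.

Core probes are then the members whose |z| clears the cutpoint that
maximizes a weighted true/false-positive utility, with the false discovery
rate at each cutpoint estimated by Benjamini-Hochberg on the z-derived
p-values:

    U(t) = w_tp * S(t) * (1 - FDR(t)) - w_fp * S(t) * FDR(t),

default weights 2 (true positives) versus 1 (false positives).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    AnnotationTable,
    BloodvarError,
    ExpressionSet,
    design_matrix,
)
from ._stats import bh_adjust


@dataclass
class GlobalTestScore:
    probe_ids: list[str]
    set_Q: float
    set_z: float
    set_p: float
    per_probe_Q: np.ndarray
    per_probe_z: np.ndarray
    per_probe_p: np.ndarray
    n_perm: int
    seed: int


@dataclass
class CoreSelection:
    variable: str
    threshold: float
    fdr_at_threshold: float
    core_probes: list[str]
    utility: float


def _residualize(M: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of the rows (or vector) of M on the column space of X."""
    Q, _ = np.linalg.qr(X)
    if M.ndim == 1:
        return M - Q @ (Q.T @ M)
    return M - (M @ Q) @ Q.T


def _outcome_matrix(annotations: AnnotationTable, outcome: str) -> np.ndarray:
    """Outcome as an (n, L) column stack.

    Numeric outcomes give one column; binary categorical outcomes code the
    lexicographically second level as 1.  Outcomes with more than two levels
    return one indicator column per level — the test then uses the maximum
    per-class statistic, an experimental convention for class-valued
    covariates.
    """
    s = annotations.data[outcome]
    if pd.api.types.is_numeric_dtype(s) and not isinstance(s.dtype, pd.CategoricalDtype):
        return s.to_numpy(dtype=float)[:, None]
    levels = sorted(pd.unique(s.astype(str)))
    if len(levels) < 2:
        raise BloodvarError(f"outcome {outcome!r} is constant")
    if len(levels) == 2:
        return (s.astype(str) == levels[1]).to_numpy(dtype=float)[:, None]
    return np.column_stack(
        [(s.astype(str) == lev).to_numpy(dtype=float) for lev in levels]
    )


class GlobalTestEngine:
    """Per-probe global-test contributions for every probe, cached.

    Computes observed contributions and the full permutation-null matrix once
    for the whole platform, so that scores for any probe subset — including
    the thousands of random same-size sets behind comparative p-values — are
    just row means.
    """

    def __init__(
        self,
        expr: ExpressionSet,
        annotations: AnnotationTable,
        outcome: str,
        adjust: list[str] = (),
        n_perm: int = 1000,
        seed: int = 0,
        exact: bool = False,
    ):
        ann = annotations.aligned_to(expr.sample_ids)
        Ymat = _outcome_matrix(ann, outcome)  # (n, L); L > 1 is experimental
        Xa, _ = design_matrix(ann, list(adjust))  # includes intercept
        R = np.column_stack(
            [_residualize(Ymat[:, k], Xa) for k in range(Ymat.shape[1])]
        )
        if np.allclose(R, 0.0):
            raise BloodvarError("outcome is constant after residualization")

        Y = expr.masked_values().to_numpy(dtype=float)
        if np.isnan(Y).any():
            raise BloodvarError("matrix has missing values; run imputation first")
        Xr = _residualize(Y, Xa)
        sd = Xr.std(axis=1)
        sd[sd == 0.0] = 1.0
        Xr = Xr / sd[:, None]

        self.probe_ids = [str(p) for p in expr.probe_ids]
        self._index = {p: i for i, p in enumerate(self.probe_ids)}
        self.seed = seed
        n, L = R.shape
        # per-probe contribution: squared score per outcome column, maximum
        # over columns (reduces to the single squared score when L = 1)
        self.q_obs = ((Xr @ R) ** 2).max(axis=1)

        if exact:
            if n > 9 or L > 1:
                raise BloodvarError(
                    "exact enumeration is limited to n <= 9 samples and "
                    "single-column outcomes"
                )
            r = R[:, 0]
            perms = np.array(sorted(set(permutations(np.round(r, 12)))))
            self.q_perm = (Xr @ perms.T) ** 2
            self.n_perm = perms.shape[0]
            self.exact = True
        else:
            rng = np.random.default_rng(seed)
            if L == 1:
                r = R[:, 0]
                P = np.column_stack(
                    [r[rng.permutation(n)] for _ in range(n_perm)]
                )
                self.q_perm = (Xr @ P) ** 2
            else:
                qp = np.empty((Xr.shape[0], n_perm))
                for b in range(n_perm):
                    qp[:, b] = ((Xr @ R[rng.permutation(n)]) ** 2).max(axis=1)
                self.q_perm = qp
            self.n_perm = n_perm
            self.exact = False

    def _rows(self, probe_set: list[str]) -> np.ndarray:
        missing = [p for p in probe_set if str(p) not in self._index]
        if missing:
            raise BloodvarError(f"probes not in expression set: {missing[:5]}")
        return np.array([self._index[str(p)] for p in probe_set])

    def scores(self, probe_set: list[str]) -> GlobalTestScore:
        rows = self._rows(probe_set)
        q = self.q_obs[rows]
        qp = self.q_perm[rows]
        mu = qp.mean(axis=1)
        sdp = qp.std(axis=1, ddof=1)
        sdp[sdp == 0.0] = np.nan
        z = (q - mu) / sdp
        if self.exact:
            # tolerance so the identity arrangement always counts itself
            p = (qp >= q[:, None] - 1e-9).mean(axis=1)
        else:
            p = (1 + (qp >= q[:, None]).sum(axis=1)) / (self.n_perm + 1)

        set_q = float(q.mean())
        set_perm = qp.mean(axis=0)
        set_sd = float(set_perm.std(ddof=1))
        set_z = (set_q - float(set_perm.mean())) / set_sd if set_sd > 0 else np.nan
        if self.exact:
            set_p = float((set_perm >= set_q - 1e-9).mean())
        else:
            set_p = (1 + int((set_perm >= set_q).sum())) / (self.n_perm + 1)
        return GlobalTestScore(
            probe_ids=[str(p) for p in probe_set],
            set_Q=set_q,
            set_z=float(set_z),
            set_p=float(set_p),
            per_probe_Q=q,
            per_probe_z=z,
            per_probe_p=p,
            n_perm=self.n_perm,
            seed=self.seed,
        )

    def set_z_for_rows(self, rows: np.ndarray) -> float:
        q = float(self.q_obs[rows].mean())
        perm = self.q_perm[rows].mean(axis=0)
        sd = float(perm.std(ddof=1))
        return (q - float(perm.mean())) / sd if sd > 0 else np.nan


def global_test_scores(
    expr: ExpressionSet,
    annotations: AnnotationTable,
    outcome: str,
    probe_set: list[str],
    adjust: list[str] = (),
    n_perm: int = 1000,
    seed: int = 0,
    exact: bool = False,
) -> GlobalTestScore:
    """Global-test set statistic with per-probe contributions and z-scores."""
    engine = GlobalTestEngine(
        expr.select_probes(probe_set), annotations, outcome, adjust, n_perm, seed, exact
    )
    return engine.scores([str(p) for p in probe_set])


def select_core_weighted(
    scores: GlobalTestScore,
    w_tp: float = 2.0,
    w_fp: float = 1.0,
    variable: str = "",
    set_alpha: float | None = 0.05,
) -> CoreSelection:
    """Pick the |z| cutpoint maximizing the weighted TP-vs-FP utility.

    With S probes above a cutpoint and FDR the Benjamini-Hochberg estimate at
    that cutpoint, the expected true and false positive counts are
    S*(1-FDR) and S*FDR; the cutpoint maximizing
    w_tp*S*(1-FDR) - w_fp*S*FDR wins, ties going to the stricter (larger)
    cutpoint.  Declining to select anything (utility 0) is an admissible
    optimum.

    Core refinement presumes the set is associated in the first place: if the
    set-level permutation p exceeds ``set_alpha`` the core set is empty.
    Without this gate the utility rule fires on pure noise roughly half the
    time — any rule selecting whenever an FDR estimate dips below
    w_tp/(w_tp+w_fp) is a Simes-type event at that level — whereas the gate
    caps the null selection probability at ``set_alpha``.  Pass ``None`` to
    search the cutpoints unconditionally.
    """
    z = np.asarray(scores.per_probe_z, dtype=float)
    if z.size == 0:
        raise BloodvarError("empty score set")
    if set_alpha is not None and scores.set_p > set_alpha:
        return CoreSelection(
            variable=variable,
            threshold=float("inf"),
            fdr_at_threshold=0.0,
            core_probes=[],
            utility=0.0,
        )
    absz = np.abs(z)
    pvals = 2.0 * stats.norm.sf(absz)
    qvals = bh_adjust(pvals)

    order = np.argsort(-absz, kind="stable")
    sorted_q = qvals[order]
    sorted_absz = absz[order]
    # running max makes q monotone along decreasing |z| (step-up property)
    running_fdr = np.maximum.accumulate(sorted_q)

    best_u, best_s, best_t, best_fdr = 0.0, 0, float("inf"), 0.0
    n = z.size
    for s in range(1, n + 1):
        if s < n and sorted_absz[s] == sorted_absz[s - 1]:
            continue  # cutpoint must clear the whole tied group
        fdr = float(running_fdr[s - 1])
        u = w_tp * s * (1.0 - fdr) - w_fp * s * fdr
        if u > best_u + 1e-12:
            best_u, best_s, best_t, best_fdr = u, s, float(sorted_absz[s - 1]), fdr
    ids = np.asarray(scores.probe_ids, dtype=object)
    core = [str(p) for p in ids[order[:best_s]]]
    return CoreSelection(
        variable=variable,
        threshold=best_t,
        fdr_at_threshold=best_fdr,
        core_probes=core,
        utility=best_u,
    )


def association_direction(
    expr: ExpressionSet,
    annotations: AnnotationTable,
    outcome: str,
    core_probes: list[str],
    adjust: list[str] = (),
) -> dict[str, str]:
    """Sign of the residualized probe-outcome covariance per core probe.

    ``up-in-level-1`` means higher expression in the outcome's coded 1 (or
    second) level; exact zero covariance reports ``undetermined``.
    """
    ann = annotations.aligned_to(expr.sample_ids)
    Ymat = _outcome_matrix(ann, outcome)
    if Ymat.shape[1] > 1:
        raise BloodvarError("direction is defined for two-level or numeric outcomes")
    y = Ymat[:, 0]
    Xa, _ = design_matrix(ann, list(adjust))
    r = _residualize(y, Xa)
    sub = expr.select_probes(core_probes)
    Xr = _residualize(sub.masked_values().to_numpy(dtype=float), Xa)
    cov = Xr @ r
    out: dict[str, str] = {}
    for pid, c in zip(core_probes, cov):
        if c > 0:
            out[str(pid)] = "up-in-level-1"
        elif c < 0:
            out[str(pid)] = "up-in-level-0"
        else:
            out[str(pid)] = "undetermined"
    return out
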