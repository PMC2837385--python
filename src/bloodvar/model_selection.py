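"""Per-probe linear mixed model selection by forward-backward BIC search.

For each probe, a linear model with candidate fixed effects (biological and
exposure covariates, an HT x MED interaction, time to freezing) and crossed
random intercepts (array lot, RNA extraction date) is selected by greedy
forward-backward search on the Bayesian information criterion,

    BIC = -2 * loglik_ML + n_params * log(n_samples),

with n_params = fixed coefficients + 1 residual variance + 1 variance per
random component.  Maximum likelihood (not REML) is used throughout so BIC
values are comparable across different fixed-effect sets.

The likelihood is profiled over the variance ratios gamma_v = sigma_v^2 /
sigma_e^2: given gamma, the GLS coefficients and the residual variance have
closed forms, so only the (at most two) ratios are optimized numerically.
All matrix work runs through sufficient statistics (cross-products of a
shared column bank), making a fit a few-microsecond q x q problem rather
than an n x n one — essential when the search visits tens of models per
probe across thousands of probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import (
    AnnotationTable,
    BloodvarError,
    ExpressionSet,
    _encode,
)

LOG_2PI = float(np.log(2.0 * np.pi))

#: optimizer search bounds for log variance ratios
_LOG_GAMMA_LO, _LOG_GAMMA_HI = -12.0, 8.0


@dataclass
class CandidatePool:
    """Candidate variables offered to the per-probe search."""

    fixed_candidates: list[str] = field(
        default_factory=lambda: [
            "age_class",
            "bmi_class",
            "fasting",
            "smoking",
            "HT",
            "MED",
            "HT:MED",
            "freeze_days",
        ]
    )
    random_candidates: list[str] = field(
        default_factory=lambda: ["array_lot", "extraction_date"]
    )
    hierarchy: dict[str, tuple[str, str]] = field(
        default_factory=lambda: {"HT:MED": ("HT", "MED")}
    )

    @property
    def all_candidates(self) -> list[str]:
        return self.fixed_candidates + self.random_candidates

    def __post_init__(self) -> None:
        for inter, (a, b) in self.hierarchy.items():
            if inter not in self.fixed_candidates:
                raise BloodvarError(f"hierarchy names unknown interaction {inter!r}")
            for parent in (a, b):
                if parent not in self.fixed_candidates:
                    raise BloodvarError(
                        f"interaction {inter!r} lists parent {parent!r} "
                        "not in the candidate pool"
                    )


@dataclass
class ProbeModel:
    probe_id: str
    selected_fixed: set[str]
    selected_random: set[str]
    bic: float
    loglik: float
    n_params: int
    variance_ratios: dict[str, float] = field(default_factory=dict)
    # fitted log variance ratios, kept as warm starts for neighbouring models
    log_gamma: dict[str, float] = field(default_factory=dict)


class MixedModelWorkspace:
    """Shared design encodings and cross-products for one annotation table.

    Build once, then fit any (fixed set, random set) submodel against any
    response cheaply.
    """

    def __init__(self, annotations: AnnotationTable, pool: CandidatePool):
        self.pool = pool
        self.n = len(annotations.data)
        # fixed-effect column bank: intercept first
        cols: list[np.ndarray] = [np.ones(self.n)]
        self._fixed_slices: dict[str, list[int]] = {"Intercept": [0]}
        for var in pool.fixed_candidates:
            enc = _encode(annotations, var)
            idx = []
            for c, _name in enc:
                idx.append(len(cols))
                cols.append(np.asarray(c, dtype=float))
            self._fixed_slices[var] = idx
        self.F = np.column_stack(cols)

        # random-effect indicator banks
        self._z_blocks: dict[str, np.ndarray] = {}
        for var in pool.random_candidates:
            s = annotations.data[var].astype(str)
            codes, levels = pd.factorize(s)
            Z = np.zeros((self.n, len(levels)))
            Z[np.arange(self.n), codes] = 1.0
            self._z_blocks[var] = Z

        B = np.column_stack([self.F] + [self._z_blocks[v] for v in pool.random_candidates])
        self._z_offsets: dict[str, slice] = {}
        off = self.F.shape[1]
        for var in pool.random_candidates:
            q = self._z_blocks[var].shape[1]
            self._z_offsets[var] = slice(off, off + q)
            off += q
        self.B = B
        self.BtB = B.T @ B

    # -- index helpers ------------------------------------------------------
    def fixed_indices(self, fixed: set[str] | list[str]) -> list[int]:
        idx = list(self._fixed_slices["Intercept"])
        for var in self.pool.fixed_candidates:  # pool order => determinism
            if var in fixed:
                idx.extend(self._fixed_slices[var])
        return idx

    def random_indices(self, random: set[str] | list[str]) -> tuple[list[int], list[int]]:
        """Column indices into B, and per-component sizes, in pool order."""
        idx: list[int] = []
        sizes: list[int] = []
        for var in self.pool.random_candidates:
            if var in random:
                sl = self._z_offsets[var]
                idx.extend(range(sl.start, sl.stop))
                sizes.append(sl.stop - sl.start)
        return idx, sizes

    def suffstats(self, y: np.ndarray) -> tuple[np.ndarray, float]:
        """(B'y, y'y) for a response vector."""
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise BloodvarError("response length does not match annotations")
        return self.B.T @ y, float(y @ y)


def _profile_loglik(
    log_gamma: np.ndarray,
    sizes: list[int],
    XtX: np.ndarray,
    Xty: np.ndarray,
    yty: float,
    ZtZ: np.ndarray,
    ZtX: np.ndarray,
    Zty: np.ndarray,
    n: int,
) -> tuple[float, float]:
    """Profiled ML log-likelihood at variance ratios exp(log_gamma).

    Returns (loglik, sigma2_hat).  Uses the Woodbury identity on the
    random-effect cross-products:  with V0 = I + Z G Z',

        A' V0^-1 B = A'B - (Z'A)' W (Z'B),   W = (G^-1 + Z'Z)^-1,
        log|V0| = log|I_q + Z'Z G|.
    """
    g = np.repeat(np.exp(log_gamma), sizes)
    q = len(g)
    Winv = ZtZ + np.diag(1.0 / g)
    try:
        Wc = np.linalg.cholesky(Winv)
    except np.linalg.LinAlgError:
        return -np.inf, np.nan
    # log|V0| = log|I + ZtZ G| = log|Winv| + sum log g
    logdet_V0 = 2.0 * float(np.sum(np.log(np.diag(Wc)))) + float(np.sum(np.log(g)))

    def w_apply(M: np.ndarray) -> np.ndarray:
        return np.linalg.solve(Wc.T, np.linalg.solve(Wc, M))

    WZtX = w_apply(ZtX)
    WZty = w_apply(Zty)
    XtVX = XtX - ZtX.T @ WZtX
    XtVy = Xty - ZtX.T @ WZty
    ytVy = yty - float(Zty @ WZty)
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return -np.inf, np.nan
    rss = ytVy - float(XtVy @ beta)
    if rss <= 0:
        return -np.inf, np.nan
    sigma2 = rss / n
    ll = -0.5 * (n * (LOG_2PI + 1.0 + np.log(sigma2)) + logdet_V0)
    return float(ll), float(sigma2)


def fit_mixed_bic(
    y: np.ndarray,
    fixed: set[str] | list[str],
    random: set[str] | list[str],
    annotations: AnnotationTable | None = None,
    *,
    workspace: MixedModelWorkspace | None = None,
    pool: CandidatePool | None = None,
) -> ProbeModel:
    """ML fit of a mixed model and its BIC.

    ``fixed`` and ``random`` name candidate-pool variables.  Either an
    existing workspace or (annotations, pool) must be supplied.
    """
    if workspace is None:
        if annotations is None:
            raise BloodvarError("need annotations or a workspace")
        workspace = MixedModelWorkspace(annotations, pool or CandidatePool())
    ws = workspace
    fixed = set(fixed)
    random = set(random)
    unknown = (fixed - set(ws.pool.fixed_candidates)) | (
        random - set(ws.pool.random_candidates)
    )
    if unknown:
        raise BloodvarError(f"variables outside the candidate pool: {sorted(unknown)}")

    By, yty = ws.suffstats(y)
    return _fit_from_suffstats(ws, fixed, random, By, yty)


def _fit_from_suffstats(
    ws: MixedModelWorkspace,
    fixed: set[str],
    random: set[str],
    By: np.ndarray,
    yty: float,
    start_log_gamma: np.ndarray | None = None,
) -> ProbeModel:
    n = ws.n
    fi = ws.fixed_indices(fixed)
    XtX = ws.BtB[np.ix_(fi, fi)]
    Xty = By[fi]

    if not random:
        try:
            beta = np.linalg.solve(XtX, Xty)
        except np.linalg.LinAlgError as exc:
            raise BloodvarError(f"singular fixed design for {sorted(fixed)}") from exc
        rss = yty - float(Xty @ beta)
        rss = max(rss, 1e-12)
        ll = -0.5 * n * (LOG_2PI + 1.0 + np.log(rss / n))
        k = len(fi) + 1
        return ProbeModel("", fixed, set(), -2.0 * ll + k * np.log(n), ll, k)

    ri, sizes = ws.random_indices(random)
    ZtZ = ws.BtB[np.ix_(ri, ri)]
    ZtX = ws.BtB[np.ix_(ri, fi)]
    Zty = By[ri]

    def neg_ll(log_gamma: np.ndarray) -> float:
        lg = np.clip(log_gamma, _LOG_GAMMA_LO, _LOG_GAMMA_HI)
        ll, _ = _profile_loglik(lg, sizes, XtX, Xty, yty, ZtZ, ZtX, Zty, n)
        return -ll

    d = len(sizes)
    if d == 1:
        res = optimize.minimize_scalar(
            lambda t: neg_ll(np.array([t])),
            bounds=(_LOG_GAMMA_LO, _LOG_GAMMA_HI),
            method="bounded",
            options={"xatol": 1e-3},
        )
        best = optimize.OptimizeResult(x=np.array([res.x]), fun=res.fun)
    else:
        start = np.full(d, -1.0) if start_log_gamma is None else start_log_gamma
        best = optimize.minimize(
            neg_ll,
            start,
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 300},
        )
    if best is None or not np.isfinite(best.fun):
        raise BloodvarError(
            f"mixed-model fit failed to converge for fixed={sorted(fixed)}, "
            f"random={sorted(random)}; optimizer trace: {best}"
        )
    lg = np.clip(best.x, _LOG_GAMMA_LO, _LOG_GAMMA_HI)
    ll = -float(best.fun)
    _, sigma2 = _profile_loglik(lg, sizes, XtX, Xty, yty, ZtZ, ZtX, Zty, n)
    gammas = np.exp(lg)
    # floor numerically-zero variance components at exactly 0 in the report
    gammas[gammas < 1e-10] = 0.0
    rvars = [v for v in ws.pool.random_candidates if v in random]
    ratios = {var: float(g * sigma2) for var, g in zip(rvars, gammas)}
    lg_map = {var: float(t) for var, t in zip(rvars, lg)}
    k = len(fi) + 1 + len(sizes)
    return ProbeModel(
        "", fixed, random, -2.0 * ll + k * np.log(n), ll, k, ratios, lg_map
    )


def forward_backward_select(
    y: np.ndarray,
    pool: CandidatePool,
    annotations: AnnotationTable | None = None,
    *,
    workspace: MixedModelWorkspace | None = None,
    probe_id: str = "",
) -> ProbeModel:
    """Greedy BIC search from the intercept-only model.

    Alternates a forward step (add the candidate yielding the largest BIC
    decrease) with backward sweeps (drop any variable whose removal lowers
    BIC) until no move improves.  The interaction term is only addable once
    both its main effects are in, and a main effect cannot be dropped while
    its interaction remains.  Any strict BIC decrease counts; ties are broken
    by candidate order in the pool.  Fit failures skip the offending move
    with a warning.
    """
    ws = workspace or MixedModelWorkspace(annotations, pool)
    By, yty = ws.suffstats(y)
    cache: dict[tuple, ProbeModel] = {}
    warm: dict[str, float] = {}

    def fit(fixed: frozenset, random: frozenset) -> ProbeModel | None:
        key = (fixed, random)
        if key not in cache:
            start = None
            if len(random) > 1:
                rvars = [v for v in pool.random_candidates if v in random]
                start = np.array([warm.get(v, -1.0) for v in rvars])
            try:
                m = _fit_from_suffstats(ws, set(fixed), set(random), By, yty, start)
                warm.update(m.log_gamma)
                cache[key] = m
            except BloodvarError as exc:
                warnings.warn(f"skipping move ({sorted(fixed)}, {sorted(random)}): {exc}")
                cache[key] = None
        return cache[key]

    order = {v: i for i, v in enumerate(pool.all_candidates)}
    fixed: frozenset = frozenset()
    random: frozenset = frozenset()
    current = fit(fixed, random)
    if current is None:
        raise BloodvarError("intercept-only model failed to fit")

    def addable() -> list[str]:
        out = []
        for v in pool.all_candidates:
            if v in fixed or v in random:
                continue
            parents = pool.hierarchy.get(v)
            if parents and not all(p in fixed for p in parents):
                continue
            out.append(v)
        return out

    def droppable() -> list[str]:
        out = []
        in_model = set(fixed) | set(random)
        protected = set()
        for inter, parents in pool.hierarchy.items():
            if inter in fixed:
                protected.update(parents)
        for v in pool.all_candidates:
            if v in in_model and v not in protected:
                out.append(v)
        return out

    improved = True
    while improved:
        improved = False
        # forward: best single addition
        best_move = None
        for v in addable():
            nf = fixed | {v} if v in pool.fixed_candidates else fixed
            nr = random | {v} if v in pool.random_candidates else random
            m = fit(frozenset(nf), frozenset(nr))
            if m is not None and m.bic < current.bic - 1e-10:
                cand = (m.bic, order[v], v, frozenset(nf), frozenset(nr), m)
                if best_move is None or cand[:2] < best_move[:2]:
                    best_move = cand
        if best_move is not None:
            _, _, _, fixed, random, current = best_move
            improved = True

        # backward sweep: keep dropping while it helps
        dropped = True
        while dropped:
            dropped = False
            best_drop = None
            for v in droppable():
                nf = fixed - {v}
                nr = random - {v}
                m = fit(frozenset(nf), frozenset(nr))
                if m is not None and m.bic < current.bic - 1e-10:
                    cand = (m.bic, order[v], v, frozenset(nf), frozenset(nr), m)
                    if best_drop is None or cand[:2] < best_drop[:2]:
                        best_drop = cand
            if best_drop is not None:
                _, _, _, fixed, random, current = best_drop
                dropped = True
                improved = True

    return ProbeModel(
        probe_id,
        set(fixed),
        set(random),
        current.bic,
        current.loglik,
        current.n_params,
        current.variance_ratios,
    )


@dataclass
class AssociationSummary:
    per_variable_counts: pd.Series
    mean_selected: float
    sd_selected: float
    fraction_technical: pd.Series
    fraction_multi_variable: float
    failed_probes: list[str]


def build_association_matrix(
    expr: ExpressionSet,
    pool: CandidatePool,
    annotations: AnnotationTable,
) -> tuple[pd.DataFrame, AssociationSummary]:
    """Run the per-probe search over the whole matrix.

    Returns the binary probes x candidate-variables membership matrix and a
    summary: per-variable probe counts, mean/SD of per-probe selected-variable
    counts, the fraction of probes selecting each random (technical) factor,
    and the fraction associated with at least two variables.
    """
    ann = annotations.aligned_to(expr.sample_ids)
    ws = MixedModelWorkspace(ann, pool)
    Y = expr.masked_values().to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise BloodvarError("matrix has missing values; run imputation first")

    cols = pool.all_candidates
    M = pd.DataFrame(
        np.zeros((expr.n_probes, len(cols)), dtype=bool),
        index=expr.probe_ids,
        columns=cols,
    )
    failed: list[str] = []
    for i, pid in enumerate(expr.probe_ids):
        try:
            model = forward_backward_select(Y[i], pool, workspace=ws, probe_id=str(pid))
        except BloodvarError:
            failed.append(str(pid))
            continue
        for v in model.selected_fixed | model.selected_random:
            M.loc[pid, v] = True

    ok = M.loc[~M.index.isin(failed)]
    row_counts = ok.sum(axis=1)
    summary = AssociationSummary(
        per_variable_counts=ok.sum(axis=0),
        mean_selected=float(row_counts.mean()) if len(ok) else float("nan"),
        sd_selected=float(row_counts.std(ddof=1)) if len(ok) > 1 else float("nan"),
        fraction_technical=ok[pool.random_candidates].mean(axis=0)
        if len(ok)
        else pd.Series(dtype=float),
        fraction_multi_variable=float((row_counts >= 2).mean()) if len(ok) else float("nan"),
        failed_probes=failed,
    )
    return M, summary


def unique_biological(
    assoc: pd.DataFrame,
    biological_variables: list[str],
    permitted_technical: tuple[str, ...] = ("array_lot",),
) -> dict[str, set[str]]:
    """Probes uniquely associated with a single biological/exposure variable.

    A probe counts as uniquely associated with variable ``v`` when its
    selected set, after removing the permitted technical terms (array lot by
    default), equals exactly ``{v}``.
    """
    unknown = [v for v in biological_variables if v not in assoc.columns]
    if unknown:
        raise BloodvarError(f"unknown variable names: {unknown}")
    out: dict[str, set[str]] = {v: set() for v in biological_variables}
    stripped = assoc.drop(columns=[c for c in permitted_technical if c in assoc.columns])
    row_sum = stripped.sum(axis=1)
    for v in biological_variables:
        sel = stripped.index[(row_sum == 1) & stripped[v]]
        out[v] = set(map(str, sel))
    return out
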