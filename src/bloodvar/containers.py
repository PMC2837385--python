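"""Core in-memory containers shared across the pipeline.

The pipeline operates on three parallel probe x sample matrices (intensity,
signal-to-noise, quality flags) plus a per-sample annotation table whose
columns are tagged with analysis roles.  Everything is pandas-backed so that
probe and sample identifiers travel with the numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Roles a covariate may play in the analysis.
ROLES = (
    "technical-random",
    "technical-fixed",
    "biological",
    "exposure",
    "interaction",
)

#: Flag values strictly above this mark a cell as unusable.
FLAG_THRESHOLD = 8191

#: Detection threshold on the signal-to-noise ratio.
SNR_THRESHOLD = 3.0


class BloodvarError(ValueError):
    """Base class for input / contract violations."""


@dataclass
class ExpressionSet:
    """Probe x sample intensity matrix with parallel S/N and flag matrices.

    Parameters
    ----------
    values
        Intensities, probes as rows, samples as columns.  ``scale`` records
        whether they are raw or log2.
    snr
        Per-cell signal-to-noise ratios (same shape), or None.
    flags
        Per-cell nonnegative integer quality codes (same shape), or None.
    missing_mask
        Boolean DataFrame, True where the measurement is unusable.  Missing
        cells carry no numeric weight downstream.
    scale
        ``"raw"`` or ``"log2"``.
    """

    values: pd.DataFrame
    snr: pd.DataFrame | None = None
    flags: pd.DataFrame | None = None
    missing_mask: pd.DataFrame | None = None
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.missing_mask is None:
            self.missing_mask = pd.DataFrame(
                np.zeros(self.values.shape, dtype=bool),
                index=self.values.index,
                columns=self.values.columns,
            )
        for name in ("snr", "flags", "missing_mask"):
            m = getattr(self, name)
            if m is not None and m.shape != self.values.shape:
                raise BloodvarError(
                    f"{name} matrix shape {m.shape} does not match values "
                    f"shape {self.values.shape}"
                )
        if self.values.index.duplicated().any():
            raise BloodvarError("duplicate probe ids")
        if self.values.columns.duplicated().any():
            raise BloodvarError("duplicate sample ids")
        if self.scale not in ("raw", "log2"):
            raise BloodvarError(f"unknown scale {self.scale!r}")

    # -- views ------------------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def masked_values(self) -> pd.DataFrame:
        """Intensities with missing cells as NaN."""
        return self.values.where(~self.missing_mask)

    # -- subsetting --------------------------------------------------------
    def _take(self, probes=None, samples=None) -> "ExpressionSet":
        def sub(df):
            if df is None:
                return None
            out = df
            if probes is not None:
                out = out.loc[probes]
            if samples is not None:
                out = out[samples]
            return out

        return replace(
            self,
            values=sub(self.values),
            snr=sub(self.snr),
            flags=sub(self.flags),
            missing_mask=sub(self.missing_mask),
        )

    def select_samples(self, sample_ids: Iterable) -> "ExpressionSet":
        return self._take(samples=list(sample_ids))

    def select_probes(self, probe_ids: Iterable) -> "ExpressionSet":
        return self._take(probes=list(probe_ids))

    def copy(self) -> "ExpressionSet":
        return replace(
            self,
            values=self.values.copy(),
            snr=None if self.snr is None else self.snr.copy(),
            flags=None if self.flags is None else self.flags.copy(),
            missing_mask=self.missing_mask.copy(),
        )


@dataclass
class AnnotationTable:
    """Per-sample covariates, each tagged with an analysis role.

    ``data`` is indexed by sample id; ``roles`` maps covariate column name to
    one of :data:`ROLES`.  ``subject`` optionally names a column identifying
    the blood donor, used to resolve technical replicates.
    """

    data: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)
    subject: str | None = None

    def __post_init__(self) -> None:
        for var, role in self.roles.items():
            if var not in self.data.columns:
                raise BloodvarError(f"role declared for unknown variable {var!r}")
            if role not in ROLES:
                raise BloodvarError(f"unknown role {role!r} for variable {var!r}")
        if self.subject is not None and self.subject not in self.data.columns:
            raise BloodvarError(f"subject column {self.subject!r} not present")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def variables(self, *roles: str) -> list[str]:
        """Column names whose role is in ``roles`` (all tagged if empty)."""
        if not roles:
            return list(self.roles)
        return [v for v, r in self.roles.items() if r in roles]

    def aligned_to(self, sample_ids: Iterable) -> "AnnotationTable":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.data.index]
        if missing:
            raise BloodvarError(
                f"annotation table lacks samples: {missing[:5]}"
            )
        return AnnotationTable(self.data.loc[ids].copy(), dict(self.roles), self.subject)


@dataclass
class QCReport:
    """Reconciliation record for the filtration cascade."""

    n_arrays_in: int
    n_arrays_out: int
    n_probes_in: int
    n_probes_out: int
    excluded_arrays: list[tuple[str, str]] = field(default_factory=list)
    excluded_probes: list[str] = field(default_factory=list)
    replicate_resolutions: list[tuple[tuple[str, ...], str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_arrays_out != self.n_arrays_in - len(self.excluded_arrays):
            raise BloodvarError("array counts do not reconcile with exclusions")
        if self.n_probes_out != self.n_probes_in - len(self.excluded_probes):
            raise BloodvarError("probe counts do not reconcile with exclusions")

    def merge(self, other: "QCReport") -> "QCReport":
        """Chain two stage reports (self ran first)."""
        if other.n_arrays_in != self.n_arrays_out or other.n_probes_in != self.n_probes_out:
            raise BloodvarError("chained QC reports do not reconcile")
        return QCReport(
            n_arrays_in=self.n_arrays_in,
            n_arrays_out=other.n_arrays_out,
            n_probes_in=self.n_probes_in,
            n_probes_out=other.n_probes_out,
            excluded_arrays=self.excluded_arrays + other.excluded_arrays,
            excluded_probes=self.excluded_probes + other.excluded_probes,
            replicate_resolutions=self.replicate_resolutions + other.replicate_resolutions,
        )


def design_matrix(
    annotations: AnnotationTable,
    variables: Iterable[str],
    *,
    intercept: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Dummy-encode covariates into a dense design matrix.

    Categorical (non-numeric or explicitly categorical) columns are encoded
    with first-level reference coding; an interaction term ``a:b`` is the
    elementwise product of the encodings of ``a`` and ``b``.  Returns the
    matrix and its column names.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    n = len(annotations.data)
    if intercept:
        cols.append(np.ones(n))
        names.append("Intercept")
    for var in variables:
        for col, name in _encode(annotations, var):
            cols.append(col)
            names.append(name)
    X = np.column_stack(cols) if cols else np.empty((n, 0))
    return X, names


def _encode(annotations: AnnotationTable, var: str) -> list[tuple[np.ndarray, str]]:
    if ":" in var or "*" in var:
        sep = ":" if ":" in var else "*"
        a, b = (s.strip() for s in var.split(sep, 1))
        out = []
        for ca, na in _encode(annotations, a):
            for cb, nb in _encode(annotations, b):
                out.append((ca * cb, f"{na}:{nb}"))
        return out
    if var not in annotations.data.columns:
        raise BloodvarError(f"unknown variable {var!r}")
    s = annotations.data[var]
    if pd.api.types.is_numeric_dtype(s) and not isinstance(s.dtype, pd.CategoricalDtype):
        return [(s.to_numpy(dtype=float), var)]
    levels = pd.unique(s.astype(str))
    levels = sorted(levels)
    return [
        ((s.astype(str) == lev).to_numpy(dtype=float), f"{var}[{lev}]")
        for lev in levels[1:]
    ]


def check_full_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise naming aliased columns if the design is rank deficient."""
    if X.shape[1] == 0:
        return
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by greedy QR-style scan
        aliased = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                aliased.append(names[j])
        raise BloodvarError(f"rank-deficient design; aliased terms: {aliased}")
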