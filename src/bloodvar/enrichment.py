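"""Curated gene-set enrichment via the global test.

Each curated set is mapped to the probes measured on the platform, scored by
the global test against an outcome, adjusted across sets by the
Benjamini-Hochberg false discovery rate, and additionally given a
*comparative* p-value: the fraction of random same-size probe sets with a
larger standardized set statistic.  Standardization makes the set statistic
comparable across sizes, so the comparative value is a competitive measure
of how special the curated membership is, not just how strong the outcome
signal is.  Core member probes and their direction of regulation come from
the weighted core-selection rule applied within the set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bh_adjust
from .containers import AnnotationTable, BloodvarError, ExpressionSet
from .coreselect import (
    GlobalTestEngine,
    association_direction,
    select_core_weighted,
)


@dataclass
class GeneSet:
    name: str
    source: str
    member_ids: list[str]
    mapped_probes: list[str] = field(default_factory=list)
    unmapped_members: list[str] = field(default_factory=list)


@dataclass
class EnrichmentRow:
    set_name: str
    n_tested: int
    p: float
    fdr: float
    comparative_p: float
    set_z: float
    core_up_group1: list[str]
    core_up_group0: list[str]


def read_gmt(path) -> list[GeneSet]:
    """Read curated gene sets from a GMT file."""
    import gseapy

    raw = gseapy.read_gmt(str(path))
    return [GeneSet(name=k, source=str(path), member_ids=list(v)) for k, v in raw.items()]


def map_gene_sets(
    gene_sets: list[GeneSet],
    expr: ExpressionSet,
    gene_to_probe: pd.DataFrame | None = None,
) -> list[GeneSet]:
    """Resolve gene members to measured probes.

    ``gene_to_probe`` is a two-column frame (gene, probe); genes matched by
    several probes contribute all of them.  Without a mapping, member ids are
    taken to be probe ids already.  Unmapped members are recorded on the set,
    never silently dropped.
    """
    measured = set(map(str, expr.probe_ids))
    mapping: dict[str, list[str]] = {}
    if gene_to_probe is not None:
        if gene_to_probe.shape[1] < 2:
            raise BloodvarError("gene-to-probe mapping needs two columns")
        g, p = gene_to_probe.columns[:2]
        for gene, probe in zip(gene_to_probe[g].astype(str), gene_to_probe[p].astype(str)):
            mapping.setdefault(gene, []).append(probe)
    out = []
    for gs in gene_sets:
        probes: list[str] = []
        unmapped: list[str] = []
        for m in gs.member_ids:
            cand = mapping.get(str(m), [str(m)] if gene_to_probe is None else [])
            hits = [c for c in cand if c in measured]
            if hits:
                probes.extend(hits)
            else:
                unmapped.append(str(m))
        seen = set()
        probes = [p for p in probes if not (p in seen or seen.add(p))]
        out.append(
            GeneSet(gs.name, gs.source, list(gs.member_ids), probes, unmapped)
        )
    return out


def test_gene_set(
    expr: ExpressionSet,
    annotations: AnnotationTable,
    outcome: str,
    gene_set: GeneSet,
    adjust: list[str] = (),
    n_perm: int = 1000,
    seed: int = 0,
    engine: GlobalTestEngine | None = None,
) -> EnrichmentRow:
    """Global-test p-value and directional core members for one set.

    ``fdr`` and ``comparative_p`` are filled by the batch runners; here they
    are NaN placeholders.
    """
    if not gene_set.mapped_probes:
        raise BloodvarError(f"gene set {gene_set.name!r} maps to zero measured probes")
    eng = engine or GlobalTestEngine(expr, annotations, outcome, adjust, n_perm, seed)
    scores = eng.scores(gene_set.mapped_probes)
    core = select_core_weighted(scores, variable=outcome)
    directions = association_direction(
        expr, annotations, outcome, core.core_probes, adjust
    )
    up1 = sorted(p for p, d in directions.items() if d == "up-in-level-1")
    up0 = sorted(p for p, d in directions.items() if d == "up-in-level-0")
    return EnrichmentRow(
        set_name=gene_set.name,
        n_tested=len(gene_set.mapped_probes),
        p=scores.set_p,
        fdr=float("nan"),
        comparative_p=float("nan"),
        set_z=scores.set_z,
        core_up_group1=up1,
        core_up_group0=up0,
    )


def adjust_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    return bh_adjust(pvals)


def comparative_pvalue(
    expr: ExpressionSet,
    annotations: AnnotationTable,
    outcome: str,
    gene_set: GeneSet,
    adjust: list[str] = (),
    n_random: int = 1000,
    n_perm: int = 1000,
    seed: int = 0,
    engine: GlobalTestEngine | None = None,
) -> float:
    """Fraction of random same-size probe sets with a larger set z-score.

    Random sets are drawn uniformly without replacement from all measured
    probes.  No add-one correction: a set beating every random draw reports
    exactly 0, matching the sub-percent reporting scale this statistic is
    used at.
    """
    size = len(gene_set.mapped_probes)
    if size == 0:
        raise BloodvarError(f"gene set {gene_set.name!r} maps to zero measured probes")
    eng = engine or GlobalTestEngine(expr, annotations, outcome, adjust, n_perm, seed)
    n_probes = len(eng.probe_ids)
    if size > n_probes:
        raise BloodvarError("set size exceeds the number of measured probes")
    obs = eng.set_z_for_rows(eng._rows(gene_set.mapped_probes))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    larger = 0
    for _ in range(n_random):
        rows = rng.choice(n_probes, size=size, replace=False)
        if eng.set_z_for_rows(rows) > obs:
            larger += 1
    return larger / n_random


def enrichment_table(
    expr: ExpressionSet,
    annotations: AnnotationTable,
    outcome: str,
    gene_sets: list[GeneSet],
    adjust: list[str] = (),
    n_perm: int = 1000,
    n_random: int = 1000,
    seed: int = 0,
) -> list[EnrichmentRow]:
    """Score a batch of curated sets: p, FDR across the batch, comparative p."""
    engine = GlobalTestEngine(expr, annotations, outcome, adjust, n_perm, seed)
    rows = [
        test_gene_set(expr, annotations, outcome, gs, adjust, n_perm, seed, engine=engine)
        for gs in gene_sets
    ]
    fdrs = adjust_fdr([r.p for r in rows])
    for r, f in zip(rows, fdrs):
        r.fdr = float(f)
    for r, gs in zip(rows, gene_sets):
        r.comparative_p = comparative_pvalue(
            expr, annotations, outcome, gs, adjust, n_random, n_perm, seed, engine=engine
        )
    return rows
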