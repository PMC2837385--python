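"""File formats, configuration, and the end-to-end pipeline runner.

Formats: tab-delimited probe x sample matrices (first column probe id),
annotation CSV with commented role declarations, GMT gene sets, an optional
two-column gene-to-probe map, and a read-only GEO Series Matrix dialect.
Every run writes a provenance record (config, seed, package versions), and
all randomness flows from the single config seed, so re-runs are
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancova import interaction_test, screen_variables
from .cohort import (
    BIOLOGICAL_VARIABLES,
    EXPOSURE_VARIABLES,
    CohortConfig,
    CohortTruth,
    simulate_cohort,
)
from .containers import AnnotationTable, BloodvarError, ExpressionSet
from .coreselect import GlobalTestEngine, select_core_weighted
from .eigenr2 import eigen_r2
from .enrichment import enrichment_table, map_gene_sets, read_gmt
from .model_selection import (
    CandidatePool,
    build_association_matrix,
    unique_biological,
)
from .qc import qc_pipeline

# ---------------------------------------------------------------------------
# matrix / annotation round trips


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="probe_id")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise BloodvarError(f"duplicate probe ids in {path}")
    if df.columns.duplicated().any():
        raise BloodvarError(f"duplicate sample ids in {path}")
    return df


def write_annotations(ann: AnnotationTable, path) -> None:
    with open(path, "w") as fh:
        for var, role in ann.roles.items():
            fh.write(f"#role {var} {role}\n")
        if ann.subject:
            fh.write(f"#subject {ann.subject}\n")
        ann.data.to_csv(fh, index_label="sample_id")


def read_annotations(path) -> AnnotationTable:
    roles: dict[str, str] = {}
    subject = None
    lines = Path(path).read_text().splitlines(keepends=True)
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#role "):
            _, var, role = line.split(None, 2)
            roles[var] = role.strip()
        elif line.startswith("#subject "):
            subject = line.split(None, 1)[1].strip()
        else:
            body_start = i
            break
    import io as _io

    data = pd.read_csv(_io.StringIO("".join(lines[body_start:])), index_col=0)
    return AnnotationTable(data, roles, subject=subject)


def read_expression_set(
    expression_path, snr_path=None, flags_path=None
) -> ExpressionSet:
    values = read_matrix(expression_path)
    snr = read_matrix(snr_path) if snr_path else None
    flags = read_matrix(flags_path) if flags_path else None
    for name, m in (("S/N", snr), ("flags", flags)):
        if m is not None and (
            not m.index.equals(values.index) or not m.columns.equals(values.columns)
        ):
            raise BloodvarError(f"{name} matrix ids do not match the expression matrix")
    return ExpressionSet(values=values, snr=snr, flags=flags, scale="raw")


def read_series_matrix(path) -> pd.DataFrame:
    """Read the data table of a GEO Series Matrix file (read-only dialect)."""
    rows = []
    header = None
    with open(path) as fh:
        in_table = False
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                break
            if not in_table or not line:
                continue
            parts = [p.strip('"') for p in line.split("\t")]
            if header is None:
                header = parts
            else:
                rows.append(parts)
    if header is None:
        raise BloodvarError(f"{path} contains no series matrix table")
    df = pd.DataFrame(rows, columns=header).set_index(header[0])
    return df.apply(pd.to_numeric, errors="coerce")


def write_truth(truth: CohortTruth, path) -> None:
    record = {
        "affected_probes": {k: sorted(v) for k, v in truth.affected_probes.items()},
        "variance_fraction_technical": truth.variance_fraction_technical,
        "variance_fraction_biological": truth.variance_fraction_biological,
        "replicate_pairs": [list(p) for p in truth.replicate_pairs],
    }
    Path(path).write_text(json.dumps(record, indent=1))


def read_truth(path) -> CohortTruth:
    record = json.loads(Path(path).read_text())
    return CohortTruth(
        affected_probes={k: set(v) for k, v in record["affected_probes"].items()},
        variance_fraction_technical=record["variance_fraction_technical"],
        variance_fraction_biological=record["variance_fraction_biological"],
        replicate_pairs=[tuple(p) for p in record["replicate_pairs"]],
    )


def simulate_to_dir(config: CohortConfig, out_dir) -> None:
    """Generate a cohort and write the standard pipeline inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, ann, truth = simulate_cohort(config)
    write_matrix(expr.values, out / "expression.tsv")
    write_matrix(expr.snr, out / "snr.tsv")
    write_matrix(expr.flags, out / "flags.tsv")
    write_annotations(ann, out / "annotations.csv")
    write_truth(truth, out / "truth.json")
    (out / "cohort_config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config)))


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass
class PipelineConfig:
    """All paths, thresholds and stage toggles for a pipeline run."""

    expression_path: str | None = None
    snr_path: str | None = None
    flags_path: str | None = None
    annotations_path: str | None = None
    gene_sets_path: str | None = None
    gene_probe_map_path: str | None = None
    out_dir: str = "bloodvar_out"

    stages: list[str] = field(
        default_factory=lambda: [
            "qc",
            "screen",
            "eigenr2",
            "select",
            "core",
            "unique",
            "enrich",
        ]
    )

    flag_threshold: int = 8191
    snr_threshold: float = 3.0
    array_fraction: float = 0.40
    probe_fraction: float = 0.50
    knn_k: int = 10
    alpha_screen: float = 0.001
    w_tp: float = 2.0
    w_fp: float = 1.0
    n_perm_screen: int = 1000
    n_perm_test: int = 1000
    n_random_sets: int = 1000
    enrichment_outcomes: list[str] = field(default_factory=lambda: ["smoking"])
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("flag_threshold", "snr_threshold", "array_fraction",
                     "probe_fraction", "knn_k", "alpha_screen", "w_tp", "w_fp"):
            if getattr(self, name) <= 0:
                raise BloodvarError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def read_inputs(config: PipelineConfig):
    """Load expression set, annotations and gene sets named by the config."""
    if not config.expression_path or not config.annotations_path:
        raise BloodvarError("config must name expression and annotation files")
    expr = read_expression_set(config.expression_path, config.snr_path, config.flags_path)
    ann = read_annotations(config.annotations_path)
    missing = [s for s in expr.sample_ids if s not in ann.data.index]
    if missing:
        raise BloodvarError(f"annotations missing for samples: {missing[:5]}")
    extra = [s for s in ann.data.index if s not in set(expr.sample_ids)]
    if extra:
        raise BloodvarError(f"annotation rows for unknown samples: {extra[:5]}")
    gene_sets = read_gmt(config.gene_sets_path) if config.gene_sets_path else []
    if gene_sets and config.gene_probe_map_path:
        gmap = pd.read_csv(config.gene_probe_map_path, sep="\t")
        gene_sets = map_gene_sets(gene_sets, expr, gmap)
    elif gene_sets:
        gene_sets = map_gene_sets(gene_sets, expr)
    return expr, ann, gene_sets


# ---------------------------------------------------------------------------
# pipeline runner


@dataclass
class PipelineResult:
    qc_report: object = None
    screen: object = None
    interaction: object = None
    eigen_r2_technical: object = None
    eigen_r2_biological: object = None
    association: pd.DataFrame | None = None
    association_summary: object = None
    core: dict = field(default_factory=dict)
    unique: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)


def run_pipeline(
    config: PipelineConfig,
    expr: ExpressionSet | None = None,
    annotations: AnnotationTable | None = None,
    gene_sets=None,
) -> PipelineResult:
    """Execute the analysis stages in order, persisting each one.

    Stage order: QC -> technical screen -> eigenR2 -> per-probe selection ->
    core selection -> unique association -> enrichment.  Inputs may be passed
    in memory or read from the config's paths.  On a stage failure the
    checkpoint file in the output directory names the completed stages.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if expr is None or annotations is None:
        expr, annotations, file_sets = read_inputs(config)
        if gene_sets is None:
            gene_sets = file_sets
    gene_sets = gene_sets or []

    provenance = {
        "config": dataclasses.asdict(config),
        "bloodvar_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    (out / "provenance.yaml").write_text(yaml.safe_dump(provenance))

    result = PipelineResult()
    completed: list[str] = []

    def checkpoint(stage: str) -> None:
        completed.append(stage)
        (out / "checkpoint.json").write_text(json.dumps({"completed": completed}))

    stages = list(config.stages)
    try:
        if "qc" in stages:
            expr, annotations, report = qc_pipeline(
                expr,
                annotations,
                flag_threshold=config.flag_threshold,
                array_fraction=config.array_fraction,
                probe_fraction=config.probe_fraction,
                k=config.knn_k,
            )
            result.qc_report = report
            _write_qc_report(report, out / "qc_report.tsv")
            checkpoint("qc")

        technical = annotations.variables("technical-random", "technical-fixed")
        biological = [
            v
            for v in annotations.variables("biological", "exposure")
            if v in annotations.data.columns
        ]

        if "screen" in stages:
            result.screen = screen_variables(
                expr,
                annotations,
                technical,
                alpha=config.alpha_screen,
                n_perm=config.n_perm_screen,
                seed=config.seed,
            )
            rows = [
                {
                    "variable": v,
                    "univariate_p": result.screen.univariate[v].perm_p,
                    "multivariate_p": result.screen.multivariate[v].perm_p,
                    "passed": v in result.screen.passed,
                    "role": result.screen.roles.get(v, ""),
                }
                for v in technical
            ]
            pd.DataFrame(rows).to_csv(out / "technical_screen.tsv", sep="\t", index=False)
            if "HT" in biological and "MED" in biological:
                result.interaction = interaction_test(
                    expr, annotations, "HT", "MED",
                    [v for v in biological if v not in ("HT", "MED")],
                    n_perm=config.n_perm_screen, seed=config.seed + 7,
                )
            checkpoint("screen")
            technical_selected = result.screen.passed
            random_vars = [v for v in technical_selected
                           if result.screen.roles.get(v) == "random"]
            fixed_tech = [v for v in technical_selected
                          if result.screen.roles.get(v) == "fixed"]
        else:
            technical_selected = technical
            random_vars = annotations.variables("technical-random")
            fixed_tech = annotations.variables("technical-fixed")

        if "eigenr2" in stages:
            result.eigen_r2_technical = eigen_r2(expr, annotations, technical_selected)
            result.eigen_r2_biological = eigen_r2(expr, annotations, biological)
            pd.DataFrame(
                [
                    {"variables": "technical",
                     "eigen_r2": result.eigen_r2_technical.eigen_r2},
                    {"variables": "biological",
                     "eigen_r2": result.eigen_r2_biological.eigen_r2},
                ]
            ).to_csv(out / "eigen_r2.tsv", sep="\t", index=False)
            checkpoint("eigenr2")

        pool = None
        if "select" in stages:
            fixed = biological + fixed_tech
            hierarchy = {}
            if "HT" in biological and "MED" in biological:
                fixed = fixed + ["HT:MED"]
                hierarchy["HT:MED"] = ("HT", "MED")
            pool = CandidatePool(
                fixed_candidates=fixed,
                random_candidates=random_vars,
                hierarchy=hierarchy,
            )
            result.association, result.association_summary = build_association_matrix(
                expr, pool, annotations
            )
            result.association.astype(int).to_csv(out / "association_matrix.tsv", sep="\t")
            checkpoint("select")

        if "core" in stages and result.association is not None:
            for var in biological:
                probes = list(result.association.index[result.association[var]])
                if not probes:
                    result.core[var] = None
                    continue
                engine = GlobalTestEngine(
                    expr.select_probes(probes),
                    annotations,
                    var,
                    n_perm=config.n_perm_test,
                    seed=config.seed + 101,
                )
                scores = engine.scores(probes)
                result.core[var] = select_core_weighted(
                    scores, config.w_tp, config.w_fp, variable=var
                )
            checkpoint("core")

        if "unique" in stages and result.association is not None:
            # exempt the dominant batch factor (the one most probes select),
            # since filtering on it would empty the unique lists
            permitted: tuple[str, ...] = ()
            if random_vars:
                counts = result.association[random_vars].sum(axis=0)
                permitted = (str(counts.idxmax()),)
            result.unique = unique_biological(
                result.association, biological, permitted_technical=permitted
            )
            checkpoint("unique")

        if "enrich" in stages and gene_sets:
            for outcome in config.enrichment_outcomes:
                result.enrichment[outcome] = enrichment_table(
                    expr,
                    annotations,
                    outcome,
                    [g for g in gene_sets if g.mapped_probes],
                    n_perm=config.n_perm_test,
                    n_random=config.n_random_sets,
                    seed=config.seed + 211,
                )
            checkpoint("enrich")
    except Exception:
        (out / "checkpoint.json").write_text(
            json.dumps({"completed": completed, "failed": True})
        )
        raise

    write_report(result, out)
    return result


# ---------------------------------------------------------------------------
# reports


def _write_qc_report(report, path) -> None:
    rows = [
        {"item": "arrays_in", "value": report.n_arrays_in, "reason": ""},
        {"item": "arrays_out", "value": report.n_arrays_out, "reason": ""},
        {"item": "probes_in", "value": report.n_probes_in, "reason": ""},
        {"item": "probes_out", "value": report.n_probes_out, "reason": ""},
    ]
    for sid, reason in report.excluded_arrays:
        rows.append({"item": "excluded_array", "value": sid, "reason": reason})
    for pid in report.excluded_probes:
        rows.append({"item": "excluded_probe", "value": pid, "reason": "detection < 50%"})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_report(result: PipelineResult, out_dir) -> None:
    """Per-variable summary and enrichment tables, bit-stable ordering."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if result.association is not None:
        rows = []
        for var in result.association.columns:
            n_sel = int(result.association[var].sum())
            core = result.core.get(var)
            rows.append(
                {
                    "variable": var,
                    "n_probes_selected": n_sel,
                    "n_core_probes": len(core.core_probes) if core else 0,
                    "fdr_at_threshold": round(core.fdr_at_threshold, 4) if core else "",
                    "n_unique": len(result.unique.get(var, ())) if result.unique else "",
                }
            )
        pd.DataFrame(rows).to_csv(out / "variable_summary.tsv", sep="\t", index=False)

    for outcome, rows in result.enrichment.items():
        table = pd.DataFrame(
            [
                {
                    "gene_set": r.set_name,
                    "tested_genes": r.n_tested,
                    "p_value": r.p,
                    "fdr_adjusted": r.fdr,
                    "comparative_p": r.comparative_p,
                    "core_up_group1": ";".join(r.core_up_group1),
                    "core_up_group0": ";".join(r.core_up_group0),
                }
                for r in rows
            ]
        )
        table.to_csv(out / f"enrichment_{outcome}.tsv", sep="\t", index=False)
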