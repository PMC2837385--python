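"""Synthetic whole-blood cohort generator.

Emulates the statistical structure the downstream analysis assumes: a few
hundred arrays with technical replicates, crossed batch random effects
(array lot, RNA extraction date), a fixed degradation covariate (days from
blood collection to freezing), binary biological/exposure covariates that
shift a configured fraction of probes, long-tailed probe baselines, and a
detection layer (signal-to-noise, quality flags) feeding the QC filters.

Every random draw flows from the config seed, so outputs are byte-identical
across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import AnnotationTable, BloodvarError, ExpressionSet

#: Default covariate prevalences (probability of the "1"/exposed class),
#: mirroring a postmenopausal population cohort: mostly non-smokers, ~10%
#: fasting at blood draw, roughly half overweight (BMI >= 25), age split at
#: its median, ~30% on hormone therapy, ~58% using some other medication.
DEFAULT_PREVALENCES = {
    "smoking": 0.25,
    "fasting": 0.10,
    "bmi_class": 0.46,
    "age_class": 0.50,
    "HT": 0.30,
    "MED": 0.582,
}

BIOLOGICAL_VARIABLES = ("age_class", "bmi_class", "fasting")
EXPOSURE_VARIABLES = ("smoking", "HT", "MED")


@dataclass
class CohortConfig:
    """Design of a simulated cohort.

    All intensity scales are in log2 units.  ``effect_fraction[v]`` is the
    fraction of probes whose expression shifts with covariate ``v``;
    ``effect_size[v]`` the mean absolute log2 shift on those probes.
    """

    n_samples: int = 289
    n_probes: int = 16185
    n_lots: int = 10
    n_extraction_dates: int = 25
    n_decoy_technical: int = 5
    # default variance scales are solved so the designed probe-centered
    # variance splits 46.5% technical / 8.1% biological / rest residual
    # (finite-level corrections at the default lot/date counts included)
    sd_lot: float = 0.4409549
    sd_extraction: float = 0.2309764
    beta_freeze: float = 0.1994796
    max_freeze_days: float = 3.0
    covariate_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    effect_fraction: dict[str, float] = field(
        default_factory=lambda: {v: 0.10 for v in DEFAULT_PREVALENCES}
    )
    effect_size: dict[str, float] = field(
        default_factory=lambda: {v: 0.6023897 for v in DEFAULT_PREVALENCES}
    )
    sd_resid: float = 0.50
    baseline_mean: float = 7.0
    baseline_scale: float = 1.6
    flag_fail_fraction: float = 0.01
    snr_noise_scale: float = 14.0
    n_replicate_pairs: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sd_lot, self.sd_extraction, self.sd_resid) < 0:
            raise BloodvarError("standard deviations must be nonnegative")
        if self.n_lots < 1 or self.n_extraction_dates < 1:
            raise BloodvarError("n_lots and n_extraction_dates must be >= 1")
        if self.n_lots > self.n_samples:
            raise BloodvarError("n_lots exceeds n_samples")
        for name, d in (
            ("covariate_prevalences", self.covariate_prevalences),
            ("effect_fraction", self.effect_fraction),
        ):
            for v, p in d.items():
                if not 0.0 <= p <= 1.0:
                    raise BloodvarError(f"{name}[{v!r}] = {p} outside [0, 1]")
        if not 0.0 <= self.flag_fail_fraction <= 1.0:
            raise BloodvarError("flag_fail_fraction outside [0, 1]")

    @classmethod
    def with_variance_fractions(
        cls,
        technical: float = 0.465,
        biological: float = 0.081,
        **kwargs,
    ) -> "CohortConfig":
        """Config whose designed variance fractions hit the given targets.

        Keeps the relative split between lot, extraction-date and freezing
        variance and between the covariate effects, and rescales them so that
        (technical variance) / (total) and (biological variance) / (total)
        equal the requested fractions, with total = technical + biological +
        residual.  Fractions are of the probe-centered (sample-wise) variance,
        which is what the eigen-R2 decomposition sees; the sample variance of
        an L-level random intercept is sd^2 * (1 - 1/L), and that finite-level
        correction is applied here so the realized fractions land on target.
        """
        if technical + biological >= 1.0:
            raise BloodvarError("variance fractions must sum to < 1")
        cfg = cls(**kwargs)
        resid_var = cfg.sd_resid**2
        total = resid_var / (1.0 - technical - biological)

        tech_now = (
            cfg.sd_lot**2 * (1.0 - 1.0 / cfg.n_lots)
            + cfg.sd_extraction**2 * (1.0 - 1.0 / cfg.n_extraction_dates)
            + cfg.beta_freeze**2 * cfg.max_freeze_days**2 / 12.0
        )
        tech_scale = np.sqrt(technical * total / tech_now) if tech_now > 0 else 0.0

        bio_now = sum(
            cfg.effect_fraction.get(v, 0.0)
            * cfg.effect_size.get(v, 0.0) ** 2
            * p
            * (1.0 - p)
            for v, p in cfg.covariate_prevalences.items()
        )
        bio_scale = np.sqrt(biological * total / bio_now) if bio_now > 0 else 0.0

        return replace(
            cfg,
            sd_lot=cfg.sd_lot * tech_scale,
            sd_extraction=cfg.sd_extraction * tech_scale,
            beta_freeze=cfg.beta_freeze * tech_scale,
            effect_size={v: s * bio_scale for v, s in cfg.effect_size.items()},
        )


@dataclass
class CohortTruth:
    """Ground truth recorded by the generator for recovery testing."""

    affected_probes: dict[str, set[str]] = field(default_factory=dict)
    variance_fraction_technical: float = 0.0
    variance_fraction_biological: float = 0.0
    replicate_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("variance_fraction_technical", "variance_fraction_biological"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise BloodvarError(f"{name} = {v} outside [0, 1]")
        if self.variance_fraction_technical + self.variance_fraction_biological > 1.0 + 1e-12:
            raise BloodvarError("variance fractions exceed 1 jointly")


def generate_annotations(config: CohortConfig) -> AnnotationTable:
    """Draw per-sample technical and biological covariates.

    Lot and extraction date are categorical labels assigned uniformly (so the
    two batch factors are crossed, not nested); time to freezing is uniform on
    [0, max_freeze_days].  Binary covariates are Bernoulli at the configured
    prevalences.  Decoy technical variables are continuous processing
    measurements with no expression effect.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]

    # every lot/date level occurs at least once, remainder uniform
    def assign_levels(n_levels: int, prefix: str) -> np.ndarray:
        base = np.array(
            [f"{prefix}{k:02d}" for k in range(n_levels)], dtype=object
        )
        labels = np.concatenate([base, rng.choice(base, size=n - n_levels)])
        rng.shuffle(labels)
        return labels

    data = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    data["array_lot"] = assign_levels(config.n_lots, "L")
    data["extraction_date"] = assign_levels(config.n_extraction_dates, "D")
    data["freeze_days"] = rng.uniform(0.0, config.max_freeze_days, size=n)

    roles = {
        "array_lot": "technical-random",
        "extraction_date": "technical-random",
        "freeze_days": "technical-fixed",
    }
    for j in range(config.n_decoy_technical):
        name = f"tech_decoy_{j}"
        data[name] = rng.normal(size=n)
        roles[name] = "technical-fixed"

    for var, p in config.covariate_prevalences.items():
        data[var] = rng.binomial(1, p, size=n)
        roles[var] = "biological" if var in BIOLOGICAL_VARIABLES else "exposure"

    data["subject"] = sample_ids
    return AnnotationTable(data, roles, subject="subject")


def generate_expression(
    annotations: AnnotationTable, config: CohortConfig
) -> tuple[ExpressionSet, CohortTruth]:
    """Simulate the intensity matrix and record ground truth.

    Model per probe g and sample j (log2 scale):

        y_gj = mu_g + lot_{g, lot(j)} + date_{g, date(j)}
               + beta_freeze * sign_g * days_j            (a probe subset)
               + sum_v delta_gv * x_vj                    (affected probes)
               + eps_gj

    Lot and date intercepts are probe-specific draws (crossed random
    effects); covariate shifts delta_gv have magnitude effect_size[v] and
    random sign on the configured fraction of probes.  Probe baselines mu_g
    come from a shifted-exponential (long-tailed) distribution so quantile
    normalization has real work to do.  The freezing-time slope also acts on
    a probe subset (fraction as for covariates' mean, default 0.5) — a fixed
    technical gradient.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(annotations.data)
    G = config.n_probes
    probe_ids = pd.Index([f"P{i:05d}" for i in range(G)], name="probe_id")

    mu = config.baseline_mean + rng.exponential(config.baseline_scale, size=G)

    lot_codes, lot_levels = pd.factorize(annotations.data["array_lot"])
    date_codes, date_levels = pd.factorize(annotations.data["extraction_date"])
    lot_eff = rng.normal(0.0, config.sd_lot, size=(G, len(lot_levels)))
    date_eff = rng.normal(0.0, config.sd_extraction, size=(G, len(date_levels)))
    days = annotations.data["freeze_days"].to_numpy()
    freeze_sign = rng.choice([-1.0, 1.0], size=G)

    technical = (
        lot_eff[:, lot_codes]
        + date_eff[:, date_codes]
        + config.beta_freeze * freeze_sign[:, None] * days[None, :]
    )

    biological = np.zeros((G, n))
    affected: dict[str, set[str]] = {}
    # effect_fraction may also name interaction terms like "HT:MED", whose
    # regressor is the product of the parent columns
    effect_vars = list(config.covariate_prevalences) + [
        v for v in config.effect_fraction if v not in config.covariate_prevalences
    ]
    for var in effect_vars:
        frac = config.effect_fraction.get(var, 0.0)
        size = config.effect_size.get(var, 0.0)
        n_aff = int(round(frac * G))
        idx = rng.choice(G, size=n_aff, replace=False)
        affected[var] = set(probe_ids[np.sort(idx)])
        if n_aff and size != 0.0:
            delta = size * rng.choice([-1.0, 1.0], size=n_aff)
            if ":" in var:
                a, b = var.split(":", 1)
                x = (
                    annotations.data[a].to_numpy(dtype=float)
                    * annotations.data[b].to_numpy(dtype=float)
                )
            else:
                x = annotations.data[var].to_numpy(dtype=float)
            biological[idx] += delta[:, None] * x[None, :]

    resid = rng.normal(0.0, config.sd_resid, size=(G, n))
    values = mu[:, None] + technical + biological + resid

    # realized fractions of probe-centered variance, from the components
    def comp_var(m: np.ndarray) -> float:
        return float(np.mean(np.var(m, axis=1)))

    v_tech = comp_var(technical)
    v_bio = comp_var(biological)
    v_tot = v_tech + v_bio + comp_var(resid)
    truth = CohortTruth(
        affected_probes=affected,
        variance_fraction_technical=v_tech / v_tot if v_tot else 0.0,
        variance_fraction_biological=v_bio / v_tot if v_tot else 0.0,
    )

    expr = ExpressionSet(
        values=pd.DataFrame(values, index=probe_ids, columns=annotations.data.index),
        scale="log2",
    )
    return expr, truth


def simulate_detection(expr: ExpressionSet, config: CohortConfig) -> ExpressionSet:
    """Attach signal-to-noise ratios and quality flags.

    S/N is linear-scale intensity divided by a per-array noise constant with
    multiplicative jitter, so it is monotone in intensity within an array; a
    configured fraction of cells fails outright (flag above the unusable
    threshold and S/N pulled below detection).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    G, n = expr.values.shape
    linear = np.exp2(expr.values.to_numpy()) if expr.scale == "log2" else expr.values.to_numpy()

    noise = config.snr_noise_scale * rng.lognormal(0.0, 0.15, size=n)
    jitter = rng.lognormal(0.0, 0.10, size=(G, n))
    snr = linear / noise[None, :] * jitter

    flags = rng.integers(0, 4096, size=(G, n))
    fail = rng.random(size=(G, n)) < config.flag_fail_fraction
    flags = np.where(fail, 8192 + rng.integers(0, 1024, size=(G, n)), flags)
    snr = np.where(fail, rng.uniform(0.0, 1.0, size=(G, n)), snr)

    return replace(
        expr,
        snr=pd.DataFrame(snr, index=expr.probe_ids, columns=expr.sample_ids),
        flags=pd.DataFrame(flags, index=expr.probe_ids, columns=expr.sample_ids),
    )


def spike_replicates(
    expr: ExpressionSet,
    annotations: AnnotationTable,
    n_pairs: int,
    seed: int,
) -> tuple[ExpressionSet, AnnotationTable, CohortTruth]:
    """Duplicate chosen samples as technical replicate arrays.

    The replicate keeps the subject's biological/technical covariates but is
    re-hybridized: it receives fresh residual noise of the same scale
    (estimated from the probe-wise residual spread) and, if detection has
    been simulated, fresh S/N jitter and flags are expected to be assigned by
    re-running :func:`simulate_detection` on the result.
    """
    if n_pairs > expr.n_samples:
        raise BloodvarError("more replicate pairs than samples")
    if n_pairs == 0:
        return expr, annotations, CohortTruth(replicate_pairs=[])

    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    chosen = rng.choice(expr.n_samples, size=n_pairs, replace=False)
    chosen.sort()

    vals = expr.values.to_numpy()
    # technical re-hybridization noise: half the probe-wise residual spread
    sd = float(np.median(np.std(vals, axis=1))) * 0.5
    new_cols, new_ids, pairs = [], [], []
    ann = annotations.data.copy()
    for j in chosen:
        sid = expr.sample_ids[j]
        rid = f"{sid}r"
        new_cols.append(vals[:, j] + rng.normal(0.0, sd, size=expr.n_probes))
        new_ids.append(rid)
        pairs.append((str(sid), rid))
        row = ann.loc[sid].copy()
        ann.loc[rid] = row

    values = pd.concat(
        [
            expr.values,
            pd.DataFrame(
                np.column_stack(new_cols), index=expr.probe_ids, columns=new_ids
            ),
        ],
        axis=1,
    )
    out = ExpressionSet(values=values, scale=expr.scale)
    truth = CohortTruth(replicate_pairs=pairs)
    new_ann = AnnotationTable(ann, dict(annotations.roles), subject=annotations.subject)
    return out, new_ann, truth


def simulate_cohort(
    config: CohortConfig,
) -> tuple[ExpressionSet, AnnotationTable, CohortTruth]:
    """Full generator: annotations, expression, replicates, detection."""
    annotations = generate_annotations(config)
    expr, truth = generate_expression(annotations, config)
    expr, annotations, rep_truth = spike_replicates(
        expr, annotations, config.n_replicate_pairs, config.seed
    )
    truth.replicate_pairs = rep_truth.replicate_pairs
    expr = simulate_detection(expr, config)
    return expr, annotations, truth
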