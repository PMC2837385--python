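import numpy as np
import pandas as pd
import pytest

from bloodvar.containers import AnnotationTable, ExpressionSet


def make_expr(values, snr=None, flags=None, scale="log2", probe_ids=None, sample_ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    G, n = values.shape
    probes = probe_ids or [f"P{i:04d}" for i in range(G)]
    samples = sample_ids or [f"S{i:03d}" for i in range(n)]

    def df(m):
        return None if m is None else pd.DataFrame(
            np.atleast_2d(np.asarray(m)), index=probes, columns=samples
        )

    return ExpressionSet(values=df(values), snr=df(snr), flags=df(flags), scale=scale)


def make_annotations(n=None, seed=0, subject=None, **columns):
    if columns:
        n = len(next(iter(columns.values())))
    data = pd.DataFrame(
        {k: np.asarray(v) for k, v in columns.items()},
        index=[f"S{i:03d}" for i in range(n)],
    )
    roles = {}
    for k in columns:
        if k in ("array_lot", "extraction_date"):
            roles[k] = "technical-random"
        elif k.startswith("tech") or k == "freeze_days":
            roles[k] = "technical-fixed"
        elif k in ("smoking", "HT", "MED"):
            roles[k] = "exposure"
        elif k != subject:
            roles[k] = "biological"
    return AnnotationTable(data, roles, subject=subject)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """Balanced toy cohort: 40 samples, 2 lots, binary smoking."""
    r = np.random.default_rng(7)
    n = 40
    ann = make_annotations(
        array_lot=np.repeat(["L0", "L1"], n // 2),
        smoking=r.binomial(1, 0.4, n),
        freeze_days=r.uniform(0, 3, n),
    )
    Y = r.normal(7.0, 0.5, size=(100, n))
    return make_expr(Y, sample_ids=list(ann.data.index)), ann
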