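"""Shared fixtures: small synthetic records and prepared datasets.

Everything is generated at test time from fixed seeds; session scope
keeps the expensive conditioning chains from re-running per test.
"""

from __future__ import annotations

import numpy as np
import pytest

from ecgfusion.evaluate import prepare_record
from ecgfusion.labels import ClassLabel
from ecgfusion.synth import SynthSpec, generate_record


@pytest.fixture(scope="session")
def base_spec() -> SynthSpec:
    return SynthSpec(seed=42)


@pytest.fixture(scope="session")
def normal_record(base_spec):
    """A clean 30-s normal-rhythm record with its ground truth."""
    rng = np.random.default_rng(42)
    return generate_record(base_spec, ClassLabel.N, rng, duration_s=30.0)


@pytest.fixture(scope="session")
def tiny_two_class_data():
    """20 conditioned records, two well-separated classes (N vs LBBB).

    Returns (segments, labels): lead-II stacks of shape (20, 10, 1500)
    and integer class indices.
    """
    spec = SynthSpec(seed=7)
    x, y = [], []
    for i in range(20):
        cls = ClassLabel.N if i % 2 == 0 else ClassLabel.LBBB
        rng = np.random.default_rng([7, i])
        rec, _ = generate_record(spec, cls, rng, duration_s=10.0)
        prep = prepare_record(rec)
        x.append(prep.segments[1])
        y.append(cls.index)
    return np.stack(x), np.array(y)


@pytest.fixture(scope="session")
def rr_random_series():
    """100 random RR series (ms) for oracle-equivalence checks."""
    rng = np.random.default_rng(123)
    out = []
    for _ in range(100):
        n = int(rng.integers(10, 40))
        out.append(rng.normal(850, 120, size=n).clip(350, 2000))
    return out
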