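import numpy as np
import pandas as pd
import pytest

from icftraj import items, simulate


def make_record(pid, day, values):
    return items.AssessmentRecord(pid, day, dict(zip(items.ITEM_CODES, values)))


@pytest.fixture
def toy_cohort():
    """Three hand-written patients with admission and endpoint assessments."""
    adm = [
        make_record("a", 0, [5, 0, 3] + [0] * 17),
        make_record("b", 0, [2, 4, 0] + [0] * 17),
        make_record("c", 0, [0, 1, 6] + [0] * 17),
    ]
    end = [
        make_record("a", 28, [3, 0, 3] + [0] * 17),
        make_record("b", 14, [2, 1, 0] + [0] * 17),
        make_record("c", 42, [0, 2, 1] + [0] * 17),
    ]
    return adm, end


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-patient synthetic cohort from the reference generative model."""
    cfg = simulate.default_stroke_config(n_patients=150, seed=11)
    return simulate.generate(cfg)


@pytest.fixture(scope="session")
def small_totals(small_cohort):
    return items.totals_frame(small_cohort.assessments)
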