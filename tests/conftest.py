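import warnings

import numpy as np
import pytest

from otogene.data import FREQUENCIES, Audiogram, PatientRecord
from otogene.simulate import default_panel, simulate


def make_audiogram(age=40.0, thresholds=None, pid="P1", aid="A1", gene=None, region=None):
    if thresholds is None:
        thresholds = {f: 30.0 for f in FREQUENCIES}
    elif isinstance(thresholds, (int, float)):
        thresholds = {f: float(thresholds) for f in FREQUENCIES}
    return Audiogram(pid, aid, age, thresholds, gene=gene, region=region)


def flat_record(pid="P1", gene="WFS1", age=40.0, level=30.0, n_audiograms=1):
    bag = [
        make_audiogram(age + i, level, pid=pid, aid=f"{pid}-{i}", gene=gene)
        for i in range(n_audiograms)
    ]
    return PatientRecord(pid, bag, gene=gene)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_cohort(panel):
    """150 synthetic patients, enough for every gene class to appear."""
    return simulate(panel, 150, seed=11)


@pytest.fixture(scope="session")
def two_gene_cohort():
    """Two well-separated synthetic genes, 50 noiseless-ish audiograms each.

    Constructed so a nearest-centroid rule is a 100%-accurate oracle.
    """
    rng = np.random.default_rng(5)
    records = []
    for gi, (gene, level) in enumerate([("WFS1", 20.0), ("KCNQ4", 90.0)]):
        for i in range(50):
            pid = f"{gene}-{i}"
            age = float(rng.uniform(20, 60))
            thr = {f: float(np.clip(level + rng.normal(0, 2), -10, 130)) for f in FREQUENCIES}
            records.append(PatientRecord(pid, [Audiogram(pid, f"{pid}-a", age, thr, gene=gene)], gene=gene))
    return records


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
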