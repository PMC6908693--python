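import numpy as np
import pandas as pd
import pytest

from oxynet import quant, synth


@pytest.fixture(scope="session")
def default_config():
    return synth.SynthConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(default_config):
    return synth.generate_dataset(default_config)


@pytest.fixture(scope="session")
def profile(dataset):
    return quant.build_profile(dataset.peaks, dataset.abundance.sum(axis=0))


@pytest.fixture()
def toy_peaks():
    """Two samples, full six-analyte panel, hand-sized areas."""
    panel = quant.default_panel()
    rows = []
    for sample, a_s, vol in [("S1", 5000.0, 2.0), ("S2", 1000.0, 0.5)]:
        for k, code in enumerate(panel.codes):
            rows.append((sample, code, 250.0 * (k + 1), a_s, vol))
    return pd.DataFrame(rows, columns=quant.PEAK_COLUMNS)


def spearman_rho(a, b):
    """Independent Spearman helper for oracles (rank then Pearson)."""
    ra = pd.Series(a).rank().to_numpy()
    rb = pd.Series(b).rank().to_numpy()
    za, zb = ra - ra.mean(), rb - rb.mean()
    return float(za @ zb / np.sqrt((za ** 2).sum() * (zb ** 2).sum()))
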