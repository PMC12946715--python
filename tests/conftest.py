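import numpy as np
import pytest

from lifespanfc.filterbank import AnalyticTensor


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_analytic(rng, n_parcels=4, n_freqs=3, n_epochs=1, n_samples=100,
                  edge_invalid=0, fs=250.0):
    """Random complex AnalyticTensor for metric-level tests."""
    values = rng.standard_normal((n_parcels, n_freqs, n_epochs, n_samples)) \
        + 1j * rng.standard_normal((n_parcels, n_freqs, n_epochs, n_samples))
    mask = np.ones((n_freqs, n_samples), dtype=bool)
    if edge_invalid:
        mask[:, :edge_invalid] = False
        mask[:, -edge_invalid:] = False
    freqs = np.linspace(5.0, 5.0 + n_freqs - 1, n_freqs)
    return AnalyticTensor(values=values, valid_mask=mask, fs=fs, freqs=freqs)
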