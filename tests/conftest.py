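import numpy as np
import pytest

from ornspike import synthdata
from ornspike.types import RecordingSet, SpikeTrain


def make_train(spikes, neuron="n0", trial=0, receptor="OR59b",
               odorant="methyl butyrate", concentration=-4.0):
    return SpikeTrain(
        neuron_id=neuron, trial=trial, receptor=receptor, odorant=odorant,
        concentration=concentration, spikes=np.asarray(spikes, dtype=float),
    )


@pytest.fixture
def tiny_recordings():
    """Two neurons x two trials, hand-written spikes (one condition)."""
    trains = [
        make_train([-50.0, 5.0, 7.0, 12.0], neuron="a", trial=0),
        make_train([-20.0, 5.5, 8.0], neuron="a", trial=1),
        make_train([6.0, 9.0], neuron="b", trial=0),
        make_train([-120.0, 6.5, 9.5, 30.0], neuron="b", trial=1),
    ]
    return RecordingSet(trains, baseline_window=(-200.0, 0.0),
                       response_window=(0.0, 100.0))


@pytest.fixture(scope="session")
def or59b_mid_conc():
    """Synthetic OR59b population at 10^-4: 8 neurons x 6 trials."""
    return synthdata.generate_population(
        "OR59b", "methyl butyrate", -4.0, n_neurons=8, n_trials=6,
        rng_seed=42, baseline=200.0, duration=120.0,
    )
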