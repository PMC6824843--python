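import numpy as np
import pytest

from bilat.core import Session, TrialRecord, canonical_load_set
from bilat.preprocess import ALIGNED_SPAN, RateSeries, build_context_matrices, epoch_means, smooth_spike_trains
from bilat.simulate import SimConfig, simulate_session
from bilat.tuning import load_sensitivity_anova


@pytest.fixture(scope="session")
def default_bundle():
    """One study-scale session (100 neurons) shared by the heavier tests."""
    session, truth = simulate_session(SimConfig(n_neurons=100, seed=42))
    rates = smooth_spike_trains(session)
    means = epoch_means(rates)
    C, I = build_context_matrices(rates)
    return {
        "session": session, "truth": truth, "rates": rates,
        "means": means, "C": C, "I": I,
    }


@pytest.fixture(scope="session")
def default_sensitivity(default_bundle):
    return load_sensitivity_anova(default_bundle["means"])


@pytest.fixture(scope="session")
def tiny_session():
    session, truth = simulate_session(
        SimConfig(n_neurons=8, n_trials_per_condition=2, seed=7)
    )
    return session, truth


def make_rate_series(traces, steady=None, n_trials=1):
    """RateSeries from per-(context, load) deterministic traces.

    ``traces[(ctx, load)]`` is (n_neurons, 500); every trial is a copy.
    """
    some = next(iter(traces.values()))
    n = some.shape[0]
    lo, hi = ALIGNED_SPAN
    perturb, stead, tids = {}, {}, {}
    for ctx in ("contra", "ipsi"):
        for load in range(8):
            tr = traces[(ctx, load)]
            perturb[(ctx, load)] = np.repeat(tr[:, None, :], n_trials, axis=1)
            s = steady[(ctx, load)] if steady else np.zeros((n, 1000))
            stead[(ctx, load)] = np.repeat(s[:, None, :], n_trials, axis=1)
            tids[(ctx, load)] = list(range(n_trials))
    return RateSeries(
        neuron_ids=list(range(n)), perturb=perturb, steady=stead, trial_ids=tids
    )


def make_session_skeleton(spikes_per_cell=None, perturb=600, end=1900):
    """Minimal valid Session: one trial per (context, load) cell."""
    trials, spikes = [], {}
    tid = 0
    cells = {}
    for ctx in ("contra", "ipsi"):
        for load in canonical_load_set():
            trials.append(
                TrialRecord(
                    trial_id=tid, context=ctx, load=load,
                    perturb_time_ms=perturb, trial_end_ms=end,
                )
            )
            cells[(ctx, load.index)] = tid
            tid += 1
    if spikes_per_cell:
        for nid, per_cell in spikes_per_cell.items():
            spikes[nid] = {
                cells[key]: np.asarray(times, dtype=np.int64)
                for key, times in per_cell.items()
            }
    return Session(trials=trials, spikes=spikes), cells
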