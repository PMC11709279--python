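import numpy as np
import pytest

from lamigain.data_model_io import TrialResponseTable
from lamigain.synthetic_data import make_ground_truth, simulate_probe


def make_small_table(
    n_sites=2,
    directions=(0.0, 60.0, 120.0, 180.0, 240.0, 300.0),
    n_reps=2,
    n_blank=1,
    seed=0,
    with_psth=False,
):
    """Hand-built minimal table for IO and screening tests."""
    rng = np.random.default_rng(seed)
    n_dir = len(directions)
    n_cond = n_dir + 1
    max_rep = max(n_reps, n_blank)
    rates = np.full((n_sites, n_cond, max_rep), np.nan)
    n_trials = np.array([n_reps] * n_dir + [n_blank])
    for c in range(n_cond):
        rates[:, c, : n_trials[c]] = rng.uniform(1.0, 30.0, (n_sites, n_trials[c]))
    psth = None
    time_ms = None
    if with_psth:
        time_ms = np.arange(-99.0, 300.0, 2.0)
        psth = np.full((n_sites, n_cond, max_rep, len(time_ms)), np.nan)
        for c in range(n_cond):
            psth[:, c, : n_trials[c]] = rng.uniform(
                0.0, 40.0, (n_sites, n_trials[c], len(time_ms))
            )
    return TrialResponseTable(
        probe_id="test-probe",
        site_ids=[f"s{i}" for i in range(n_sites)],
        relative_depth=np.linspace(0.1, 0.9, n_sites),
        area_label="A17",
        directions=np.array(directions, dtype=float),
        rates=rates,
        n_trials=n_trials,
        psth=psth,
        time_ms=time_ms,
    )


@pytest.fixture
def small_table():
    return make_small_table()


@pytest.fixture(scope="session")
def default_probe():
    """One default-condition synthetic probe with PSTHs."""
    truth = make_ground_truth({}, seed=11)
    return simulate_probe(truth, seed=12)


@pytest.fixture(scope="session")
def clean_probe():
    """Probe with input-trial noise but noise-free output coupling."""
    truth = make_ground_truth({"output_noise_scale": 0.0}, seed=21)
    return simulate_probe(truth, seed=22, with_psth=False)


def group_masks(layer_labels):
    kind = np.array(
        ["output" if l in ("L2/3", "L5") else "input" for l in layer_labels]
    )
    return kind == "input", kind == "output"
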