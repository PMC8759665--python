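"""Shared fixtures: settled attractors and protocol runs are expensive,
so they are computed once per session and reused across test modules."""

import numpy as np
import pytest

from pawshake.model import ModelParameters
from pawshake.simulate import settle_to_attractor, run_pulse_protocol
from pawshake.bursts import extract_transient_episode


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def slow_ref(params):
    return settle_to_attractor(params, regime="slow")


@pytest.fixture(scope="session")
def fast_ref(params):
    return settle_to_attractor(params, regime="fast")


@pytest.fixture(scope="session")
def reference_trajectory(slow_ref):
    """The canonical perturbation: 950 ms, 1 nS pulse at 20% phase."""
    return run_pulse_protocol(slow_ref, 20.0, 0.950, 1.0)


@pytest.fixture(scope="session")
def reference_episode(reference_trajectory):
    return extract_transient_episode(reference_trajectory)


@pytest.fixture(scope="session")
def coarse_window_grid(slow_ref):
    """Desk-scale sweep of the 20-40% phase window (1% x 20 ms steps)."""
    from pawshake.sweep import phase_duration_sweep

    phases = np.arange(20.0, 40.0 + 1e-9, 1.0)
    durations = np.round(np.arange(0.700, 1.000 + 1e-9, 0.020), 3)
    return phase_duration_sweep(slow_ref, phases, durations,
                                post_horizon=8.0)


@pytest.fixture(scope="session")
def reduced_grid_5x5():
    """Constant-hCaS model over a 5x5 grid spanning 0.0075-0.02."""
    from pawshake.reduced import constant_hcas_grid

    levels = np.round(np.linspace(0.0075, 0.02, 5), 5)
    return constant_hcas_grid(levels, run_time=100.0)


@pytest.fixture(scope="session")
def emg_cohort_stats():
    """Pipeline slope recovery over a 20-episode synthetic cohort with the
    recorded-data-like slope structure (BD growth on flexor-like
    channels, IBI growth on extensor-like ones)."""
    import warnings
    from pawshake.emg import analyze_episode, muscle_group_stats
    from pawshake.synth_emg import SyntheticEpisodeSpec, generate_cohort

    spec = SyntheticEpisodeSpec(envelope="rect", cp_slope=0.013)
    cohort = generate_cohort(20, spec, seed=7)
    tables = {}
    for _, rec, _ in cohort:
        for muscle, df in analyze_episode(rec).items():
            tables.setdefault(muscle, []).append(df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return muscle_group_stats(tables)
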