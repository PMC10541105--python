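import numpy as np
import pytest

from posmtd.config import TaskConfig
from posmtd.experiment import ExperimentConfig, run_experiment
from posmtd.state_spaces import (DwellKernelParams, ObservationAlphabet,
                                 StateSpace)


def make_toy_space(seed, n_states=3, n_symbols=3, n_dwell=3, *,
                   point_dwell=False, deterministic=False):
    """Random small semi-Markov space; symbol n_symbols-1 is the null."""
    rng = np.random.default_rng(seed)
    kp = DwellKernelParams(cv_d=0.3, d_b=1e-4, d_max=n_dwell * 0.1, dt=0.1)
    alphabet = ObservationAlphabet(
        tuple(f"o{i}" for i in range(n_symbols - 1)) + ("null",))
    if deterministic:
        T = np.roll(np.eye(n_states), 1, axis=1)
        O = np.zeros((n_states, n_symbols))
        for s in range(n_states):
            O[s, s % (n_symbols - 1)] = 1.0
    else:
        T = rng.dirichlet(np.ones(n_states), size=n_states)
        O = rng.dirichlet(np.ones(n_symbols), size=n_states)
    if point_dwell:
        D = np.zeros((n_states, n_dwell))
        D[:, 0] = 1.0
    else:
        D = rng.dirichlet(np.ones(n_dwell), size=n_states)
        D = kp.d_b + (1 - n_dwell * kp.d_b) * D
    return StateSpace(
        state_labels=tuple(f"s{i}" for i in range(n_states)),
        alphabet=alphabet, T=T, O=O, D=D, kernel=kp,
        level=tuple("lower" for _ in range(n_states)),
        model=1, initial_state="s0")


def sample_sequence(space, rng, length):
    """Draw an observation sequence from the generative model itself."""
    null = space.alphabet.null_index
    n_dwell = space.D.shape[1]
    obs = []
    s = space.initial_index
    dwell = 1 + rng.choice(n_dwell, p=space.D[s] / space.D[s].sum())
    entry = True
    while len(obs) < length:
        obs.append(int(rng.choice(len(space.alphabet), p=space.O[s]))
                   if entry else null)
        entry = False
        dwell -= 1
        if dwell == 0:
            s = int(rng.choice(space.n_states, p=space.T[s]))
            dwell = 1 + rng.choice(n_dwell, p=space.D[s] / space.D[s].sum())
            entry = True
    return obs


@pytest.fixture(scope="session")
def study_results():
    """The four full-scale study conditions (shared across test modules).

    20 runs x 30 sessions (10 burn-in) per condition, matching the averaging
    protocol of the headline comparisons.
    """
    out = {}
    for model in (1, 2):
        for lesion in (False, True):
            cfg = ExperimentConfig(model=model, lesion=lesion, seed=1)
            out[(model, lesion)] = run_experiment(cfg)
    return out


@pytest.fixture(scope="session")
def task_config():
    return TaskConfig()
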