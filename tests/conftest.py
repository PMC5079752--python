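import numpy as np
import pytest

from plrkit import synthetic_data as sd


@pytest.fixture(scope="session")
def library():
    return sd.default_genotype_library()


@pytest.fixture(scope="session")
def wt_spec(library):
    return library["wildtype"]


@pytest.fixture(scope="session")
def wt_omega(wt_spec):
    from plrkit import feedback_model as fb

    pulse = sd.generate_pulse_chase(wt_spec, seed=0, noise_sd=0.0)
    return fb.omega_from_pulse_chase(pulse)


def brute_force_feedback(drc, weights, env_lux, horizon):
    """Independent nested-loop reference for the negative-feedback recursion.

    Pure-python, dict-based, literal transcription of the per-second rule:
    each packet s carries depth_s = 1 - drc(lux_s); at time t the retinal
    intensity is reduced by the single deepest weighted previous packet,
    and the reported pupil size is set by the deepest weighted packet
    including the current one.
    """
    weights = list(weights)
    depth, lux, rpa = {}, {}, []
    for t in range(1, horizon + 1):
        constriction = 0.0
        for s in range(1, t):
            lag = t - s
            if lag < len(weights):
                constriction = max(constriction, depth[s] * weights[lag])
        lux[t] = (1.0 - constriction) * env_lux
        depth[t] = 1.0 - drc(lux[t])
        deepest = 0.0
        for s in range(1, t + 1):
            lag = t - s
            if lag < len(weights):
                deepest = max(deepest, depth[s] * weights[lag])
        rpa.append(1.0 - deepest)
    return np.array(rpa), np.array([lux[t] for t in range(1, horizon + 1)])


@pytest.fixture(scope="session")
def feedback_oracle():
    return brute_force_feedback
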