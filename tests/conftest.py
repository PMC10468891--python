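import numpy as np
import pytest

import triagecea as t
from triagecea.psa import BaseCase


@pytest.fixture(scope="session")
def cfg():
    return t.load_default_config()


@pytest.fixture(scope="session")
def base_case(cfg):
    return BaseCase.from_config(cfg)


@pytest.fixture(scope="session")
def pre_params(cfg):
    return cfg.pre.phase_params(cfg.missed_days)


@pytest.fixture(scope="session")
def post_params(cfg):
    return cfg.post.phase_params(cfg.missed_days)


@pytest.fixture(scope="session")
def small_cohort(pre_params):
    from dataclasses import replace

    from triagecea.synthetic_trial import generate_phase

    return generate_phase(replace(pre_params, n_patients=400), seed=7, phase="pre")


@pytest.fixture(scope="session")
def arm_results(cfg, base_case):
    pre_inputs, post_inputs = base_case.deterministic_arm_inputs()
    out = {}
    for arm, inputs in (("pre", pre_inputs), ("post", post_inputs)):
        out[arm] = t.evaluate_arm(
            inputs,
            cfg.schedule,
            cfg.econ,
            arm,
            pre_inputs=pre_inputs,
            program_cost_child=base_case.program_cost_child,
        )
    return out
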