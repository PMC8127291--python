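import copy
import dataclasses

import pytest
from hypothesis import settings

import sarcocea as sc

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def base_params() -> sc.ParameterSet:
    """Canonical base-case parameter set (constant-mortality default)."""
    return sc.load_default_parameters()


@pytest.fixture(scope="session")
def vec_params(base_params) -> sc.ParameterSet:
    """Base case with the age-indexed life-table mortality vector enabled."""
    return base_params.with_mortality_mode("vector")


def _pin(params: sc.ParameterSet, **overrides) -> sc.ParameterSet:
    """Copy of ``params`` with values pinned to exact constants.

    Registry names are set as ``family=fixed`` point values (so extreme
    probabilities like 0 or 1 are allowed); run-level fields are set directly.
    """
    run_keys = {
        "horizon_cycles", "cohort_size", "wtp",
        "default_sd_fraction", "stage2_charge_multiplier",
    }
    out = copy.copy(params)
    out.params = dict(params.params)
    for key, val in overrides.items():
        if key in run_keys:
            setattr(out, key, val)
        else:
            out.params[key] = dataclasses.replace(
                out.params[key],
                base=float(val), family="fixed",
                sd=None, ci_low=None, ci_high=None, sd_defaulted=False,
            )
    out.__post_init__()
    return out


@pytest.fixture(scope="session")
def pin():
    """Callable fixture: pin(params, name=value, ...) -> modified copy."""
    return _pin
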