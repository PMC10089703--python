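import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from comoyld import Stratum, SynthSpec, generate_registry

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def stratum() -> Stratum:
    return Stratum("male", "40-49", 2015)


@pytest.fixture
def tiny_registry_dir(tmp_path):
    """A small but complete synthetic registry written as the four CSVs."""
    spec = SynthSpec(causes_per_group=1, sequelae_per_cause=1, seed=11)
    out = tmp_path / "registry"
    generate_registry(spec, out)
    return out


def random_slice(rng: np.random.Generator, k: int):
    """A random stratum slice of k sequelae with p, dw drawn uniformly."""
    p = rng.random(k)
    dw = rng.random(k)
    return [(f"s{i:02d}", float(p[i]), float(dw[i])) for i in range(k)]
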