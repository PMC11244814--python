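import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240701)


@pytest.fixture
def small_cohort():
    """A tiny hand-built two-nucleus cohort used across modules."""
    from cocount.model import Cohort, FocusTrack, Nucleus

    def nucleus(nid, specs):
        tracks = tuple(
            FocusTrack(nid, "wt", rank, length, focus_positions=foci)
            for rank, length, foci in specs
        )
        return Nucleus(nid, "wt", tracks)

    return Cohort(
        genotype="wt",
        nuclei=(
            nucleus("n1", [(1, 10.0, (2.0, 7.5)), (2, 8.0, (4.0,))]),
            nucleus("n2", [(1, 10.0, (1.0, 5.0, 9.0)), (2, 8.0, ())]),
        ),
    )
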