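import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_track(values, total_tags=None, sample_id="t", replicate=1, assay="netseq_ip"):
    """Build a StrandedTrack from {chrom: {strand: list}} with dense arrays."""
    from antisense_scope.io_formats import StrandedTrack

    dense = {
        c: {s: np.asarray(v, dtype=float) for s, v in per.items()}
        for c, per in values.items()
    }
    if total_tags is None:
        total_tags = sum(a.sum() for per in dense.values() for a in per.values())
        total_tags = max(total_tags, 1.0)
    return StrandedTrack(
        sample_id=sample_id, replicate=replicate, assay=assay, values=dense,
        total_tags=total_tags,
    )
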