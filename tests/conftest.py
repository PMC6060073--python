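import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def records_key(records):
    """Canonical representation of a detection list for set comparison."""
    return sorted(
        (r.label, tuple(sorted(r.pixels)), r.centroid, r.total_intensity,
         r.row_span, r.finalized_at_row)
        for r in records)
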