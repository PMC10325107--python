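import numpy as np
import pytest

from birdcrop import (
    ComparisonRecord,
    EffectSize,
    MetaDataset,
)


@pytest.fixture
def simple_record():
    return ComparisonRecord(
        study_id="s1", comparison_id="c1",
        mean_treatment=10.0, mean_control=5.0,
        sd_treatment=2.0, sd_control=2.0,
        n_treatment=10, n_control=10,
    )


def make_effects(g, v, one_per_study=True):
    """Effect list from plain arrays; study structure optional."""
    out = []
    for i, (gi, vi) in enumerate(zip(g, v)):
        sid = f"s{i}" if one_per_study else f"s{i // 2}"
        out.append(
            EffectSize(g=float(gi), v_g=float(vi), study_id=sid, comparison_id=f"c{i}")
        )
    return out


@pytest.fixture
def handmade_k5():
    """Five effects with easy numbers for hand-checked statistics."""
    g = [0.1, 0.3, 0.5, 0.7, 0.2]
    v = [0.04, 0.09, 0.16, 0.25, 0.01]
    return MetaDataset(make_effects(g, v))


@pytest.fixture
def rng():
    return np.random.default_rng(20230706)
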