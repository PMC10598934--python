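import numpy as np
import pandas as pd
import pytest

from icefalcon.config import TransformSpec
from icefalcon.preprocess import build_risk_scores
from icefalcon.presets import calibrated_config
from icefalcon.simulate import simulate_pairs

# fixed once for the whole suite (derandomization, not tuning)
SUITE_SEED = 20260923


@pytest.fixture(scope="session")
def printed_transforms():
    """The published power transforms of the four raw measures."""
    return {
        "light": TransformSpec("light", lam=1 / 3),
        "bright": TransformSpec("bright", lam=1 / 3),
        "brightest": TransformSpec("brightest", lam=1 / 5),
        "cirrus": TransformSpec("cirrus", lam=2.0, shift=-2907.0),
    }


@pytest.fixture(scope="session")
def study_raw():
    """One study-sized draw (371 pairs) from the calibrated four-trait model."""
    return simulate_pairs(calibrated_config(n_pairs=371, seed=SUITE_SEED))


@pytest.fixture(scope="session")
def study_scores(study_raw, printed_transforms):
    return build_risk_scores(study_raw, printed_transforms)


@pytest.fixture()
def rng():
    return np.random.default_rng(SUITE_SEED)


def toy_scores(values_by_trait: dict[str, list[tuple[float, float]]]) -> pd.DataFrame:
    """Build a tiny score frame from per-trait lists of (twin1, twin2) values."""
    traits = list(values_by_trait)
    n = len(values_by_trait[traits[0]])
    rows = []
    for i in range(n):
        for t_idx in (1, 2):
            row = {"pair_id": f"P{i}", "twin_index": t_idx, "age": 50.0}
            for trait, pairs in values_by_trait.items():
                row[trait] = pairs[i][t_idx - 1]
            rows.append(row)
    return pd.DataFrame(rows)
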