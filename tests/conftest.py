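import numpy as np
import pandas as pd
import pytest

import speceffect as se


@pytest.fixture(scope="session")
def small_refset() -> pd.DataFrame:
    return se.generate_reference_db(n_per_category=3, seed=1)


@pytest.fixture(scope="session")
def large_refset() -> pd.DataFrame:
    """110 reference compounds, enough to draw a 108-component peak table."""
    return se.generate_reference_db(n_per_category=11, seed=2)


@pytest.fixture(scope="session")
def peak_table(large_refset) -> se.PeakTable:
    """Standard 18-group, 3-replicate table of 108 components."""
    return se.generate_peak_table(se.default_conditions(), large_refset,
                                  n_replicates=3, seed=3, n_components=108)


@pytest.fixture(scope="session")
def anthraquinone_refset() -> pd.DataFrame:
    """Hand-built two-compound reference set: an anthraquinone aglycone and
    an unrelated flavanol, for cascade unit tests."""
    return pd.DataFrame({
        "name": ["aloe-emodin", "catechin"],
        "formula": ["C15H10O5", "C15H14O6"],
        "monoisotopic_mass": [270.052823, 290.079038],
        "category": ["Rh-01", "Rh-04"],
        "signature_losses": ["", ""],
        "is_confirmed_reference": [True, True],
        "aglycone_name": ["", ""],
    })


@pytest.fixture(scope="session")
def linear_training_data():
    """Noiseless linear quantity-effect data: 200 samples x 10 components."""
    rng = np.random.default_rng(1)
    X = rng.uniform(0.0, 1.0, (200, 10))
    y = 0.3 * X[:, 0] + 0.2 * X[:, 1]
    return X, y
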