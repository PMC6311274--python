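import numpy as np
import pandas as pd
import pytest

import mhmmseg as m
from mhmmseg.mhmm import TrainConfig, train_mhmm


@pytest.fixture(scope="session")
def straight_phantom():
    """Noise-free straight tube, radius 2 mm, distinct wall tissue."""
    return m.generate_phantom(m.PhantomConfig(radius_profile_mm=2.0, seed=0))


@pytest.fixture(scope="session")
def feature_volumes(straight_phantom):
    return m.multiscale_features(straight_phantom.volume)


def _training_table(noise=40.0, radii=(1.2, 1.8, 2.4), wall_mode="stripped"):
    tables = []
    for i, r in enumerate(radii):
        # the widest vessel carries a calcified arc so every tissue state
        # (including pathology) appears in the training series
        plaques = [m.PlaqueArc((0.2, 0.8), (0.0, 150.0), 1.2)] if i == 2 else []
        ph = m.generate_phantom(m.PhantomConfig(
            radius_profile_mm=r, noise_variance=noise, seed=100 + i,
            wall_mode=wall_mode, plaque_spec=plaques,
        ))
        feats = m.multiscale_features(ph.volume)
        tables.append(m.build_series_table(
            ph.volume, ph.axes[0], feats, labels=ph.labels,
            wall_thickness_vox=2, on_bounds_error="skip", phantom_id=i,
        ))
    table = pd.concat(tables, ignore_index=True)
    table.attrs["n_samples"] = 18
    return table


@pytest.fixture(scope="session")
def small_series_table():
    """Labeled ray series from three bright-tube phantoms at noise 40."""
    return _training_table()


@pytest.fixture(scope="session")
def trained_model(small_series_table):
    """A supervised-count MHMM trained on the small series table."""
    model, _ = train_mhmm(
        small_series_table, TrainConfig(max_iter=0, scheme_mode="fitted")
    )
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
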