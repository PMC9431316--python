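import numpy as np
import pytest

from mdquant.geometry import prepare_rois
from mdquant.quant import QuantConfig, quantify_field
from mdquant.simulate import FieldParams


@pytest.fixture(scope="session")
def matched_cfg():
    """Analysis config matched to the generator defaults (band = ring
    width, known constant background)."""
    return QuantConfig(band_width_um=0.5, background=20.0)


@pytest.fixture(scope="session")
def small_params():
    return FieldParams(n_cells=4, image_shape=(224, 224), seed=11)


def quantify_with_truth(params, cfg=None, **gen_kwargs):
    """Generate a field, run the full quantification, and join ground truth.

    Returns (metrics DataFrame, {label: CellTruth}).
    """
    from mdquant.simulate import generate_field

    field, mask, truth = generate_field(params, **gen_kwargs)
    rois, _ = prepare_rois(mask, field)
    cfg = cfg or QuantConfig(band_width_um=0.5, background=params.background)
    df = quantify_field(field, rois, cfg)
    return df, {c.label: c for c in truth.cells}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
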