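import numpy as np
import pytest

from endoflow import hemodynamics as hemo
from endoflow import segment, synthgen


@pytest.fixture(scope="session")
def chip_geometry() -> hemo.ChannelGeometry:
    """The 1 mm x 100 um x 17 mm chip channel."""
    return hemo.ChannelGeometry.from_full_dimensions(1.0e-3, 100e-6, 17e-3)


@pytest.fixture(scope="session")
def pinned_fluid() -> hemo.Fluid:
    """Culture medium with viscosity pinned at 1.0e-3 Pa s.

    The condition-table fixtures are internally consistent only under
    this viscosity; the library default (0.00072 Pa s) yields values
    ~28% lower.
    """
    return hemo.Fluid(density=1000.0, dynamic_viscosity=1.0e-3)


def flow_ul_min(q: float) -> float:
    return q * 1e-9 / 60.0


@pytest.fixture(scope="session")
def clean_field():
    """Noise-free default-phenotype field with its segmentation."""
    spec = synthgen.SyntheticSpec(shape=(512, 512), n_cells=40, rng_seed=3)
    stack, truth = synthgen.generate_monolayer(spec)
    maps = segment.segment_stack(stack)
    return spec, stack, truth, maps


@pytest.fixture(scope="session")
def noisy_field():
    """Same field with Poisson + Gaussian noise at SNR >= 5."""
    spec = synthgen.SyntheticSpec(
        shape=(512, 512), n_cells=40, rng_seed=3,
        gaussian_noise_sd=20.0, poisson_noise=True,
    )
    stack, truth = synthgen.generate_monolayer(spec)
    maps = segment.segment_stack(stack)
    return spec, stack, truth, maps


@pytest.fixture(scope="session")
def fingers_field():
    """Noise-free field with finger-like protrusions."""
    spec = synthgen.SyntheticSpec(
        shape=(512, 512), n_cells=40, rng_seed=5,
        phenotype="fingers", band_width=5, finger_density=0.015,
    )
    stack, truth = synthgen.generate_monolayer(spec)
    maps = segment.segment_stack(stack)
    return spec, stack, truth, maps


def match_cells(truth, secondary):
    """Map each interior ground-truth cell to its best-overlap pipeline label."""
    tl = truth.cell_labels
    out = {}
    for cid in truth.cells[truth.cells.interior].index:
        vals, cnts = np.unique(secondary[tl == cid], return_counts=True)
        vals, cnts = vals[vals > 0], cnts[vals > 0]
        if len(vals):
            out[cid] = int(vals[np.argmax(cnts)])
    return out
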