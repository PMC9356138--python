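import numpy as np
import pytest

import srscell as sc
from srscell.synthetic import (
    dual_probe_components,
    make_component_spectrum,
)


@pytest.fixture(scope="session")
def ch_phantom_clean():
    """Noise-free C-H window phantom: 8 cells, nuclei/cytoplasm/droplets."""
    spec = sc.PhantomSpec(image_shape=(192, 192), n_cells=8, noise=(0.0, 0.0), seed=7)
    stack, truth = sc.generate_cell_phantom(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def dual_probe_phantom():
    """Dual-probe phantom: droplets carry C#C and C-D at 0.3 / 0.7, mild noise."""
    cc, cd = dual_probe_components()
    spec = sc.PhantomSpec(
        image_shape=(192, 192),
        n_cells=10,
        wavenumber_range=(2050.0, 2350.0),
        components=(cc, cd),
        component_abundances={
            "nucleus": {},
            "cytoplasm": {},
            "droplet": {"CC_odya": 0.3, "CD_glucose": 0.7},
        },
        class_droplet_scale=(1.0, 1.0),
        noise=(0.05, 0.02),
        seed=5,
    )
    stack, truth = sc.generate_cell_phantom(spec)
    refs = {
        "CC": make_component_spectrum(cc, spec.wavenumbers),
        "CD": make_component_spectrum(cd, spec.wavenumbers),
    }
    return spec, stack, truth, refs
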