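import numpy as np
import pytest

from octapcd.segmentation import VesselMaskSet
from octapcd.synthetic import AngiogramSpec, generate_angiogram


@pytest.fixture(scope="session")
def default_angiogram():
    """One representative synthetic angiogram with moderate noise."""
    spec = AngiogramSpec(capillary_fraction_target=0.35, noise_sd=0.05, seed=11)
    return generate_angiogram(spec)


@pytest.fixture(scope="session")
def noiseless_angiogram():
    spec = AngiogramSpec(capillary_fraction_target=0.30, noise_sd=0.0, seed=23)
    return generate_angiogram(spec)


def maskset_from(perfusion: np.ndarray, scale_um_per_px: float = 1.0) -> VesselMaskSet:
    """Wrap a raw boolean perfusion mask as a VesselMaskSet (no large vessels yet)."""
    perfusion = np.asarray(perfusion, dtype=bool)
    return VesselMaskSet(
        perfusion_mask=perfusion,
        large_vessel_mask=np.zeros_like(perfusion),
        capillary_mask=perfusion.copy(),
        threshold_value=0.5,
        scale_um_per_px=scale_um_per_px,
    )
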