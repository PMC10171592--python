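import numpy as np
import pytest

from orbitseg.phantom import PhantomSpec, render_slice
from orbitseg.pipeline import SliceSample
from orbitseg.preprocess import apply_window


@pytest.fixture(scope="session")
def spec64() -> PhantomSpec:
    """Small phantom spec (64 px) used to keep CPU runtime low."""
    return PhantomSpec(image_size=64)


@pytest.fixture(scope="session")
def axial1_samples(spec64) -> list[SliceSample]:
    """Eight deterministic eye-level slices with all four axial-1 masks."""
    samples = []
    for i in range(8):
        ct, masks = render_slice(spec64, "axial1", seed=100 + i)
        samples.append(SliceSample(id=f"ax{i:02d}", plane="axial1",
                                   image=ct.pixels,
                                   masks={t: masks[t] for t in masks.tissues()}))
    return samples


@pytest.fixture(scope="session")
def eyeball_pairs(axial1_samples):
    return [(apply_window(s.image), s.masks["eyeball"].astype(np.float32))
            for s in axial1_samples]
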