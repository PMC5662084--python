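"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ctc_markerquant import BlobSpec, EventSpec, FluorescentFrame

BACKGROUND_SIGMA = 6.6   # reference background noise level
BACKGROUND_MU = 30.0


def make_frame(
    pixels: np.ndarray,
    channel: str = "MARKER1",
    rescaled: bool = True,
    header: tuple[float, float] = (0.0, 4095.0),
) -> FluorescentFrame:
    """Wrap a raw pixel array in a frame on the restored 12-bit scale."""
    return FluorescentFrame(
        channel_name=channel,
        pixels=np.asarray(pixels, dtype=np.float64),
        stored_bit_depth=8,
        header_min=header[0],
        header_max=header[1],
        is_rescaled=rescaled,
    )


def noise_frame(
    shape=(100, 100),
    mu: float = BACKGROUND_MU,
    sigma: float = BACKGROUND_SIGMA,
    seed: int = 0,
    channel: str = "MARKER1",
) -> FluorescentFrame:
    rng = np.random.default_rng(seed)
    px = np.clip(rng.normal(mu, sigma, size=shape), 0.0, 4095.0)
    return make_frame(px, channel=channel)


def disk_mask(shape: tuple[int, int], center: tuple[float, float],
              radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    return np.hypot(yy - center[0], xx - center[1]) <= radius


def marker_blob_spec(
    plateau: float,
    radius: float = 6.0,
    center: tuple[float, float] = (40.0, 40.0),
    seed: int = 0,
    **kwargs,
) -> EventSpec:
    """One marker-channel blob on default noise; other channels pure noise."""
    blobs = {}
    if plateau > 0:
        blobs["MARKER1"] = (BlobSpec(center=center, radius_px=radius,
                                     plateau=plateau),)
    return EventSpec(blobs=blobs, seed=seed, **kwargs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
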