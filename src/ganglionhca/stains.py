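"""Beer–Lambert H&E stain model: composition and optical-density unmixing.

The synthetic renderer composes RGB transmission images from per-pixel
hematoxylin/eosin concentration maps against the fixed stain matrix in
:mod:`ganglionhca.config`; :func:`separate_stains` inverts that model by
least squares, so on noise-free synthetic slides the round trip is exact up
to 8-bit quantization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import STAIN_OD_MATRIX, STAIN_RESIDUAL_VECTOR

_EPS_TRANSMISSION = 1.0 / 255.0


@dataclass
class StainChannels:
    """Per-pixel stain concentrations recovered from an RGB image.

    ``hematoxylin`` and ``eosin`` are nonnegative concentration grids in
    optical-density units; ``residual`` is the signed projection of the
    pixel OD vector on the direction orthogonal to both stains (zero for a
    perfect two-stain image).
    """

    hematoxylin: np.ndarray
    eosin: np.ndarray
    residual: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.hematoxylin.shape


# 8-bit -> OD lookup table; keeps whole-slide conversion cheap
_OD_LUT = (-np.log(np.clip(np.arange(256) / 255.0,
                           _EPS_TRANSMISSION, 1.0))).astype(np.float32)


def rgb_to_od(image: np.ndarray) -> np.ndarray:
    """Convert an RGB image to optical density, shape (H, W, 3)."""
    image = np.asarray(image)
    if image.dtype == np.uint8:
        return _OD_LUT[image]
    transmission = np.clip(image.astype(np.float32) / 255.0,
                           _EPS_TRANSMISSION, 1.0)
    return -np.log(transmission)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Convert optical density back to an 8-bit RGB image."""
    rgb = 255.0 * np.exp(-od)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def compose_rgb(hematoxylin: np.ndarray, eosin: np.ndarray) -> np.ndarray:
    """Render concentrations to 8-bit RGB through the fixed stain matrix."""
    od = (hematoxylin[..., None] * STAIN_OD_MATRIX[0]
          + eosin[..., None] * STAIN_OD_MATRIX[1])
    return od_to_rgb(od)


def separate_stains(image: np.ndarray) -> StainChannels:
    """Unmix an RGB image into hematoxylin/eosin concentrations.

    Parameters
    ----------
    image
        8-bit RGB array of shape (H, W, 3).

    Raises
    ------
    ValueError
        If the image is entirely black: the log transform of zero
        transmission is undefined, so a saturated image carries no stain
        information.
    """
    image = np.asarray(getattr(image, "pixels", image))
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB (H, W, 3) image, got {image.shape}")
    if not image.any():
        raise ValueError(
            "image is entirely black; optical density is undefined"
        )
    od = rgb_to_od(image)
    # Least-squares unmixing: pinv is 3x2, rows of STAIN_OD_MATRIX are unit.
    pinv = np.linalg.pinv(STAIN_OD_MATRIX).astype(od.dtype)
    conc = od @ pinv
    residual = od @ STAIN_RESIDUAL_VECTOR.astype(od.dtype)
    return StainChannels(
        hematoxylin=np.ascontiguousarray(conc[..., 0]),
        eosin=np.ascontiguousarray(conc[..., 1]),
        residual=np.ascontiguousarray(residual),
    )


def reconstruction_rmse(image: np.ndarray, channels: StainChannels) -> float:
    """Per-pixel RMSE (OD units) of the two-stain reconstruction."""
    od = rgb_to_od(image)
    od_hat = (channels.hematoxylin[..., None] * STAIN_OD_MATRIX[0]
              + channels.eosin[..., None] * STAIN_OD_MATRIX[1])
    return float(np.sqrt(np.mean((od - od_hat) ** 2)))
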