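"""Denoising and binarization of fluorescence stacks.

The processing chain applied to every fluorescence stack before
segmentation: a normalized 3D Gaussian filter (variance 0.8 in pixel
units, isotropic in index space) followed by thresholding.  High staining
contrast makes any histogram-valley threshold adequate; Otsu's method is
the deterministic default, and a fixed threshold can be supplied instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .stacks_io import ImageStack


def gaussian3d(stack: ImageStack, variance: float = 0.8) -> ImageStack:
    """Smooth a stack with a normalized isotropic 3D Gaussian.

    ``variance`` is in squared pixels (sigma = sqrt(variance) in index
    space).  Reflect padding keeps the DC gain exactly 1 on constants.
    Output values are float64.
    """
    if not variance > 0:
        raise ValueError("variance must be strictly positive")
    sigma = math.sqrt(variance)
    smoothed = ndimage.gaussian_filter(np.asarray(stack.values, dtype=np.float64),
                                       sigma=sigma, mode="reflect")
    return stack.with_values(smoothed)


@dataclass
class Binarization:
    """Result of thresholding one stack."""

    stack: ImageStack          # boolean foreground mask, same shape/geometry
    threshold: float
    method: str
    degenerate: bool = False   # constant-valued input, auto threshold impossible


def binarize(stack: ImageStack, method: str | float = "otsu") -> Binarization:
    """Threshold a grayscale stack into a boolean foreground mask.

    ``method`` is either ``"otsu"`` (per-stack automatic threshold;
    foreground strictly above the threshold) or a fixed numeric threshold
    (foreground at or above it).  A constant-valued stack under the auto
    method is flagged degenerate and returned all-background.
    """
    values = np.asarray(stack.values)
    if isinstance(method, str):
        if method != "otsu":
            raise ValueError(f"unknown binarization method {method!r}")
        vmin, vmax = values.min(), values.max()
        if vmin == vmax:
            mask = np.zeros(values.shape, dtype=bool)
            return Binarization(stack.with_values(mask), float(vmin), "otsu",
                                degenerate=True)
        thr = float(threshold_otsu(values))
        mask = values > thr
    else:
        thr = float(method)
        mask = values >= thr
    return Binarization(stack.with_values(mask), thr,
                        "otsu" if isinstance(method, str) else "fixed")
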