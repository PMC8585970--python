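"""Two-channel 3-D image stacks (ZCYX) and their TIFF round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

from ._exceptions import StackFormatError

CHANNELS = ("red", "green")


@dataclass
class ImageStack:
    """A two-channel confocal z-stack.

    ``voxels`` is indexed (z, channel, y, x); channel order follows
    ``channels`` (red first by convention).  ``bit_depth`` is 8 or 16.
    """

    voxels: np.ndarray
    channels: tuple[str, str] = CHANNELS
    bit_depth: int = 16

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 4:
            raise StackFormatError(f"expected 4-D ZCYX voxels, got ndim={v.ndim}")
        if v.shape[1] != 2 or len(self.channels) != 2:
            raise StackFormatError("expected exactly 2 channels")
        if self.bit_depth not in (8, 16):
            raise StackFormatError("bit_depth must be 8 or 16")
        if v.min() < 0 or v.max() > 2**self.bit_depth - 1:
            raise StackFormatError(
                f"intensities must lie in [0, {2**self.bit_depth - 1}]"
            )
        self.voxels = v

    @property
    def shape(self) -> tuple[int, int, int]:
        z, _, y, x = self.voxels.shape
        return (z, y, x)

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise StackFormatError(f"unknown channel {name!r}") from None
        return self.voxels[:, idx]

    def channel_sum(self) -> np.ndarray:
        """Per-voxel sum over channels (used for segmentation)."""
        return self.voxels.sum(axis=1, dtype=np.float64)

    def swapped(self) -> "ImageStack":
        """Stack with channel order reversed (for symmetry checks)."""
        return ImageStack(
            self.voxels[:, ::-1].copy(),
            (self.channels[1], self.channels[0]),
            self.bit_depth,
        )


def save_tiff(stack: ImageStack, path) -> None:
    dtype = np.uint8 if stack.bit_depth == 8 else np.uint16
    tifffile.imwrite(path, stack.voxels.astype(dtype), metadata={"axes": "ZCYX"})


def load_tiff(path, channels: tuple[str, str] = CHANNELS) -> ImageStack:
    arr = tifffile.imread(path)
    if arr.ndim != 4 or arr.shape[1] != 2:
        raise StackFormatError(
            f"expected ZCYX TIFF with 2 channels, got shape {arr.shape}"
        )
    bit_depth = 8 if arr.dtype == np.uint8 else 16
    return ImageStack(arr, channels, bit_depth)
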