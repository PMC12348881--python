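"""Multi-channel 3D image stacks and their TIFF round-trip.

A stack is a set of named single-channel voxel volumes on one (z, y, x)
grid — the in-memory form of a multi-channel confocal z-stack. Volumes are
stored channel-major; the channel order is part of the object and is
persisted in a JSON sidecar next to the TIFF so that round-trips are exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack3D", "read_stack", "write_stack"]


@dataclass
class ImageStack3D:
    """Named-channel voxel volumes with a uniform (z, y, x) shape."""

    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {name: np.asarray(vol).shape for name, vol in self.channels.items()}
        for name, shape in shapes.items():
            if len(shape) != 3:
                raise ValueError(f"channel {name!r} is not 3D (shape {shape})")
        if len({s for s in shapes.values()}) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int, int]:
        if not self.channels:
            return (0, 0, 0)
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"unknown channel {name!r}; available: {self.channel_names}"
            ) from None


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_stack(stack: ImageStack3D, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF plus a JSON sidecar.

    Pages are written channel-major (all z of channel 0, then channel 1, ...);
    the sidecar records channel order, shape and dtype.
    """
    path = Path(path)
    names = stack.channel_names
    data = np.stack([stack.channels[n] for n in names], axis=0)
    tifffile.imwrite(path, data)
    meta = {
        "channels": names,
        "shape": list(stack.shape),
        "dtype": str(data.dtype),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_stack(path: str | Path, channel_names: list[str] | None = None) -> ImageStack3D:
    """Read a multi-page TIFF written by :func:`write_stack`.

    Without a sidecar, ``channel_names`` must be given and the page count must
    factor as ``len(channel_names) * n_z``.
    """
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = _sidecar_path(path)
    if channel_names is None:
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no channel sidecar {sidecar}; pass channel_names explicitly"
            )
        channel_names = json.loads(sidecar.read_text())["channels"]
    if data.ndim == 3:
        # single channel written without the channel axis
        data = data[None]
    if data.ndim != 4 or data.shape[0] != len(channel_names):
        # channel-major pages flattened into the first axis
        n_c = len(channel_names)
        if data.ndim == 3 or data.shape[0] % n_c:
            raise ValueError(
                f"cannot split {data.shape} into {n_c} channels"
            )
        data = data.reshape(n_c, -1, *data.shape[-2:])
    return ImageStack3D({n: data[i] for i, n in enumerate(channel_names)})
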