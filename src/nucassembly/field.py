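"""In-memory container for a registered multi-channel 2D fluorescence field."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np


@dataclass
class ImageField:
    """A set of co-registered single-plane channels.

    Channels are stored by name; all share one 2D shape and (by convention,
    not enforcement) one integer dtype matching the acquisition bit depth.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageField needs at least one channel")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels differ in shape: {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValueError(
                    f"channel {name!r} is {arr.ndim}D; only single 2D planes are "
                    "supported (max-project stacks upstream)"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"unknown channel {name!r}; available: {self.channel_names}"
            ) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self.channels)

    @classmethod
    def from_arrays(cls, arrays: Mapping[str, np.ndarray], **kw) -> "ImageField":
        return cls(channels=dict(arrays), **kw)
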