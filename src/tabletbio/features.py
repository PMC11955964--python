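"""Shared container for one named biometric feature sampled over a challenge."""

from __future__ import annotations

import dataclasses

import numpy as np


@dataclasses.dataclass
class FeatureSeries:
    """A named feature observed at irregular times within one challenge.

    ``t`` is seconds from challenge start; NaN values mark observations
    that exist in time but carry no level (treated as missing by the
    binning stage).
    """

    name: str
    t: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.shape != self.values.shape:
            raise ValueError(f"{self.name}: t and values must have equal length")

    def __len__(self) -> int:
        return len(self.t)
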