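"""Potential recordings: nodes x time matrices with sampling metadata."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PotentialRecording"]


@dataclass
class PotentialRecording:
    """A nodes x samples potential matrix in mV.

    Column ``k`` is sample ``k`` (0-based) at ``t = k / fs * 1000`` ms.
    """

    data: np.ndarray
    fs: float = 1000.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite values")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in milliseconds."""
        return np.arange(self.n_samples) * (1000.0 / self.fs)
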