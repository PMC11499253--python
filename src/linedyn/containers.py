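"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PopulationRaster", "LatentTrajectory", "zscore_rows"]


def zscore_rows(data: np.ndarray, eps: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each row; returns (zscored, constant_row_mask).

    Constant rows (sd < eps) are left centred but unscaled and flagged.
    """
    data = np.asarray(data, dtype=float)
    mu = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)
    constant = sd[:, 0] < eps
    sd = np.where(sd < eps, 1.0, sd)
    return (data - mu) / sd, constant


@dataclass
class PopulationRaster:
    """Neurons x frames matrix of (z-scored) calcium activity."""

    data: np.ndarray  # (n_neurons, n_frames)
    frame_rate: float = 10.0
    neuron_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster must be 2-D (neurons x frames)")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.data.shape[0])

    @property
    def n_neurons(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def zscored(self) -> "PopulationRaster":
        z, _ = zscore_rows(self.data)
        return PopulationRaster(z, self.frame_rate, self.neuron_ids)


@dataclass
class LatentTrajectory:
    """Continuous latents with (optionally) per-frame discrete states.

    ``x`` is D x frames; ``z`` the most-likely discrete state per frame;
    ``credences`` the posterior state probabilities (frames x K).
    """

    x: np.ndarray
    z: np.ndarray | None = None
    credences: np.ndarray | None = None
    frame_rate: float = 10.0

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        if self.z is None:
            self.z = np.zeros(self.x.shape[1], dtype=int)
        if self.credences is None:
            k = int(self.z.max()) + 1
            self.credences = np.zeros((self.x.shape[1], k))
            self.credences[np.arange(self.x.shape[1]), self.z] = 1.0

    @property
    def n_dims(self) -> int:
        return self.x.shape[0]

    @property
    def n_frames(self) -> int:
        return self.x.shape[1]
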