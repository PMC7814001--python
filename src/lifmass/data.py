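"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

__all__ = ["Adjacency", "SpikeRaster", "DriveSeries", "PotentialTrace"]

EXCITATORY = 1
INHIBITORY = 0


@dataclass
class Adjacency:
    """Directed binary adjacency.

    ``matrix[n, m] == 1`` means source ``m`` projects onto target ``n``
    (targets index rows, sources index columns).  Stored sparse; the
    internal graph has no self-loops, the external graph has all-zero
    rows for inhibitory targets.
    """

    matrix: sp.csr_array

    @property
    def n_targets(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_edges(self) -> int:
        return int(self.matrix.nnz)

    def in_degrees(self) -> np.ndarray:
        """Number of sources projecting onto each target."""
        return np.asarray(self.matrix.sum(axis=1)).ravel().astype(np.int64)

    def out_degrees(self) -> np.ndarray:
        """Number of targets each source projects onto."""
        return np.asarray(self.matrix.sum(axis=0)).ravel().astype(np.int64)

    def out_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """(indptr, indices) giving, per source, its target units."""
        csc = self.matrix.tocsc()
        return csc.indptr.astype(np.int64), csc.indices.astype(np.int64)


@dataclass
class SpikeRaster:
    """Spike events of the network: parallel arrays of unit index and time.

    ``unit_type`` is a boolean mask, ``True`` for excitatory units.
    """

    units: np.ndarray
    times: np.ndarray
    unit_type: np.ndarray
    t_total: float

    def __post_init__(self) -> None:
        self.units = np.asarray(self.units, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.unit_type = np.asarray(self.unit_type, dtype=bool)
        if self.units.shape != self.times.shape:
            raise ValueError("units and times must have equal length")
        if self.units.size and (self.units.min() < 0 or self.units.max() >= self.n_units):
            raise ValueError("unit index out of range")
        if self.times.size and (self.times.min() < 0 or self.times.max() > self.t_total):
            raise ValueError("spike times must lie in [0, t_total]")

    @property
    def n_units(self) -> int:
        return self.unit_type.size

    @property
    def n_spikes(self) -> int:
        return self.units.size

    @property
    def n_excitatory(self) -> int:
        return int(self.unit_type.sum())

    def spike_trains(self) -> list[np.ndarray]:
        """Per-unit sorted spike-time arrays."""
        order = np.lexsort((self.times, self.units))
        u, t = self.units[order], self.times[order]
        bounds = np.searchsorted(u, np.arange(self.n_units + 1))
        return [t[bounds[i]: bounds[i + 1]] for i in range(self.n_units)]

    def firing_rates(self) -> np.ndarray:
        """Per-unit mean firing rate in Hz."""
        counts = np.bincount(self.units, minlength=self.n_units)
        return counts / self.t_total * 1e3

    def subset(self, mask: np.ndarray) -> "SpikeRaster":
        """Raster restricted to units where ``mask`` is True (indices remapped)."""
        mask = np.asarray(mask, dtype=bool)
        keep = mask[self.units]
        remap = np.cumsum(mask) - 1
        return SpikeRaster(
            units=remap[self.units[keep]],
            times=self.times[keep],
            unit_type=self.unit_type[mask],
            t_total=self.t_total,
        )


@dataclass
class DriveSeries:
    """Time-binned population-mean spike input, one channel per synapse type.

    Values are rate densities in 1/ms: a spike delivered in a bin
    contributes ``1 / (n_averaged * dt)`` to that bin of its channel.
    """

    phi_exc: np.ndarray
    phi_inh: np.ndarray
    phi_ext: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.phi_exc = np.asarray(self.phi_exc, dtype=np.float64)
        self.phi_inh = np.asarray(self.phi_inh, dtype=np.float64)
        self.phi_ext = np.asarray(self.phi_ext, dtype=np.float64)
        if not (self.phi_exc.shape == self.phi_inh.shape == self.phi_ext.shape):
            raise ValueError("drive channels must share one shape")
        for name in ("phi_exc", "phi_inh", "phi_ext"):
            arr = getattr(self, name)
            if arr.size and arr.min() < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.phi_exc.size

    @property
    def t_total(self) -> float:
        return self.n_bins * self.dt


@dataclass
class PotentialTrace:
    """Uniformly sampled potential time series (mV).

    ``values[k]`` is the potential at ``t = k * dt``.  ``t_transient``
    marks the initial stretch excluded from ``v_bar`` and from all
    downstream statistics (the samples themselves are retained).
    """

    values: np.ndarray
    dt: float
    label: str = "LIF"
    t_transient: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("potential trace contains non-finite values")

    @property
    def t_total(self) -> float:
        return (self.values.size - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt

    def post_transient(self) -> np.ndarray:
        """Samples at t >= t_transient."""
        k0 = int(np.ceil(self.t_transient / self.dt - 1e-9))
        return self.values[k0:]

    @property
    def v_bar(self) -> float:
        """Time average of the potential over the post-transient window."""
        return float(self.post_transient().mean())
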