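"""Stochastic LIF network on a directed Erdős-Rényi graph.

Generates the ground truth against which the mass models are compared:
graph construction (Gilbert model with geometric edge skipping), merged
Poisson external drive, the Euler-Maruyama integration of the
conductance-based membrane equations, and the recomputation of the
population drive from a spike raster.
"""

from __future__ import annotations

import logging
import time

import numpy as np
import scipy.sparse as sp

from ._kernel import run_lif_kernel
from .config import NetworkConfig
from .data import Adjacency, DriveSeries, PotentialTrace, SpikeRaster

__all__ = [
    "IntegrationError",
    "build_internal_graph",
    "build_external_graph",
    "generate_external_drive",
    "simulate_network",
    "population_drive",
]

logger = logging.getLogger(__name__)


class IntegrationError(RuntimeError):
    """The membrane potential diverged during time stepping."""


def _sample_bernoulli_cells(n_cells: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Indices of occupied cells among ``n_cells`` i.i.d. Bernoulli(p) cells.

    Geometric gap sampling (the Gilbert-model trick): the distance
    between consecutive occupied cells is geometric with parameter p, so
    only ~n_cells * p random numbers are drawn instead of n_cells.
    """
    if n_cells == 0 or p <= 0.0:
        return np.empty(0, dtype=np.int64)
    if p >= 1.0:
        return np.arange(n_cells, dtype=np.int64)
    chunks: list[np.ndarray] = []
    pos = -1
    batch = max(1024, int(n_cells * p * 1.1) + 16)
    while True:
        gaps = rng.geometric(p, size=batch)
        idx = pos + np.cumsum(gaps)
        if idx[-1] >= n_cells:
            chunks.append(idx[idx < n_cells])
            break
        chunks.append(idx)
        pos = int(idx[-1])
        batch = max(1024, int((n_cells - pos) * p * 1.1) + 16)
    return np.concatenate(chunks)


def build_internal_graph(n_units: int, p_internal: float, seed) -> Adjacency:
    """Directed Erdős-Rényi graph: every ordered pair (target, source),
    excluding self-loops, is an edge independently with ``p_internal``.

    Edge placement is blind to unit types.
    """
    if not (0.0 <= p_internal <= 1.0):
        raise ValueError(f"p_internal must be in [0, 1], got {p_internal}")
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    rng = np.random.default_rng(seed)
    cells = _sample_bernoulli_cells(n_units * n_units, p_internal, rng)
    targets = cells // n_units
    sources = cells % n_units
    keep = targets != sources
    targets, sources = targets[keep], sources[keep]
    mat = sp.csr_array(
        (np.ones(targets.size, dtype=np.int8), (targets, sources)),
        shape=(n_units, n_units),
    )
    return Adjacency(matrix=mat)


def build_external_graph(
    n_units: int,
    unit_type: np.ndarray,
    m_external: int,
    p_external: float,
    seed,
) -> Adjacency:
    """Bipartite graph from external sources onto the network.

    Only excitatory targets receive external edges; rows of inhibitory
    units are all zero.
    """
    if not (0.0 <= p_external <= 1.0):
        raise ValueError(f"p_external must be in [0, 1], got {p_external}")
    unit_type = np.asarray(unit_type, dtype=bool)
    if unit_type.size != n_units:
        raise ValueError("unit_type must have length n_units")
    rng = np.random.default_rng(seed)
    exc_idx = np.flatnonzero(unit_type)
    cells = _sample_bernoulli_cells(exc_idx.size * m_external, p_external, rng)
    targets = exc_idx[cells // m_external]
    sources = cells % m_external
    mat = sp.csr_array(
        (np.ones(targets.size, dtype=np.int8), (targets, sources)),
        shape=(n_units, m_external),
    )
    return Adjacency(matrix=mat)


def generate_external_drive(
    m_external: int,
    rate_ext: float,
    external_graph: Adjacency,
    t_total: float,
    dt: float,
    seed,
) -> np.ndarray:
    """Binned external spike counts, one row per target unit.

    The merged train of a unit's connected Poisson sources is itself
    Poisson at the aggregate rate (in-degree times ``rate_ext``), so it
    is realized directly: counts[n, k] ~ Poisson(indeg_n * rate * dt).
    """
    if rate_ext < 0:
        raise ValueError("rate_ext must be >= 0")
    if external_graph.n_sources != m_external:
        raise ValueError("external_graph does not match m_external")
    rng = np.random.default_rng(seed)
    n_bins = int(round(t_total / dt))
    lam = external_graph.in_degrees() * (rate_ext / 1e3) * dt
    return rng.poisson(lam[:, None], size=(lam.size, n_bins))


def _unit_types(n_units: int, lambda_exc: float) -> np.ndarray:
    """Boolean type mask with round(lambda * N) excitatory units."""
    n_exc = int(round(lambda_exc * n_units))
    unit_type = np.zeros(n_units, dtype=bool)
    unit_type[:n_exc] = True
    return unit_type


def simulate_network(
    config: NetworkConfig,
    subset: str = "all",
    g_ext_clamp: float | None = None,
    v_init: float | np.ndarray | None = None,
) -> tuple[SpikeRaster, DriveSeries, PotentialTrace]:
    """Integrate the noisy LIF network and record its outputs.

    Returns the spike raster, the three population-mean drive channels
    (excitatory, inhibitory, external; rate densities in 1/ms) and the
    population-mean membrane potential sampled every ``dt``.

    Parameters
    ----------
    config
        Full parameter set; ``config.seed`` fixes graphs, initial
        conditions, external arrivals and membrane noise.
    subset
        ``"all"`` averages drive and potential over every unit,
        ``"excitatory"`` over excitatory units only.
    g_ext_clamp
        If given, the external conductance of every unit is held at this
        constant (nS) and Poisson input is ignored — used for analytic
        single-neuron checks.
    v_init
        Optional initial membrane potential (scalar or per-unit array);
        default is uniform on [v_reset, v_thres) from the seeded stream.
    """
    config.validate()
    if subset not in ("all", "excitatory"):
        raise ValueError(f"subset must be 'all' or 'excitatory', got {subset!r}")

    t0 = time.perf_counter()
    ss = np.random.SeedSequence(config.seed)
    ss_graph, ss_ext, ss_init, ss_kernel = ss.spawn(4)

    unit_type = _unit_types(config.n_units, config.lambda_exc)
    graph = build_internal_graph(config.n_units, config.p_internal, ss_graph)
    ext_graph = build_external_graph(
        config.n_units, unit_type, config.m_external, config.p_external, ss_ext
    )

    rng_init = np.random.default_rng(ss_init)
    if v_init is None:
        v0 = rng_init.uniform(config.v_reset, config.v_thres, size=config.n_units)
    else:
        v0 = np.broadcast_to(np.asarray(v_init, dtype=np.float64), (config.n_units,)).copy()

    sub_mask = np.ones(config.n_units, dtype=bool) if subset == "all" else unit_type.copy()
    if not sub_mask.any():
        raise ValueError("averaging subset is empty")

    ext_lam = ext_graph.in_degrees() * (config.rate_ext / 1e3) * config.dt
    if g_ext_clamp is not None:
        ext_lam = np.zeros_like(ext_lam)
    out_indptr, out_indices = graph.out_csr()

    kernel_seed = int(ss_kernel.generate_state(1, dtype=np.uint32)[0])
    n_ref_steps = int(round(config.tau_ref / config.dt))
    noise_amp = np.sqrt(config.noise_var * config.dt) / config.tau_mem

    (sp_unit, sp_step, phi_e, phi_i, phi_x, vtrace, err_step, err_unit) = run_lif_kernel(
        kernel_seed,
        config.n_steps,
        config.dt,
        v0,
        unit_type,
        sub_mask,
        out_indptr,
        out_indices,
        ext_lam,
        config.v_leak,
        config.v_thres,
        config.v_reset,
        config.v_rev_exc,
        config.v_rev_inh,
        config.v_rev_ext,
        config.tau_mem,
        config.tau_syn_exc,
        config.tau_syn_inh,
        config.tau_syn_ext,
        n_ref_steps,
        config.g_leak,
        config.g_hat_exc,
        config.g_hat_inh,
        config.g_hat_ext,
        noise_amp,
        -1.0 if g_ext_clamp is None else float(g_ext_clamp),
    )
    if err_step >= 0:
        raise IntegrationError(
            f"non-finite membrane potential for unit {err_unit} "
            f"at step {err_step} (t = {err_step * config.dt:.3f} ms)"
        )

    raster = SpikeRaster(
        units=sp_unit,
        times=sp_step * config.dt,
        unit_type=unit_type,
        t_total=config.t_total,
    )
    drive = DriveSeries(phi_exc=phi_e, phi_inh=phi_i, phi_ext=phi_x, dt=config.dt)
    trace = PotentialTrace(
        values=vtrace, dt=config.dt, label="LIF", t_transient=config.t_transient
    )

    n_exc = unit_type.sum()
    rates = raster.firing_rates()
    logger.info(
        "simulated N=%d T=%.0f ms p=%.3g lambda=%.3g: mean degree %.1f, "
        "rate E %.2f Hz / I %.2f Hz, %d spikes, %.1f s wall time",
        config.n_units,
        config.t_total,
        config.p_internal,
        config.lambda_exc,
        graph.n_edges / config.n_units,
        rates[unit_type].mean() if n_exc else float("nan"),
        rates[~unit_type].mean() if n_exc < config.n_units else float("nan"),
        raster.n_spikes,
        time.perf_counter() - t0,
    )
    return raster, drive, trace


def population_drive(
    raster: SpikeRaster,
    internal_graph: Adjacency,
    unit_type: np.ndarray,
    dt: float,
    subset: str = "all",
) -> DriveSeries:
    """Recompute the internal population drive from a spike raster.

    For each synapse type and time bin: the mean over target units (in
    ``subset``) of spikes received through edges of that type, divided
    by ``dt``.  A spike lands in bin ``floor(t / dt)``; spikes at
    exactly ``t_total`` fall outside the recorded window and are
    dropped, mirroring the simulator (they are never delivered).

    The external channel cannot be reconstructed from the raster (the
    external arrivals are not part of it) and is returned as zeros.
    """
    unit_type = np.asarray(unit_type, dtype=bool)
    if unit_type.size != raster.n_units:
        raise ValueError("unit_type length does not match raster")
    if internal_graph.n_targets != raster.n_units or internal_graph.n_sources != raster.n_units:
        raise ValueError("internal_graph shape does not match raster")
    if subset not in ("all", "excitatory"):
        raise ValueError(f"subset must be 'all' or 'excitatory', got {subset!r}")

    sub_mask = np.ones(raster.n_units, dtype=bool) if subset == "all" else unit_type
    n_sub = int(sub_mask.sum())
    if n_sub == 0:
        raise ValueError("averaging subset is empty")

    n_bins = int(round(raster.t_total / dt))
    # out-degree of each source restricted to subset targets
    sub_rows = internal_graph.matrix[sub_mask]
    out_deg_sub = np.asarray(sub_rows.sum(axis=0)).ravel().astype(np.float64)

    bins = np.floor(raster.times / dt + 1e-9).astype(np.int64)
    keep = bins < n_bins
    bins = bins[keep]
    units = raster.units[keep]
    w = out_deg_sub[units] / (n_sub * dt)
    is_exc_spike = unit_type[units]

    phi_exc = np.bincount(bins[is_exc_spike], weights=w[is_exc_spike], minlength=n_bins)
    phi_inh = np.bincount(bins[~is_exc_spike], weights=w[~is_exc_spike], minlength=n_bins)
    return DriveSeries(
        phi_exc=phi_exc,
        phi_inh=phi_inh,
        phi_ext=np.zeros(n_bins),
        dt=dt,
    )
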