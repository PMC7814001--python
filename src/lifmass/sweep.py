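"""Orchestration of the {p, lambda} comparison experiment.

Per grid point: repeated network simulations (fresh graph and drive per
repetition), mass-model integration on each recorded drive, synchrony of
the raster, realization-averaged spectra with χ² comparison, and
lag-optimized correlations.  Results accumulate in an append-safe CSV
table, one row per point, resumable by grid coordinates.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .config import MassConfig, NetworkConfig
from .data import PotentialTrace
from .mass import integrate_cfm, integrate_mfm
from .network import simulate_network
from .spectral import (
    DEFAULT_BAND,
    chi2_significance,
    chi2_spectra,
    estimate_spectrum,
)
from .synchrony import UndefinedMeasureError, spike_contrast
from .temporal import DEFAULT_MAX_LAG, DEFAULT_RHO0, fisher_significance, lagged_correlation

__all__ = ["SweepGrid", "ComparisonResult", "run_point", "run_sweep", "point_seeds"]

logger = logging.getLogger(__name__)


@dataclass
class SweepGrid:
    """Grid specification plus the counter-based seeding scheme."""

    p_values: list[float]
    lambda_values: list[float]
    base_config: NetworkConfig
    n_repetitions: int = 10
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.p_values or not self.lambda_values:
            raise ValueError("grids must be non-empty")
        for v in list(self.p_values) + list(self.lambda_values):
            if not (0.0 <= v <= 1.0):
                raise ValueError("grid values must lie in [0, 1]")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")

    def points(self) -> list[tuple[int, float, float]]:
        out = []
        idx = 0
        for p in self.p_values:
            for lam in self.lambda_values:
                out.append((idx, float(p), float(lam)))
                idx += 1
        return out


def point_seeds(master_seed: int, p: float, lam: float, n_repetitions: int) -> list[int]:
    """Per-repetition seeds, reproducible from (master, coordinates, repetition).

    Keyed on the grid coordinates (at 1e-9 resolution), not on the sweep
    order, so shuffling the grid leaves every point's seeds unchanged.
    """
    key = (int(round(p * 1e9)), int(round(lam * 1e9)))
    return [
        int(
            np.random.SeedSequence(
                entropy=master_seed, spawn_key=(*key, rep)
            ).generate_state(1)[0]
        )
        for rep in range(n_repetitions)
    ]


@dataclass
class ComparisonResult:
    """All comparison statistics of one {p, lambda} grid point."""

    p: float
    lam: float
    n_repetitions: int
    synchrony: float
    median_freq_lif: float
    median_freq_cfm: float
    median_freq_mfm: float
    chi2_cfm: float
    chi2_mfm: float
    chi2_cfm_ok: bool
    chi2_mfm_ok: bool
    chi2_self: float
    tau_max_cfm: float
    rho_max_cfm: float
    corr_cfm_ok: bool
    tau_max_mfm: float
    rho_max_mfm: float
    corr_mfm_ok: bool
    v_bar: float
    mean_rate_hz: float

    def to_row(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @staticmethod
    def columns() -> list[str]:
        return [f.name for f in fields(ComparisonResult)]


def _modal_tau(taus: list[float]) -> float:
    """Most common optimal lag; ties resolved toward small |tau|, then positive."""
    counts = Counter(taus)
    best = max(counts.values())
    cand = [t for t, c in counts.items() if c == best]
    cand.sort(key=lambda t: (abs(t), -np.sign(t)))
    return float(cand[0])


def run_point(
    p: float,
    lam: float,
    base_config: NetworkConfig,
    seeds: list[int],
    subset: str = "all",
    max_lag: float = DEFAULT_MAX_LAG,
    band: tuple[float, float] = DEFAULT_BAND,
    alpha: float = 0.01,
    rho0: float = DEFAULT_RHO0,
) -> ComparisonResult:
    """Simulate one grid point with repetitions and compare all models.

    Each repetition redraws graph, initial conditions and drive from its
    own seed.  Spectra are averaged across repetitions before the χ²
    comparison; correlations are computed per repetition and summarized
    by their mean peak value and the modal optimal lag.  A silent or
    single-spike raster counts as zero synchrony.
    """
    if not seeds:
        raise ValueError("need at least one seed")
    lif_traces: list[PotentialTrace] = []
    cfm_traces: list[PotentialTrace] = []
    mfm_traces: list[PotentialTrace] = []
    sync_vals: list[float] = []
    corr_cfm = []
    corr_mfm = []
    v_bars: list[float] = []
    rates: list[float] = []

    try:
        for seed in seeds:
            cfg = base_config.replace(p_internal=p, lambda_exc=lam, seed=int(seed))
            raster, drive, lif = simulate_network(cfg, subset=subset)
            try:
                sync_vals.append(spike_contrast(raster).value)
            except UndefinedMeasureError:
                sync_vals.append(0.0)
            rates.append(float(raster.firing_rates().mean()))
            v_bar = lif.v_bar
            v_bars.append(v_bar)

            cfm = integrate_cfm(
                drive,
                MassConfig.from_network(cfg, "CFM", v_bar=v_bar),
                t_transient=cfg.t_transient,
            )
            mfm = integrate_mfm(
                drive,
                MassConfig.from_network(cfg, "MFM", v0=float(lif.values[0])),
                t_transient=cfg.t_transient,
            )
            lif_traces.append(lif)
            cfm_traces.append(cfm)
            mfm_traces.append(mfm)
            corr_cfm.append(lagged_correlation(lif, cfm, max_lag, alpha=alpha, rho0=rho0))
            corr_mfm.append(lagged_correlation(lif, mfm, max_lag, alpha=alpha, rho0=rho0))

        spec_lif = estimate_spectrum(lif_traces, band=band)
        spec_cfm = estimate_spectrum(cfm_traces, band=band)
        spec_mfm = estimate_spectrum(mfm_traces, band=band)
        chi2_c = chi2_spectra(spec_lif, spec_cfm)
        chi2_m = chi2_spectra(spec_lif, spec_mfm)
        chi2_self = chi2_spectra(spec_lif, spec_lif)

        rho_c = float(np.mean([c.rho_max for c in corr_cfm]))
        rho_m = float(np.mean([c.rho_max for c in corr_mfm]))
        n_eff_c = float(np.median([c.n_effective for c in corr_cfm]))
        n_eff_m = float(np.median([c.n_effective for c in corr_mfm]))
    except Exception as exc:
        raise RuntimeError(f"grid point (p={p}, lambda={lam}) failed: {exc}") from exc

    return ComparisonResult(
        p=float(p),
        lam=float(lam),
        n_repetitions=len(seeds),
        synchrony=float(np.mean(sync_vals)),
        median_freq_lif=spec_lif.median_freq,
        median_freq_cfm=spec_cfm.median_freq,
        median_freq_mfm=spec_mfm.median_freq,
        chi2_cfm=chi2_c,
        chi2_mfm=chi2_m,
        chi2_cfm_ok=chi2_significance(chi2_c, spec_lif.n_bins, alpha),
        chi2_mfm_ok=chi2_significance(chi2_m, spec_lif.n_bins, alpha),
        chi2_self=chi2_self,
        tau_max_cfm=_modal_tau([c.tau_max for c in corr_cfm]),
        rho_max_cfm=rho_c,
        corr_cfm_ok=fisher_significance(rho_c, n_eff_c, alpha=alpha, rho0=rho0),
        tau_max_mfm=_modal_tau([c.tau_max for c in corr_mfm]),
        rho_max_mfm=rho_m,
        corr_mfm_ok=fisher_significance(rho_m, n_eff_m, alpha=alpha, rho0=rho0),
        v_bar=float(np.mean(v_bars)),
        mean_rate_hz=float(np.mean(rates)),
    )


def _format_value(v) -> str:
    if isinstance(v, (bool, np.bool_)):
        return str(bool(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    return str(v)


def run_sweep(
    grid: SweepGrid,
    out_dir: str | Path | None = None,
    resume: bool = False,
    subset: str = "all",
    **point_kwargs,
) -> pd.DataFrame:
    """Run :func:`run_point` over the grid; returns the sorted result table.

    With ``out_dir`` set, every completed point is appended to
    ``results.csv`` immediately (values serialized via ``repr`` so reruns
    are bit-identical); with ``resume=True`` points already present in
    that file are skipped and their stored rows reused.  Failed points
    are logged and skipped, not fatal.
    """
    csv_path = Path(out_dir) / "results.csv" if out_dir is not None else None
    done: dict[tuple[float, float], dict] = {}
    if csv_path is not None:
        csv_path.parent.mkdir(parents=True, exist_ok=True)
        if resume and csv_path.exists():
            prev = pd.read_csv(csv_path)
            for _, row in prev.iterrows():
                done[(float(row["p"]), float(row["lam"]))] = row.to_dict()
        elif csv_path.exists():
            csv_path.unlink()

    cols = ComparisonResult.columns()
    rows: list[dict] = []
    for idx, p, lam in grid.points():
        key = (p, lam)
        if key in done:
            rows.append(done[key])
            continue
        seeds = point_seeds(grid.master_seed, p, lam, grid.n_repetitions)
        try:
            result = run_point(p, lam, grid.base_config, seeds, subset=subset, **point_kwargs)
        except RuntimeError:
            logger.exception("sweep point (p=%g, lambda=%g) failed; skipping", p, lam)
            continue
        row = result.to_row()
        rows.append(row)
        if csv_path is not None:
            write_header = not csv_path.exists()
            with open(csv_path, "a", newline="") as fh:
                writer = csv.DictWriter(fh, fieldnames=cols)
                if write_header:
                    writer.writeheader()
                writer.writerow({k: _format_value(v) for k, v in row.items()})
                fh.flush()
        logger.info(
            "point (p=%g, lambda=%g): synchrony=%.3f, median f=%.2f Hz, "
            "rho(CFM)=%.3f, rho(MFM)=%.3f",
            p, lam, row["synchrony"], row["median_freq_lif"],
            row["rho_max_cfm"], row["rho_max_mfm"],
        )

    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["p", "lam"], kind="mergesort").reset_index(drop=True)


def render_heatmaps(df: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """Quick-look heatmaps of the sweep statistics (one PNG per metric)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    metrics = [
        "synchrony",
        "median_freq_lif",
        "chi2_cfm",
        "chi2_mfm",
        "tau_max_cfm",
        "tau_max_mfm",
        "rho_max_cfm",
        "rho_max_mfm",
    ]
    written = []
    pivoted = {m: df.pivot(index="lam", columns="p", values=m) for m in metrics}
    for m, grid in pivoted.items():
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.pcolormesh(grid.columns.values, grid.index.values, grid.values, shading="nearest")
        fig.colorbar(im, ax=ax, label=m)
        ax.set_xlabel("p")
        ax.set_ylabel("lambda")
        ax.set_title(m)
        path = out_dir / f"heatmap_{m}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
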