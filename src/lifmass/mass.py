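"""Second-order neural mass models driven by recorded population spike input.

Both variants share the factorized linear operator
``[tau_mem d/dt + 1][tau_syn d/dt + 1] V = RHS``:

* conventional (CFM) — the synaptic driving forces use the constant
  time-averaged potential ``v_bar``, so the model is linear in the drive;
* modified (MFM) — the driving forces use the instantaneous potential
  ``V(t)``, a parametric (multiplicative) forcing.

Integration is an explicit forward-Euler cascade matching the network's
time step, with the drive held piecewise constant per bin.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .config import MassConfig
from .data import DriveSeries, PotentialTrace

__all__ = ["integrate_cfm", "integrate_mfm", "integrate_mass", "analytic_response"]


@njit(nogil=True)
def _mass_euler(
    rhs_const: np.ndarray,
    rhs_slope: np.ndarray,
    v0: float,
    u0: float,
    dt: float,
    tau_mem: float,
    tau_syn: float,
) -> np.ndarray:
    """Cascade Euler integration of the factorized second-order operator.

    Per bin k the right-hand side is ``rhs_const[k] + rhs_slope[k] * V``
    (slope is zero for the linear variant).  State: V and the auxiliary
    U = tau_syn * dV/dt + V, so each operator factor is one first-order
    Euler step.

    Bins with a stiff parametric term (|slope| large, e.g. a whole
    population burst landing in one bin of the multiplicative variant)
    are integrated with Euler sub-steps sized so that
    ``dt_sub * sqrt(|slope| / (tau_mem * tau_syn)) <= 0.05``; the
    explicit single-step scheme diverges there while the underlying
    dynamics — a momentarily stiff damped oscillator — is bounded.
    Slope-free bins take exactly one plain Euler step.
    """
    n = rhs_const.size
    out = np.empty(n + 1)
    v = v0
    u = u0
    out[0] = v
    stiff_scale = 0.05 * 0.05 * tau_mem * tau_syn / (dt * dt)
    for k in range(n):
        slope = rhs_slope[k]
        n_sub = 1
        if slope != 0.0:
            # n_sub^2 >= dt^2 |slope| / (0.05^2 tau_mem tau_syn)
            ratio = abs(slope) / stiff_scale
            if ratio > 1.0:
                n_sub = int(np.ceil(np.sqrt(ratio)))
        h = dt / n_sub
        for _ in range(n_sub):
            rhs = rhs_const[k] + slope * v
            u_new = u + (h / tau_mem) * (rhs - u)
            v_new = v + (h / tau_syn) * (u - v)
            u = u_new
            v = v_new
        out[k + 1] = v
    return out


def _check_drive(drive: DriveSeries, config: MassConfig) -> None:
    if abs(drive.dt - config.dt) > 1e-12:
        raise ValueError(f"drive dt {drive.dt} does not match config dt {config.dt}")
    for name in ("phi_exc", "phi_inh", "phi_ext"):
        if not np.all(np.isfinite(getattr(drive, name))):
            raise ValueError(f"non-finite values in drive channel {name}")


def integrate_mass(
    drive: DriveSeries,
    config: MassConfig,
    t_transient: float = 0.0,
    freeze_at: float | None = None,
) -> PotentialTrace:
    """Integrate the mass model selected by ``config.variant``.

    ``freeze_at`` (MFM only) replaces the instantaneous potential on the
    right-hand side by the given constant, which reduces the modified
    model to the conventional one — the integration then follows the
    identical code path, bit for bit.
    """
    _check_drive(drive, config)

    # per-channel weighted drive, common to both variants
    s = config.drive_scale
    w_exc = config.g_ratio_exc * s * drive.phi_exc
    w_inh = config.g_ratio_inh * s * drive.phi_inh
    w_ext = config.g_ratio_ext * s * drive.phi_ext
    phi_sum = w_exc + w_inh + w_ext
    rev_sum = (
        config.v_rev_exc * w_exc + config.v_rev_inh * w_inh + config.v_rev_ext * w_ext
    )

    if freeze_at is not None and config.variant != "MFM":
        raise ValueError("freeze_at only applies to the MFM")
    if config.variant == "CFM" or freeze_at is not None:
        v_bar = config.require_v_bar() if freeze_at is None else float(freeze_at)
        rhs_const = config.v_leak - v_bar * phi_sum + rev_sum
        rhs_slope = np.zeros_like(rhs_const)
        v0 = v_bar if config.v0 is None else config.v0
    else:
        rhs_const = config.v_leak + rev_sum
        rhs_slope = -phi_sum
        if config.v0 is None:
            raise ValueError("v0 must be given for the MFM")
        v0 = config.v0

    u0 = v0 + config.tau_syn * config.dv0
    values = _mass_euler(
        np.ascontiguousarray(rhs_const, dtype=np.float64),
        np.ascontiguousarray(rhs_slope, dtype=np.float64),
        float(v0),
        float(u0),
        config.dt,
        config.tau_mem,
        config.tau_syn,
    )
    if not np.all(np.isfinite(values)):
        raise ValueError("mass-model integration produced non-finite values")
    return PotentialTrace(
        values=values, dt=config.dt, label=config.variant, t_transient=t_transient
    )


def integrate_cfm(
    drive: DriveSeries, config: MassConfig, t_transient: float = 0.0
) -> PotentialTrace:
    """Conventional variant: constant forcing potential ``v_bar``."""
    if config.variant != "CFM":
        raise ValueError("config.variant must be 'CFM'")
    return integrate_mass(drive, config, t_transient)


def integrate_mfm(
    drive: DriveSeries, config: MassConfig, t_transient: float = 0.0
) -> PotentialTrace:
    """Modified variant: instantaneous potential in the driving forces."""
    if config.variant != "MFM":
        raise ValueError("config.variant must be 'MFM'")
    return integrate_mass(drive, config, t_transient)


def analytic_response(freq: float | np.ndarray, config: MassConfig) -> np.ndarray:
    """Complex gain of the drive-free second-order low-pass operator.

    ``1 / ((1 + i 2π f tau_mem)(1 + i 2π f tau_syn))`` with ``freq`` in
    Hz and the time constants in ms.
    """
    f = np.asarray(freq, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("freq must be >= 0")
    omega = 2.0 * np.pi * f / 1e3  # rad/ms
    gain = 1.0 / ((1.0 + 1j * omega * config.tau_mem) * (1.0 + 1j * omega * config.tau_syn))
    return gain if np.ndim(gain) else complex(gain)
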