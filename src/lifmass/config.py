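"""Configuration objects for the network simulator and the mass models."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import yaml

__all__ = ["NetworkConfig", "MassConfig"]


@dataclass
class NetworkConfig:
    """Full parameter set of the stochastic LIF network simulation.

    Defaults correspond to the reference parameter table: a network of
    10,000 conductance-based LIF units driven by 10,000 external Poisson
    units, integrated with an Euler-Maruyama scheme at 0.1 ms resolution.

    Times are in ms, potentials in mV, conductances in nS, rates in Hz.
    """

    # topology
    n_units: int = 10_000
    m_external: int = 10_000
    p_internal: float = 0.2
    p_external: float = 0.1
    lambda_exc: float = 0.8

    # membrane / reset
    v_thres: float = -50.0
    v_reset: float = -60.0
    v_leak: float = -80.0

    # synaptic reversal potentials
    v_rev_exc: float = 0.0
    v_rev_inh: float = -70.0
    v_rev_ext: float = 0.0

    # time constants
    tau_mem: float = 20.0
    tau_syn_exc: float = 3.0
    tau_syn_inh: float = 7.0
    tau_syn_ext: float = 3.0
    tau_ref: float = 5.0

    # conductances
    g_leak: float = 10.0
    g_hat_exc: float = 4.0
    g_hat_inh: float = 40.0
    g_hat_ext: float = 5.0

    # drive and noise
    noise_var: float = 5e-4
    rate_ext: float = 5.0

    # integration
    dt: float = 0.1
    t_total: float = 3e4
    t_transient: float = 3e3
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.0 <= self.p_internal <= 1.0):
            raise ValueError(f"p_internal must be in [0, 1], got {self.p_internal}")
        if not (0.0 <= self.p_external <= 1.0):
            raise ValueError(f"p_external must be in [0, 1], got {self.p_external}")
        if not (0.0 <= self.lambda_exc <= 1.0):
            raise ValueError(f"lambda_exc must be in [0, 1], got {self.lambda_exc}")
        if self.v_reset >= self.v_thres:
            raise ValueError("v_reset must be below v_thres")
        for name in ("tau_mem", "tau_syn_exc", "tau_syn_inh", "tau_syn_ext"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0.0 <= self.t_transient < self.t_total):
            raise ValueError("require 0 <= t_transient < t_total")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.m_external < 0:
            raise ValueError("m_external must be >= 0")
        if self.rate_ext < 0:
            raise ValueError("rate_ext must be >= 0")
        if self.noise_var < 0:
            raise ValueError("noise_var must be >= 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_total / self.dt))

    @property
    def n_excitatory(self) -> int:
        return int(round(self.lambda_exc * self.n_units))

    def replace(self, **kwargs) -> "NetworkConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NetworkConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class MassConfig:
    """Parameters of the second-order mass dynamics.

    ``variant`` selects between the conventional model (constant forcing
    potential ``v_bar``) and the modified one (instantaneous potential on
    the right-hand side).  ``tau_syn`` defaults to 5 ms, the average of
    the network's excitatory (3 ms) and inhibitory (7 ms) synaptic time
    constants.

    ``drive_scale`` multiplies every drive channel before it enters the
    right-hand side.  The recorded population drive is a rate density
    (1/ms); the mass dynamics consumes the per-step spike input, so the
    pipeline sets ``drive_scale = dt`` (see ``from_network``).  The
    default of 1.0 feeds the drive through unchanged, which is what the
    closed-form steady-state and filter oracles assume.
    """

    variant: Literal["CFM", "MFM"] = "CFM"
    tau_mem: float = 20.0
    tau_syn: float = 5.0
    v_leak: float = -80.0
    v_rev_exc: float = 0.0
    v_rev_inh: float = -70.0
    v_rev_ext: float = 0.0
    g_ratio_exc: float = 0.4
    g_ratio_inh: float = 4.0
    g_ratio_ext: float = 0.5
    v_bar: float | None = None
    dt: float = 0.1
    v0: float | None = None
    dv0: float = 0.0
    drive_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.variant not in ("CFM", "MFM"):
            raise ValueError(f"variant must be 'CFM' or 'MFM', got {self.variant!r}")
        if self.tau_mem <= 0 or self.tau_syn <= 0:
            raise ValueError("time constants must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def require_v_bar(self) -> float:
        if self.v_bar is None or not (self.v_bar == self.v_bar):  # NaN check
            raise ValueError("v_bar must be a finite potential for the CFM")
        return float(self.v_bar)

    @classmethod
    def from_network(
        cls,
        net: NetworkConfig,
        variant: str = "CFM",
        v_bar: float | None = None,
        tau_syn: float = 5.0,
        **kwargs,
    ) -> "MassConfig":
        """Derive mass-model parameters from a network configuration.

        Sets ``drive_scale = net.dt``: the recorded 1/ms drive densities
        are converted to the per-step spike counts the mass dynamics is
        forced with.
        """
        kwargs.setdefault("drive_scale", net.dt)
        return cls(
            variant=variant,
            tau_mem=net.tau_mem,
            tau_syn=tau_syn,
            v_leak=net.v_leak,
            v_rev_exc=net.v_rev_exc,
            v_rev_inh=net.v_rev_inh,
            v_rev_ext=net.v_rev_ext,
            g_ratio_exc=net.g_hat_exc / net.g_leak,
            g_ratio_inh=net.g_hat_inh / net.g_leak,
            g_ratio_ext=net.g_hat_ext / net.g_leak,
            v_bar=v_bar,
            dt=net.dt,
            **kwargs,
        )

    def replace(self, **kwargs) -> "MassConfig":
        return dataclasses.replace(self, **kwargs)
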