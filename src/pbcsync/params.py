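"""Biophysical parameters of the modified Toporikova-Butera PBC neuron.

The model couples a three-variable somatic subsystem (membrane potential
``V``, delayed-rectifier activation ``n``, persistent-sodium inactivation
``h``) to a two-variable calcium subsystem that traces an ellipse in the
([Ca], l) plane.  :class:`ModelParams` holds every constant of the model;
the shipped ``table1.yaml`` is the canonical default set.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = ["ModelParams", "NetworkConfig", "PARAM_ORDER"]

#: Fixed field order used when packing parameters into a flat float array
#: for the compiled integration kernels.
PARAM_ORDER = (
    "C_m", "g_Na", "g_K", "g_L", "g_NaP", "g_CAN",
    "V_Na", "V_K", "V_L", "V_m", "V_n", "V_p", "V_h",
    "s_m", "s_n", "s_h", "s_mp",
    "tau_n_bar", "tau_h_bar",
    "n_CAN", "K_CAN",
    "eps", "d", "Ca_c", "l_c",
)


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """All biophysical constants of the single-neuron model.

    Conductances in nS, voltages in mV, time constants in ms, calcium in uM.
    Defaults are the canonical parameter set shipped as ``table1.yaml``.
    """

    C_m: float = 21.0
    g_Na: float = 28.0
    g_K: float = 11.2
    g_L: float = 2.3
    g_NaP: float = 2.0
    g_CAN: float = 0.7
    V_Na: float = 50.0
    V_K: float = -85.0
    V_L: float = -58.0
    V_m: float = -34.0
    V_n: float = -29.0
    V_p: float = -40.0
    V_h: float = -48.0
    s_m: float = -5.0
    s_n: float = -4.0
    s_h: float = 5.0
    s_mp: float = -6.0
    tau_n_bar: float = 10.0
    tau_h_bar: float = 10000.0
    n_CAN: float = 0.97
    K_CAN: float = 0.74
    eps: float = 0.09
    d: float = 0.5
    Ca_c: float = 0.1
    l_c: float = 0.9

    def __post_init__(self) -> None:
        for name in ("g_Na", "g_K", "g_L", "g_NaP", "g_CAN"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        for name, cond in (
            ("C_m", self.C_m > 0),
            ("eps", self.eps > 0),
            ("d", self.d > 0),
            ("Ca_c", self.Ca_c > 0),
            ("tau_n_bar", self.tau_n_bar > 0),
            ("tau_h_bar", self.tau_h_bar > 0),
            ("K_CAN", self.K_CAN > 0),
        ):
            if not cond:
                raise ValueError(f"parameter {name} must be positive")
        if not 0.0 < self.l_c < 1.0:
            raise ValueError("l_c must lie in (0, 1)")
        for name in ("s_m", "s_n", "s_h", "s_mp"):
            if getattr(self, name) == 0:
                raise ValueError(f"gating slope {name} must be nonzero")

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_array(self) -> np.ndarray:
        """Pack into a flat float64 array in :data:`PARAM_ORDER`."""
        return np.array([getattr(self, k) for k in PARAM_ORDER], dtype=np.float64)

    # -- YAML round trip ---------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        mapping = {k: float(getattr(self, k)) for k in PARAM_ORDER}
        Path(path).write_text(yaml.safe_dump(mapping, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParams":
        mapping = yaml.safe_load(Path(path).read_text())
        return cls(**mapping)

    @classmethod
    def table1(cls) -> "ModelParams":
        """The canonical default set from the packaged ``table1.yaml``."""
        with resources.files("pbcsync").joinpath("table1.yaml").open() as fh:
            return cls(**yaml.safe_load(fh))


@dataclasses.dataclass(frozen=True)
class NetworkConfig:
    """Configuration of the electrically coupled two-neuron network.

    ``g_c`` is the gap-junction coupling strength in nS; ``tau1``/``tau2``
    are the transmission delays (ms) of the voltage each neuron sees from
    its partner; ``I_exc1``/``I_exc2`` the stimulus currents.  Negative
    ``g_c`` is the diffusive (synchronizing) direction in this sign
    convention, since the coupling current enters the voltage equation
    with a minus sign.
    """

    g_c: float = -0.4
    tau1: float = 0.0
    tau2: float = 0.0
    I_exc1: float = 8.5
    I_exc2: float = 8.5

    def __post_init__(self) -> None:
        if self.tau1 < 0 or self.tau2 < 0:
            raise ValueError("delays must be >= 0")

    @property
    def symmetric(self) -> bool:
        return self.tau1 == self.tau2

    @property
    def identical(self) -> bool:
        return self.I_exc1 == self.I_exc2

    def replace(self, **changes) -> "NetworkConfig":
        return dataclasses.replace(self, **changes)
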