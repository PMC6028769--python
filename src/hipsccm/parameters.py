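"""Model parameters, named parameter sets, and conductance scaling.

The model is a ventricular-like human iPSC-derived cardiomyocyte (hiPSC-CM)
membrane model of the Paci family: sarcolemmal currents fitted on patch-clamp
data, a two-compartment Ca2+ subsystem (cytosol + sarcoplasmic reticulum), and
a ryanodine-receptor (RyR) release flux gated by cytosolic Ca2+ through three
gates (adaptation, activation/open, inactivation/closed) plus a luminal-Ca2+
modulation factor.

Two parameter sets ship with the package:

``paci2013-baseline``
    The pre-optimization values: the Paci2013/2015 Ca2+-handling and pump
    parameters together with the RyR gate seeds (the atrial-source values
    rescaled to 1/10, adapted to this model's Ca2+ scale).
``paci2018-optimized``
    The published optimized values of the 2018 model.

Unit conventions follow the model family: potentials in volts, time in
seconds, concentrations in mM, membrane current densities in A/F, SR fluxes in
mM/s.  The RyR half-activations, adaptation constants and slopes are stored in
uM and compared against ``1000 * Ca_i`` inside the gate equations; this keeps
the printed decimal values intact in the config files.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "RyRParameters",
    "ModelParameters",
    "CONDUCTANCE_REGISTRY",
    "OPTIMIZED_PARAMETER_NAMES",
    "load_parameters",
    "save_parameters",
    "registered_parameter_sets",
    "apply_block",
    "make_immature_ryr",
]


@dataclass(frozen=True)
class RyRParameters:
    """Ryanodine-receptor release subsystem constants.

    ``I_rel_max`` is the maximum SR release rate (mM/s).  The gate equations
    compare cytosolic Ca2+ (converted to uM) against ``a_half``/``o_half``/
    ``c_half`` shifted by the adaptation gate; ``a1``/``a2`` set the range of
    the adaptation gate; ``*_k`` are sigmoid slopes (uM); ``tau_*`` are the
    gate relaxation time constants (s).
    """

    I_rel_max: float = 62.5434  # mM/s
    a1: float = 0.05354        # uM
    a2: float = 0.0488         # uM
    a_half: float = 0.02427    # uM
    o_half: float = 0.01042    # uM
    c_half: float = 0.00144    # uM
    a_k: float = 0.0082        # uM
    o_k: float = 0.003         # uM
    c_k: float = 0.001         # uM
    tau_a: float = 1.0         # s
    tau_o: float = 0.01875     # s
    tau_c: float = 0.0875      # s

    def __post_init__(self) -> None:
        if self.I_rel_max < 0:
            raise ValueError("I_rel_max must be >= 0")
        for name in ("a_k", "o_k", "c_k"):
            if getattr(self, name) == 0:
                raise ValueError(f"RyR slope {name} must be nonzero")
        for name in ("tau_a", "tau_o", "tau_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"RyR time constant {name} must be > 0")


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the hiPSC-CM model.

    Maximal conductances are in S/F, maximal pump/exchanger currents in A/F,
    SR flux maxima in mM/s (SERCA) and 1/s (leak), concentrations in mM.
    Geometry: membrane capacitance ``Cm`` (F), cytosol and SR volumes (um^3).
    """

    # sarcolemmal maximal conductances / currents
    G_Na: float = 3671.2302      # S/F
    G_NaL: float = 17.25         # S/F (2.3 * 7.5, late Na+ current)
    G_CaL: float = 8.635702e-5   # m^3/(F*s)
    G_f: float = 30.10312        # S/F
    G_to: float = 29.9038        # S/F
    G_Kr: float = 29.8667        # S/F
    G_Ks: float = 2.041          # S/F
    G_K1: float = 28.1492        # S/F
    G_bNa: float = 0.95          # S/F
    G_bCa: float = 0.727272      # S/F
    G_pCa: float = 0.4125        # A/F
    I_NaCa_max: float = 3917.0463  # A/F
    I_NaK_max: float = 2.6351      # A/F
    alpha: float = 2.5371          # outward-enhancement factor of I_NaCa
    # SR fluxes
    V_max_up: float = 0.5113       # mM/s
    K_up: float = 3.1928e-4        # mM
    I_leak_max: float = 4.7279e-4  # 1/s
    ryr: RyRParameters = dataclasses.field(default_factory=RyRParameters)
    # extracellular / fixed intracellular concentrations
    Na_o: float = 151.0  # mM
    K_o: float = 5.4     # mM
    Ca_o: float = 1.8    # mM
    K_i: float = 150.0   # mM (held constant)
    # geometry
    Cm: float = 9.87109e-11  # F
    V_c: float = 8800.0      # um^3
    V_SR: float = 583.73     # um^3
    name: str = "paci2018-optimized"

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.name in ("ryr", "name"):
                continue
            if getattr(self, f.name) < 0:
                raise ValueError(f"parameter {f.name} must be >= 0")

    # -- registry access -------------------------------------------------
    def get(self, name: str) -> float:
        """Look up a parameter by its registry name."""
        path = _REGISTRY_PATHS.get(name)
        if path is None:
            raise KeyError(_unknown_name_msg(name))
        obj = self
        for attr in path[:-1]:
            obj = getattr(obj, attr)
        return getattr(obj, path[-1])

    def with_values(self, **updates: float) -> "ModelParameters":
        """Return a copy with registry-named parameters replaced."""
        top: dict[str, float] = {}
        ryr_updates: dict[str, float] = {}
        for name, value in updates.items():
            path = _REGISTRY_PATHS.get(name)
            if path is None:
                raise KeyError(_unknown_name_msg(name))
            if path[0] == "ryr":
                ryr_updates[path[1]] = value
            else:
                top[path[0]] = value
        params = self
        if ryr_updates:
            params = replace(params, ryr=replace(params.ryr, **ryr_updates))
        if top:
            params = replace(params, **top)
        return params


# Registry name -> attribute path.  The first block is the stable public
# conductance registry; the second adds the remaining tunables.
_REGISTRY_PATHS: dict[str, tuple[str, ...]] = {
    "G_Na": ("G_Na",),
    "G_NaL": ("G_NaL",),
    "G_CaL": ("G_CaL",),
    "G_f": ("G_f",),
    "G_to": ("G_to",),
    "G_Kr": ("G_Kr",),
    "G_Ks": ("G_Ks",),
    "G_K1": ("G_K1",),
    "G_bNa": ("G_bNa",),
    "G_bCa": ("G_bCa",),
    "G_pCa": ("G_pCa",),
    "I_NaCa_max": ("I_NaCa_max",),
    "I_NaK_max": ("I_NaK_max",),
    "V_max_up": ("V_max_up",),
    "I_rel_max": ("ryr", "I_rel_max"),
    "I_leak_max": ("I_leak_max",),
    "K_up": ("K_up",),
    "alpha": ("alpha",),
    "RyR_a1": ("ryr", "a1"),
    "RyR_a2": ("ryr", "a2"),
    "RyR_a_half": ("ryr", "a_half"),
    "RyR_o_half": ("ryr", "o_half"),
    "RyR_c_half": ("ryr", "c_half"),
    "RyR_a_k": ("ryr", "a_k"),
    "RyR_o_k": ("ryr", "o_k"),
    "RyR_c_k": ("ryr", "c_k"),
    "tau_RyR_a": ("ryr", "tau_a"),
    "tau_RyR_o": ("ryr", "tau_o"),
    "tau_RyR_c": ("ryr", "tau_c"),
    "Na_o": ("Na_o",),
    "K_o": ("K_o",),
    "Ca_o": ("Ca_o",),
}

#: Names accepted by :func:`apply_block` (maximal conductances and fluxes).
CONDUCTANCE_REGISTRY: tuple[str, ...] = (
    "G_Na", "G_NaL", "G_CaL", "G_f", "G_to", "G_Kr", "G_Ks", "G_K1",
    "G_bNa", "G_bCa", "G_pCa",
    "I_NaCa_max", "I_NaK_max", "V_max_up", "I_rel_max", "I_leak_max",
)

#: The 12 parameters subjected to the biomarker-range optimization.
OPTIMIZED_PARAMETER_NAMES: tuple[str, ...] = (
    "V_max_up", "I_rel_max", "RyR_a1", "RyR_a2", "RyR_a_half",
    "RyR_o_half", "RyR_c_half", "I_NaCa_max", "I_NaK_max", "K_up",
    "I_leak_max", "alpha",
)


def _unknown_name_msg(name: str) -> str:
    return (
        f"unknown parameter name {name!r}; valid names: "
        + ", ".join(sorted(_REGISTRY_PATHS))
    )


def apply_block(params: ModelParameters, block: dict[str, float]) -> ModelParameters:
    """Scale maximal conductances by *remaining* fractions.

    ``block`` maps conductance-registry names to the remaining fraction in
    [0, 1]; e.g. ``{"G_Na": 0.18}`` leaves 18% of G_Na (an 82% block).  All
    other parameters are returned untouched.
    """
    updates = {}
    for name, fraction in block.items():
        if name not in CONDUCTANCE_REGISTRY:
            raise KeyError(
                f"unknown conductance {name!r}; valid names: "
                + ", ".join(CONDUCTANCE_REGISTRY)
            )
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"remaining fraction for {name} must be in [0, 1]")
        updates[name] = params.get(name) * fraction
    return params.with_values(**updates)


def make_immature_ryr(params: ModelParameters) -> ModelParameters:
    """Return a variant with a more immature RyR release machinery.

    Shifts the open-gate half-activation by -0.002 and the closed-gate
    half-activation by +0.002 (uM), doubles the open-gate time constant and
    halves the closed-gate time constant.  This lowers the threshold for
    spontaneous diastolic release and slows its shutoff, producing premature
    Ca2+ releases at normal extracellular Ca2+.
    """
    ryr = params.ryr
    return replace(
        params,
        ryr=replace(
            ryr,
            o_half=ryr.o_half - 0.002,
            c_half=ryr.c_half + 0.002,
            tau_o=ryr.tau_o * 2.0,
            tau_c=ryr.tau_c * 0.5,
        ),
    )


# -- serialization -------------------------------------------------------

def _data_dir():
    return importlib.resources.files("hipsccm") / "data"


_SET_FILES = {
    "paci2018-optimized": "paci2018_optimized.yaml",
    "paci2013-baseline": "paci2013_baseline.yaml",
}


def registered_parameter_sets() -> tuple[str, ...]:
    return tuple(_SET_FILES)


def load_parameters(source: str | Path = "paci2018-optimized") -> ModelParameters:
    """Load a parameter set from a registry name or a YAML file.

    A file may be partial: unspecified values overlay the named baseline given
    in its ``base`` key (default ``paci2018-optimized``).
    """
    if isinstance(source, str) and source in _SET_FILES:
        text = (_data_dir() / _SET_FILES[source]).read_text()
        doc = yaml.safe_load(text)
        return _params_from_doc(doc, name=source)
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(
            f"{source!r} is neither a registered set "
            f"({', '.join(_SET_FILES)}) nor an existing file"
        )
    doc = yaml.safe_load(path.read_text())
    return _params_from_doc(doc, name=doc.get("name", path.stem))


def _params_from_doc(doc: dict, name: str) -> ModelParameters:
    base_name = doc.get("base")
    base = load_parameters(base_name) if base_name else ModelParameters()
    values = dict(doc.get("parameters") or {})
    unknown = set(values) - set(_REGISTRY_PATHS)
    if unknown:
        raise KeyError(_unknown_name_msg(sorted(unknown)[0]))
    params = base.with_values(**{k: float(v) for k, v in values.items()})
    return replace(params, name=name)


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write a parameter set as YAML (full, registry-keyed)."""
    values = {name: params.get(name) for name in _REGISTRY_PATHS}
    doc = {"name": params.name, "parameters": values}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def parameters_to_vector(params: ModelParameters) -> np.ndarray:
    """Pack the parameter set into the flat vector consumed by the ODE core."""
    from . import model  # local import to avoid a cycle

    return model.pack_parameters(params)
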