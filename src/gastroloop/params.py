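"""Validated registry of every model constant.

All saturating neuro-effector responses in the model share one functional
form -- a Michaelis-Menten equation with a Hill coefficient (MMEHC):

    P(x) = A * x^N / (B^N + x^N)

where ``A`` is the maximum response, ``B`` the half-saturation constant (in
the units of the input) and ``N`` the Hill coefficient.  The registry holds
one :class:`MMEHCParams` record per neuro-effector modality, the named
gastric/afferent scalar constants, the brainstem interneuron map
coefficients, and the auxiliary constants of the cross-bridge, membrane and
tissue sub-models.

Constants that the primary literature defers to supplementary material or
prior works carry provenance ``"supplementary-reconstructed"`` and default to
the values frozen in :mod:`gastroloop._reconstructed`; everything else is
tagged ``"table1"`` or ``"table2"``.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Any, Dict, Mapping, Optional

import yaml

from ._reconstructed import RECONSTRUCTED

__all__ = [
    "MMEHCParams",
    "ParamEntry",
    "ParameterRegistry",
    "ConfigurationError",
    "ParameterValidationError",
    "load_registry",
    "dump_registry",
    "registry_from_document",
    "load_registry_file",
    "save_registry_file",
    "TABLE1_MODALITIES",
    "TABLE2_SCALARS",
]


class ConfigurationError(KeyError):
    """An override names a parameter that does not exist."""


class ParameterValidationError(ValueError):
    """A parameter value violates its invariant."""


@dataclass(frozen=True)
class MMEHCParams:
    """One saturating response curve A*x^N/(B^N+x^N) for a named modality."""

    A: float
    B: float
    N: float
    modality: str = ""
    unit_A: str = "-"
    unit_B: str = "-"
    provenance: str = "table1"

    def __post_init__(self) -> None:
        for name in ("A", "B", "N"):
            v = getattr(self, name)
            if not (v > 0):
                raise ParameterValidationError(
                    f"MMEHC parameter {name} for modality {self.modality!r} "
                    f"must be positive, got {v!r}"
                )

    def replace(self, **kw: Any) -> "MMEHCParams":
        d = {
            "A": self.A, "B": self.B, "N": self.N, "modality": self.modality,
            "unit_A": self.unit_A, "unit_B": self.unit_B,
            "provenance": self.provenance,
        }
        d.update(kw)
        return MMEHCParams(**d)


@dataclass(frozen=True)
class ParamEntry:
    """A named scalar (or coefficient list) with unit tag and provenance."""

    value: Any
    unit: str
    provenance: str  # "table1" | "table2" | "supplementary-reconstructed"
    positive: bool = False

    def validated(self) -> "ParamEntry":
        if self.positive:
            vals = self.value if isinstance(self.value, (list, tuple)) else [self.value]
            for v in vals:
                if not (v > 0):
                    raise ParameterValidationError(
                        f"parameter must be positive, got {v!r}"
                    )
        return self


def _m(A, B, N, modality, unit_A, unit_B) -> MMEHCParams:
    return MMEHCParams(A=A, B=B, N=N, modality=modality,
                       unit_A=unit_A, unit_B=unit_B, provenance="table1")


# ---------------------------------------------------------------------------
# Neural (MMEHC) constants.  Slash rows of the source table expand to one
# entry per compartment index; the iψ,[VIP],1 spelling maps onto ipsi_to_1.
# ---------------------------------------------------------------------------
def _default_mmehc() -> Dict[str, MMEHCParams]:
    rows = [
        # fundus / PS tonic cholinergic chain
        _m(1031.31, 165.13, 3.07, "Ach_to_1", "uM", "Hz"),
        _m(601.18, 379.05, 2.11, "Ach_to_3", "uM", "Hz"),
        _m(23.30, 4.89e5, 0.34, "Ca_to_1", "uM", "uM"),
        _m(0.71, 126.17, 0.24, "Ca_to_3", "uM", "uM"),
        # fundus NANC chain
        _m(67.37, 19.89, 2.35, "VIP_to_1", "nM", "Hz"),
        _m(1.0, 1.25, 0.82, "ipsi_to_1", "-", "nM"),
        _m(0.68, 18.0, 1.50, "NO_to_1", "uM", "Hz"),
        # PS tonic NANC
        _m(1.0, 1.03, 1.57, "ih_to_3", "-", "Hz"),
        # antrum / PS phasic cholinergic chain
        _m(156.43, 3.54, 3.99, "Ach_p_2", "nM", "Hz"),
        _m(156.43, 3.54, 3.99, "Ach_p_3", "nM", "Hz"),
        _m(0.15, 0.57, 0.33, "ea_p_2", "-", "nM"),
        _m(0.15, 0.57, 0.33, "ea_p_3", "-", "nM"),
        _m(1.3, 96.0, 1.0, "ec_p_2", "-", "nM"),
        _m(1.3, 96.0, 1.0, "ec_p_3", "-", "nM"),
        # antrum / PS phasic NANC chain
        _m(0.67, 43.82, 1.50, "NO_p_2", "uM", "Hz"),
        _m(0.67, 43.82, 1.50, "NO_p_3", "uM", "Hz"),
        _m(0.38, 3.79e-2, 0.75, "ia_p_2", "-", "nM"),
        _m(0.38, 3.79e-2, 0.75, "ia_p_3", "-", "nM"),
        _m(0.12, 3.53, 1.53, "ic_p_2", "-", "nM"),
        _m(0.12, 3.53, 1.53, "ic_p_3", "-", "nM"),
        _m(0.52, 8.76, 1.74, "Pur_p_2", "uM", "Hz"),
        _m(0.52, 8.76, 1.74, "Pur_p_3", "uM", "Hz"),
        _m(167.59, 907.93, 0.84, "ipsi_p_2", "-", "uM"),
        _m(167.59, 907.93, 0.84, "ipsi_p_3", "-", "uM"),
    ]
    return {r.modality: r for r in rows}


TABLE1_MODALITIES = sorted(_default_mmehc().keys())


def _default_scalars() -> Dict[str, ParamEntry]:
    R = RECONSTRUCTED
    t2 = "table2"
    t1 = "table1"
    sr = "supplementary-reconstructed"
    e: Dict[str, ParamEntry] = {}

    def put(key, value, unit, prov, positive=False):
        e[key] = ParamEntry(value, unit, prov, positive).validated()

    # ----- gastric scalars (Table 2) -----
    put("gastric.Ca_rest_1", 0.34, "uM", t2, True)
    put("gastric.Ca_rest_3", 0.18, "uM", t2, True)
    put("gastric.cGMP_max", 26.57, "uM", t2, True)
    put("gastric.K_NO", 21.61, "nM", t2, True)
    put("gastric.MLCP_max_1", 7.5, "uM", t2, True)
    put("gastric.MLCP_max_2", 2.5, "uM", t2, True)
    put("gastric.MLCP_max_3", 2.5, "uM", t2, True)
    put("gastric.MLCP_rest", 7.5, "uM", t2, True)
    put("gastric.N_cGMP", 2.0, "-", t2, True)
    put("gastric.K_cGMP", 5.5, "uM", t2, True)
    put("gastric.beta_1", 20.69, "-", t2, True)
    put("gastric.beta_3", 236.32, "-", t2, True)
    put("gastric.alpha_1", 0.21, "-", t2, True)
    put("gastric.alpha_3", 0.13, "-", t2, True)
    put("gastric.kappa_ini", 48.0, "mA", t2, True)
    put("gastric.cpm_ini", 3.0, "cpm", t2, True)
    put("gastric.G_coup", 1.26, "mA/mV", t2, True)
    put("gastric.o_A", 2098.37, "kPa", t2, True)
    put("gastric.o_B", 72.98, "MPa", t2, True)
    put("gastric.X_bar", 0.149, "-", t2, True)
    put("gastric.o_opt", 0.68, "-", t2, True)
    put("gastric.S3", 4.2, "kPa s", t2, True)
    put("gastric.S4", -0.19, "-", t2)
    put("gastric.S5", 0.04, "1/kPa", t2, True)
    put("gastric.S6", 5.0, "-", t2, True)
    put("gastric.Q_max_flow", 1.67, "cm3/s", t2, True)
    put("gastric.r_max_3", 0.48, "cm", t2, True)

    # ----- afferent constants (Table 1) -----
    put("afferent.X_mech_a", 42.85, "Hz", t1)
    put("afferent.X_mech_b", -42.85, "Hz", t1)
    put("afferent.X_chem_a", 26.39, "Hz s/cm3", t1)
    put("afferent.X_chem_b", -0.79, "Hz", t1)
    put("afferent.Omega", 1.2, "-", t1, True)
    put("afferent.gamma_max", 0.05, "kcal/s", t1, True)
    put("afferent.f_chem_max", 30.0, "Hz", t1, True)

    # ----- brainstem interneuron maps (supplementary) -----
    put("interneuron.f_min_mech", R["f_min_mech"], "Hz", sr, True)
    put("interneuron.f_max_mech", R["f_max_mech"], "Hz", sr, True)
    put("interneuron.f_mid_mech", R["f_mid_mech"], "Hz", sr, True)
    put("interneuron.k_inter_mech", R["k_inter_mech"], "Hz", sr, True)
    put("interneuron.k_inter_chem", list(R["k_inter_chem"]), "Hz^(1-s)", sr)
    put("interneuron.k_vol_h", list(R["k_vol_h"]), "Hz/L^s", sr)
    put("interneuron.k_vol_l", list(R["k_vol_l"]), "Hz/L^s", sr)
    put("interneuron.V_tot_o", R["V_tot_o"], "L", sr, True)

    # ----- auxiliary constants -----
    put("auxiliary.V_gas", 0.21, "L", t2, True)
    put("auxiliary.V_min", 0.08, "L", t2, True)
    put("auxiliary.V_max", 1.2, "L", t2, True)
    for key in ("k_a", "k_b", "k_c", "kcat_MLCK", "km_MLCK", "kcat_MLCP",
                "km_MLCP"):
        put(f"auxiliary.{key}", R[key], "1/s", sr, True)
    put("auxiliary.MLCK_cell", R["MLCK_cell"], "uM", sr, True)
    put("auxiliary.K_CaM", R["K_CaM"], "uM", sr, True)
    put("auxiliary.n_CaM", R["n_CaM"], "-", sr, True)
    put("auxiliary.Ca_base", R["Ca_base"], "uM", sr, True)
    put("auxiliary.Ca_amp", R["Ca_amp"], "uM", sr, True)
    put("auxiliary.V_half_Ca", R["V_half_Ca"], "mV", sr)
    put("auxiliary.k_Ca", R["k_Ca"], "mV", sr, True)
    put("auxiliary.R_ICC", R["R_ICC"], "mV/mA", sr, True)
    put("auxiliary.R_SMC", R["R_SMC"], "mV/mA", sr, True)
    put("auxiliary.tau_m_ICC", R["tau_m_ICC"], "s", sr, True)
    put("auxiliary.tau_m_SMC", R["tau_m_SMC"], "s", sr, True)
    put("auxiliary.Vm_rest_ICC", R["Vm_rest_ICC"], "mV", sr)
    put("auxiliary.Vm_rest_SMC", R["Vm_rest_SMC"], "mV", sr)
    put("auxiliary.t_open_frac_2", R["t_open_frac_2"], "-", sr, True)
    put("auxiliary.t_open_frac_3", R["t_open_frac_3"], "-", sr, True)
    put("auxiliary.window_eps", R["window_eps"], "-", sr, True)
    put("auxiliary.ps_phase_lag", R["ps_phase_lag"], "-", sr)
    put("auxiliary.r_ini_1", R["r_ini_1"], "cm", sr, True)
    put("auxiliary.r_ini_2", R["r_ini_2"], "cm", sr, True)
    put("auxiliary.L_t_2", R["L_t_2"], "cm", sr, True)
    put("auxiliary.r_ini_3", R["r_ini_3"], "cm", sr, True)
    put("auxiliary.b_max_1", R["b_max_1"], "-", sr, True)
    put("auxiliary.b_max_3", R["b_max_3"], "-", sr, True)
    put("auxiliary.f_occ_2", R["f_occ_2"], "-", sr, True)
    put("auxiliary.lam_on_2", R["lam_on_2"], "-", sr, True)
    put("auxiliary.lam_sat_2", R["lam_sat_2"], "-", sr, True)
    put("auxiliary.lam_on_3", R["lam_on_3"], "-", sr, True)
    put("auxiliary.lam_sat_3", R["lam_sat_3"], "-", sr, True)
    put("auxiliary.A_poly", list(R["A_poly"]), "kPa", sr)
    put("auxiliary.eta_floor", R["eta_floor"], "kPa s", sr, True)
    # baseline parasympathetic motor drives not set by an interneuron map
    put("auxiliary.f_e_to_1_base", 0.0, "Hz", sr)
    put("auxiliary.f_i_p_2_base", 0.0, "Hz", sr)
    put("auxiliary.f_e_to_3_base", 0.0, "Hz", sr)
    put("auxiliary.f_e_p_3_base", 0.0, "Hz", sr)
    put("auxiliary.f_i_p_3_base", 0.0, "Hz", sr)
    # sympathetic override motor frequencies
    put("auxiliary.sym_f_i_p_2", 15.0, "Hz", "table1")
    put("auxiliary.sym_f_e_p_2", 0.0, "Hz", "table1")
    put("auxiliary.sym_f_i_to_3", 0.0, "Hz", "table1")
    put("auxiliary.sym_f_e_to_3", 10.0, "Hz", "table1")
    return e


TABLE2_SCALARS = sorted(
    k.split(".", 1)[1] for k, v in _default_scalars().items()
    if v.provenance == "table2" and k.startswith("gastric.")
)


@dataclass
class ParameterRegistry:
    """Complete, validated set of model constants."""

    mmehc: Dict[str, MMEHCParams] = field(default_factory=_default_mmehc)
    scalars: Dict[str, ParamEntry] = field(default_factory=_default_scalars)

    # -- access helpers ----------------------------------------------------
    def get(self, key: str) -> Any:
        """Return the value of a scalar parameter, e.g. ``"gastric.beta_1"``."""
        try:
            return self.scalars[key].value
        except KeyError:
            raise ConfigurationError(f"unknown parameter {key!r}") from None

    def curve(self, modality: str) -> MMEHCParams:
        """Return the MMEHC record for a modality, e.g. ``"Ach_to_1"``."""
        try:
            return self.mmehc[modality]
        except KeyError:
            raise ConfigurationError(f"unknown MMEHC modality {modality!r}") from None

    # -- invariants --------------------------------------------------------
    def validate(self) -> "ParameterRegistry":
        vmin, vmax = self.get("auxiliary.V_min"), self.get("auxiliary.V_max")
        if not (0 < vmin < vmax):
            raise ParameterValidationError(
                f"volume bounds must satisfy 0 < V_min < V_max, got "
                f"({vmin}, {vmax})"
            )
        for entry in self.scalars.values():
            entry.validated()
        return self

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParameterRegistry):
            return NotImplemented
        return self.mmehc == other.mmehc and self.scalars == other.scalars


def load_registry(overrides: Optional[Mapping[str, Any]] = None) -> ParameterRegistry:
    """Build the default registry, optionally overriding named parameters.

    Override keys address either a scalar (``"gastric.Q_max_flow"``) or one
    field of an MMEHC record (``"mmehc.Ach_to_1.N"``).  Unknown keys raise
    :class:`ConfigurationError`; values violating an invariant raise
    :class:`ParameterValidationError`.
    """
    reg = ParameterRegistry()
    for key, value in (overrides or {}).items():
        parts = key.split(".")
        if parts[0] == "mmehc":
            if len(parts) != 3 or parts[2] not in ("A", "B", "N"):
                raise ConfigurationError(
                    f"MMEHC override key must look like 'mmehc.<modality>.<A|B|N>', "
                    f"got {key!r}"
                )
            modality = parts[1]
            if modality not in reg.mmehc:
                raise ConfigurationError(f"unknown MMEHC modality {modality!r}")
            reg.mmehc[modality] = reg.mmehc[modality].replace(**{parts[2]: value})
        else:
            if key not in reg.scalars:
                raise ConfigurationError(f"unknown parameter {key!r}")
            old = reg.scalars[key]
            reg.scalars[key] = ParamEntry(
                value, old.unit, old.provenance, old.positive
            ).validated()
    return reg.validate()


def dump_registry(registry: ParameterRegistry) -> Dict[str, Any]:
    """Serialize a registry to a plain document (dict of dicts).

    Round-trips: ``registry_from_document(dump_registry(r)) == r``.
    """
    doc: Dict[str, Any] = {"mmehc": {}, "scalars": {}}
    for mod, p in sorted(registry.mmehc.items()):
        doc["mmehc"][mod] = {
            "A": {"value": p.A, "unit": p.unit_A},
            "B": {"value": p.B, "unit": p.unit_B},
            "N": {"value": p.N, "unit": "-"},
            "provenance": p.provenance,
        }
    for key, e in sorted(registry.scalars.items()):
        doc["scalars"][key] = {
            "value": copy.deepcopy(e.value),
            "unit": e.unit,
            "provenance": e.provenance,
        }
    return doc


def registry_from_document(doc: Mapping[str, Any]) -> ParameterRegistry:
    """Rebuild a registry from the document produced by :func:`dump_registry`."""
    reg = ParameterRegistry()
    for mod, rec in doc.get("mmehc", {}).items():
        if mod not in reg.mmehc:
            raise ConfigurationError(f"unknown MMEHC modality {mod!r}")
        reg.mmehc[mod] = reg.mmehc[mod].replace(
            A=rec["A"]["value"], B=rec["B"]["value"], N=rec["N"]["value"],
        )
    for key, rec in doc.get("scalars", {}).items():
        if key not in reg.scalars:
            raise ConfigurationError(f"unknown parameter {key!r}")
        old = reg.scalars[key]
        reg.scalars[key] = ParamEntry(
            rec["value"], old.unit, old.provenance, old.positive
        ).validated()
    return reg.validate()


def save_registry_file(registry: ParameterRegistry, path: str) -> None:
    doc = dump_registry(registry)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(doc, fh, indent=1)
        else:
            yaml.safe_dump(doc, fh, sort_keys=True)


def load_registry_file(path: str) -> ParameterRegistry:
    with open(path) as fh:
        doc = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    return registry_from_document(doc)
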