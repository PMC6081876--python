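"""Physiological parameter sets and chemical partitioning.

The toxicokinetic models in this package describe an adult zebrafish either as
a single well-mixed compartment or as seven interconnected compartments
(arterial blood, venous blood, brain, gonads, richly perfused tissue, poorly
perfused tissue, liver).  Everything chemical-specific enters through a single
number, the octanol--water partition ratio ``log10 Kow``: the blood--water
partition ratio follows the log-linear regression

    log10 P_bw = 0.78 * log10 Kow - 0.82

and tissue--blood partition ratios follow the standard lipid-fraction closure

    P_tw = L_t * Kow + W_t,      P_tb = P_tw / P_bw

where ``L_t`` and ``W_t`` are the tissue lipid and water volume fractions.

Masses are converted to volumes at unit tissue density (1 g == 1000 uL); BCF
is a concentration ratio, so only relative volumes matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import yaml

from .exceptions import InvalidInputError, SchemaError

__all__ = [
    "TISSUES",
    "BODY_PARAMETERS",
    "GRAMS_TO_MICROLITERS",
    "PBW_SLOPE",
    "PBW_INTERCEPT",
    "Chemical",
    "BCFRecord",
    "Physiology1C",
    "Physiology7C",
    "PartitionSet",
    "blood_water_partition",
    "tissue_blood_partition",
    "partition_set",
    "load_physiology_7c",
    "load_physiology_1c",
    "default_physiology_7c",
    "default_physiology_1c",
    "get_parameter",
    "with_parameter",
]

#: Perfused tissue compartments of the 7C model (blood is handled separately).
TISSUES = ("brain", "gonads", "rpt", "ppt", "liver")

#: Unit-density mass -> volume conversion.
GRAMS_TO_MICROLITERS = 1000.0

#: Coefficients of the blood--water partition regression on log10 Kow.
PBW_SLOPE = 0.78
PBW_INTERCEPT = -0.82

_ABBREV = {
    "bld": "blood",
    "brn": "brain",
    "gon": "gonads",
    "rpt": "rpt",
    "ppt": "ppt",
    "liv": "liver",
}

#: Scalar body parameters of the 7C model, i.e. everything except the
#: source (F_gill) and sink (k_m) rates.  These are the parameters varied by
#: the all-parameter swarm optimisation and the uncertainty analysis.
BODY_PARAMETERS = (
    ("f_car",)
    + tuple(f"f_{a}" for a in ("brn", "gon", "rpt", "ppt", "liv"))
    + ("m_tot",)
    + tuple(f"m_{a}" for a in ("bld", "brn", "gon", "rpt", "ppt", "liv"))
    + tuple(f"L_{a}" for a in ("brn", "gon", "rpt", "ppt", "liv"))
    + tuple(f"W_{a}" for a in ("brn", "gon", "rpt", "ppt", "liv"))
)


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise InvalidInputError(f"{name} must be finite, got {value!r}")
    return value


def _require_positive(name: str, value: float) -> float:
    value = _require_finite(name, value)
    if value <= 0.0:
        raise InvalidInputError(f"{name} must be strictly positive, got {value!r}")
    return value


@dataclass(frozen=True)
class Chemical:
    """A chemical identified solely by its octanol--water partition ratio."""

    name: str
    log10_kow: float

    def __post_init__(self) -> None:
        if not self.name:
            raise InvalidInputError("Chemical name must be nonempty")
        _require_finite("log10_kow", self.log10_kow)


@dataclass(frozen=True)
class BCFRecord:
    """One observed bioconcentration factor measurement."""

    chemical: Chemical
    log10_bcf_observed: float
    species: str = "Danio rerio"
    life_stage: str = "adult"
    source: str = ""

    def __post_init__(self) -> None:
        _require_finite("log10_bcf_observed", self.log10_bcf_observed)
        if self.life_stage not in ("adult", "embryo"):
            raise InvalidInputError(
                f"life_stage must be 'adult' or 'embryo', got {self.life_stage!r}"
            )


@dataclass(frozen=True)
class Physiology1C:
    """Parameters of the single-compartment model.

    Attributes
    ----------
    F_gill : float
        Countercurrent water-flow rate between gill lamellae, uL/s.
    k_m : float
        First-order metabolic decomposition rate, 1/s.
    V_t : float
        Total body volume, uL.
    L_body, W_body : float
        Whole-body lipid and water volume fractions.
    """

    F_gill: float
    k_m: float
    V_t: float
    L_body: float
    W_body: float

    def __post_init__(self) -> None:
        _require_finite("F_gill", self.F_gill)
        if self.F_gill < 0:
            raise InvalidInputError("F_gill must be non-negative")
        k_m = _require_finite("k_m", self.k_m)
        if k_m < 0:
            raise InvalidInputError("k_m must be >= 0")
        _require_positive("V_t", self.V_t)
        _require_positive("L_body", self.L_body)
        _require_positive("W_body", self.W_body)
        if self.L_body + self.W_body > 1.0 + 1e-12:
            raise InvalidInputError("L_body + W_body must not exceed 1")

    def replace(self, **kwargs) -> "Physiology1C":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Physiology7C:
    """Parameters of the seven-compartment model.

    Flow fractions must sum to exactly 1 (within 1e-9): blood leaving the
    arterial pool is conserved.  Mass fractions may sum to less than 1 (the
    remainder is structural mass outside the modelled compartments).
    """

    F_gill: float
    k_m: float
    f_car: float
    flow_fractions: Mapping[str, float]
    m_tot: float
    mass_fractions: Mapping[str, float]
    lipid_content: Mapping[str, float]
    water_content: Mapping[str, float]
    arterial_blood_share: float = 1.0 / 3.0
    label: str = ""

    def __post_init__(self) -> None:
        _require_finite("F_gill", self.F_gill)
        if self.F_gill < 0:
            raise InvalidInputError("F_gill must be non-negative")
        if _require_finite("k_m", self.k_m) < 0:
            raise InvalidInputError("k_m must be >= 0")
        _require_positive("f_car", self.f_car)
        _require_positive("m_tot", self.m_tot)
        share = _require_positive("arterial_blood_share", self.arterial_blood_share)
        if share >= 1.0:
            raise InvalidInputError("arterial_blood_share must be in (0, 1)")

        object.__setattr__(self, "flow_fractions", dict(self.flow_fractions))
        object.__setattr__(self, "mass_fractions", dict(self.mass_fractions))
        object.__setattr__(self, "lipid_content", dict(self.lipid_content))
        object.__setattr__(self, "water_content", dict(self.water_content))

        if set(self.flow_fractions) != set(TISSUES):
            raise InvalidInputError(
                f"flow_fractions must have keys {TISSUES}, got {sorted(self.flow_fractions)}"
            )
        if set(self.mass_fractions) != set(TISSUES) | {"blood"}:
            raise InvalidInputError(
                "mass_fractions must have keys blood + " f"{TISSUES}"
            )
        for m in (self.lipid_content, self.water_content):
            if set(m) != set(TISSUES):
                raise InvalidInputError(f"tissue content maps must have keys {TISSUES}")

        for name, m in (
            ("flow_fractions", self.flow_fractions),
            ("mass_fractions", self.mass_fractions),
            ("lipid_content", self.lipid_content),
            ("water_content", self.water_content),
        ):
            for key, value in m.items():
                _require_positive(f"{name}[{key}]", value)

        flow_sum = sum(self.flow_fractions.values())
        if abs(flow_sum - 1.0) > 1e-9:
            raise InvalidInputError(
                f"flow_fractions must sum to 1 within 1e-9, got {flow_sum!r}; "
                "configs are rejected rather than renormalised"
            )
        if sum(self.mass_fractions.values()) > 1.0 + 1e-9:
            raise InvalidInputError("mass_fractions must sum to <= 1")
        for t in TISSUES:
            if self.lipid_content[t] + self.water_content[t] > 1.0 + 1e-12:
                raise InvalidInputError(
                    f"lipid + water content of {t} exceeds 1"
                )

    # -- derived geometry ---------------------------------------------------

    @property
    def V_blood(self) -> float:
        """Total blood volume, uL."""
        return self.m_tot * self.mass_fractions["blood"] * GRAMS_TO_MICROLITERS

    @property
    def V_art(self) -> float:
        """Arterial blood volume, uL."""
        return self.V_blood * self.arterial_blood_share

    @property
    def V_ven(self) -> float:
        """Venous blood volume, uL."""
        return self.V_blood * (1.0 - self.arterial_blood_share)

    def tissue_volume(self, tissue: str) -> float:
        return self.m_tot * self.mass_fractions[tissue] * GRAMS_TO_MICROLITERS

    @property
    def volumes(self) -> dict:
        """Volumes (uL) of all seven compartments."""
        v = {"arterial": self.V_art, "venous": self.V_ven}
        v.update({t: self.tissue_volume(t) for t in TISSUES})
        return v

    @property
    def V_total(self) -> float:
        """Summed volume of the seven compartments, uL."""
        return self.V_blood + sum(self.tissue_volume(t) for t in TISSUES)

    def tissue_flow(self, tissue: str) -> float:
        """Blood flow through a tissue, Q_i = f_i * f_car (uL/s)."""
        return self.flow_fractions[tissue] * self.f_car

    def replace(self, **kwargs) -> "Physiology7C":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PartitionSet:
    """Chemical-dependent partition ratios for one chemical."""

    P_bw: float
    P_tb: Mapping[str, float]
    alpha: float = 1.0

    def __post_init__(self) -> None:
        _require_positive("P_bw", self.P_bw)
        object.__setattr__(self, "P_tb", dict(self.P_tb))
        for t, p in self.P_tb.items():
            _require_positive(f"P_tb[{t}]", p)
        a = _require_finite("alpha", self.alpha)
        if not 0.0 < a <= 1.0:
            raise InvalidInputError(f"alpha must be in (0, 1], got {a!r}")


# -- partitioning operations ------------------------------------------------


def blood_water_partition(log10_kow: float):
    """Blood--water partition ratio from the log-linear Kow regression.

    ``P_bw = 10 ** (0.78 * log10_kow - 0.82)``.  The ratio crosses 1 at
    ``log10 Kow = 0.82 / 0.78 = 1.05``: more hydrophilic chemicals partition
    preferentially into water.
    """
    arr = np.asarray(log10_kow, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("log10_kow must be finite")
    out = 10.0 ** (PBW_SLOPE * arr + PBW_INTERCEPT)
    return float(out) if np.isscalar(log10_kow) or arr.ndim == 0 else out


def tissue_blood_partition(log10_kow: float, lipid: float, water: float, p_bw: float):
    """Tissue--blood partition ratio from lipid/water content.

    ``P_tb = (lipid * Kow + water) / P_bw`` -- the tissue--water ratio of the
    lipid-fraction model, referred to blood.
    """
    if np.any(np.asarray(lipid) < 0) or np.any(np.asarray(water) < 0):
        raise InvalidInputError("lipid and water fractions must be >= 0")
    if np.any(np.asarray(lipid) + np.asarray(water) > 1.0 + 1e-12):
        raise InvalidInputError("lipid + water must not exceed 1")
    if np.any(np.asarray(p_bw) == 0):
        raise InvalidInputError("P_bw must be nonzero")
    kow = 10.0 ** np.asarray(log10_kow, dtype=float)
    out = (np.asarray(lipid) * kow + np.asarray(water)) / np.asarray(p_bw)
    return float(out) if np.ndim(out) == 0 else out


#: Signature of a Kow-dependent assimilation-efficiency rule.
AlphaRule = Callable[[float], float]


def partition_set(
    chemical: Chemical,
    physiology: Physiology7C,
    alpha_rule: AlphaRule | None = None,
) -> PartitionSet:
    """Bundle P_bw, the five tissue P_tb values and alpha for one chemical.

    ``alpha_rule`` maps log10 Kow to an assimilation efficiency in (0, 1];
    the default is the constant 1 (any multiplicative constant is absorbed
    into the calibrated F_gill).
    """
    p_bw = blood_water_partition(chemical.log10_kow)
    p_tb = {
        t: tissue_blood_partition(
            chemical.log10_kow,
            physiology.lipid_content[t],
            physiology.water_content[t],
            p_bw,
        )
        for t in TISSUES
    }
    alpha = 1.0 if alpha_rule is None else float(alpha_rule(chemical.log10_kow))
    return PartitionSet(P_bw=p_bw, P_tb=p_tb, alpha=alpha)


# -- configuration files ----------------------------------------------------

_DATA_DIR = Path(__file__).parent / "data"


def _load_yaml(path: Path) -> dict:
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    except FileNotFoundError:
        raise SchemaError(f"physiology config not found: {path}") from None
    if not isinstance(doc, dict):
        raise SchemaError(f"physiology config {path} is not a mapping")
    return doc


def load_physiology_7c(path: str | Path | None = None) -> Physiology7C:
    """Load a 7C parameter set from YAML (default: shipped adult zebrafish)."""
    path = Path(path) if path is not None else _DATA_DIR / "zebrafish_adult_7c.yaml"
    doc = _load_yaml(path)
    required = {
        "F_gill", "k_m", "f_car", "flow_fractions", "m_tot",
        "mass_fractions", "lipid_content", "water_content",
    }
    missing = required - set(doc)
    if missing:
        raise SchemaError(f"physiology config {path} missing keys: {sorted(missing)}")
    try:
        return Physiology7C(
            F_gill=doc["F_gill"],
            k_m=doc["k_m"],
            f_car=doc["f_car"],
            flow_fractions=doc["flow_fractions"],
            m_tot=doc["m_tot"],
            mass_fractions=doc["mass_fractions"],
            lipid_content=doc["lipid_content"],
            water_content=doc["water_content"],
            arterial_blood_share=doc.get("arterial_blood_share", 1.0 / 3.0),
            label=doc.get("name", path.stem),
        )
    except (TypeError, KeyError) as exc:
        raise SchemaError(f"malformed physiology config {path}: {exc}") from exc


def load_physiology_1c(path: str | Path | None = None) -> Physiology1C:
    """Load a 1C parameter set from YAML (default: shipped adult zebrafish)."""
    path = Path(path) if path is not None else _DATA_DIR / "zebrafish_adult_1c.yaml"
    doc = _load_yaml(path)
    missing = {"F_gill", "k_m", "V_t", "L_body", "W_body"} - set(doc)
    if missing:
        raise SchemaError(f"physiology config {path} missing keys: {sorted(missing)}")
    return Physiology1C(
        F_gill=doc["F_gill"], k_m=doc["k_m"], V_t=doc["V_t"],
        L_body=doc["L_body"], W_body=doc["W_body"],
    )


def default_physiology_7c() -> Physiology7C:
    """The literature-derived adult zebrafish 7C parameter set."""
    return load_physiology_7c()


def default_physiology_1c() -> Physiology1C:
    """The literature-derived adult zebrafish 1C parameter set."""
    return load_physiology_1c()


# -- scalar parameter access for optimisation / uncertainty -----------------


def _split_param(name: str):
    if name in ("f_car", "m_tot"):
        return name, None
    prefix, _, abbrev = name.partition("_")
    if abbrev not in _ABBREV:
        raise InvalidInputError(f"unknown body parameter {name!r}")
    compartment = _ABBREV[abbrev]
    if prefix == "f":
        if compartment == "blood":
            raise InvalidInputError("blood has no flow fraction")
        return "flow_fractions", compartment
    if prefix == "m":
        return "mass_fractions", compartment
    if prefix == "L":
        return "lipid_content", compartment
    if prefix == "W":
        return "water_content", compartment
    raise InvalidInputError(f"unknown body parameter {name!r}")


def get_parameter(physiology: Physiology7C, name: str) -> float:
    """Read a scalar body parameter (e.g. ``"f_brn"``, ``"L_liv"``) by name."""
    attr, key = _split_param(name)
    value = getattr(physiology, attr)
    return value if key is None else value[key]


def with_parameter(
    physiology: Physiology7C,
    name: str,
    value: float,
    renormalize_flows: bool = True,
) -> Physiology7C:
    """Return a copy with one scalar body parameter replaced.

    Flow fractions must sum to 1; perturbing a single fraction therefore
    renormalises the whole set (keeping relative magnitudes) unless
    ``renormalize_flows`` is disabled, in which case validation will reject
    the result.
    """
    attr, key = _split_param(name)
    if key is None:
        return physiology.replace(**{attr: value})
    mapping = dict(getattr(physiology, attr))
    mapping[key] = value
    if attr == "flow_fractions" and renormalize_flows:
        total = sum(mapping.values())
        mapping = {k: v / total for k, v in mapping.items()}
    return physiology.replace(**{attr: mapping})
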