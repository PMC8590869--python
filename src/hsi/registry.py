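"""Registry of the physiological variables the model may consume.

Each variable carries a class (vital / lab / vent / demographic / derived),
a forward-fill staleness limit in hours, an imputation policy for when no
sufficiently fresh measurement exists, and a plausible range used for
clipping. The default registry holds 33 variables and can be overridden
from a YAML file with the same schema.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import yaml

#: imputation policies
IMPUTE_POPULATION_MEAN = "population_mean"
IMPUTE_CONSTANT = "constant"
IMPUTE_LEAVE_ABSENT = "leave_absent"

VARIABLE_CLASSES = ("vital", "lab", "vent", "demographic", "derived")

OPERATING_MODES = ("basic", "basic+labs", "basic+ventilation", "all")

#: variables every valid feature vector must carry as measured/forward-filled
REQUIRED_VARIABLES = ("heart_rate", "systolic_bp")

_BASIC_MODE = ("heart_rate", "systolic_bp", "diastolic_bp", "mean_bp",
               "shock_index", "age")
_VENT_VARS = ("fio2", "mawp", "pip")


@dataclass(frozen=True)
class VariableSpec:
    """Static description of one model input variable."""

    name: str
    var_class: str
    fill_limit: float  # hours; math.inf means never expires
    impute: str
    impute_value: float | None = None  # only for constant policy
    low: float = -math.inf
    high: float = math.inf

    def __post_init__(self) -> None:
        if self.var_class not in VARIABLE_CLASSES:
            raise ValueError(f"unknown variable class {self.var_class!r}")
        if self.fill_limit <= 0:
            raise ValueError("fill_limit must be positive")
        if self.impute not in (IMPUTE_POPULATION_MEAN, IMPUTE_CONSTANT,
                               IMPUTE_LEAVE_ABSENT):
            raise ValueError(f"unknown impute policy {self.impute!r}")
        if self.impute == IMPUTE_CONSTANT and self.impute_value is None:
            raise ValueError("constant imputation requires impute_value")


_VITAL_FILL = 2.0
_LAB_FILL = 26.0

# (name, class, fill limit, impute, impute_value, low, high)
_DEFAULT_TABLE = [
    ("heart_rate", "vital", _VITAL_FILL, IMPUTE_POPULATION_MEAN, None, 10, 300),
    ("systolic_bp", "vital", _VITAL_FILL, IMPUTE_POPULATION_MEAN, None, 20, 300),
    ("diastolic_bp", "vital", _VITAL_FILL, IMPUTE_POPULATION_MEAN, None, 10, 200),
    ("mean_bp", "vital", _VITAL_FILL, IMPUTE_POPULATION_MEAN, None, 15, 250),
    ("respiratory_rate", "vital", _VITAL_FILL, IMPUTE_POPULATION_MEAN, None, 0, 80),
    ("spo2", "vital", _VITAL_FILL, IMPUTE_POPULATION_MEAN, None, 40, 100),
    ("temperature", "vital", _VITAL_FILL, IMPUTE_POPULATION_MEAN, None, 25, 45),
    ("hematocrit", "lab", _LAB_FILL, IMPUTE_POPULATION_MEAN, None, 5, 70),
    ("hemoglobin", "lab", _LAB_FILL, IMPUTE_POPULATION_MEAN, None, 2, 25),
    ("wbc", "lab", _LAB_FILL, IMPUTE_POPULATION_MEAN, None, 0.1, 100),
    ("platelets", "lab", _LAB_FILL, IMPUTE_POPULATION_MEAN, None, 1, 2000),
    ("sodium", "lab", _LAB_FILL, IMPUTE_POPULATION_MEAN, None, 100, 180),
    ("potassium", "lab", _LAB_FILL, IMPUTE_POPULATION_MEAN, None, 1, 12),
    ("chloride", "lab", _LAB_FILL, IMPUTE_POPULATION_MEAN, None, 60, 150),
    ("bicarbonate", "lab", _LAB_FILL, IMPUTE_POPULATION_MEAN, None, 2, 60),
    ("bun", "lab", _LAB_FILL, IMPUTE_POPULATION_MEAN, None, 1, 250),
    ("creatinine", "lab", _LAB_FILL, IMPUTE_POPULATION_MEAN, None, 0.1, 30),
    ("glucose", "lab", _LAB_FILL, IMPUTE_POPULATION_MEAN, None, 10, 1500),
    ("lactate", "lab", _LAB_FILL, IMPUTE_POPULATION_MEAN, None, 0.1, 30),
    ("albumin", "lab", _LAB_FILL, IMPUTE_POPULATION_MEAN, None, 0.5, 7),
    ("total_bilirubin", "lab", _LAB_FILL, IMPUTE_POPULATION_MEAN, None, 0.05, 60),
    ("calcium", "lab", _LAB_FILL, IMPUTE_POPULATION_MEAN, None, 3, 20),
    ("magnesium", "lab", _LAB_FILL, IMPUTE_POPULATION_MEAN, None, 0.3, 10),
    ("inr", "lab", _LAB_FILL, IMPUTE_POPULATION_MEAN, None, 0.5, 20),
    ("ph", "lab", _LAB_FILL, IMPUTE_POPULATION_MEAN, None, 6.5, 8.0),
    ("pao2", "lab", _LAB_FILL, IMPUTE_POPULATION_MEAN, None, 20, 700),
    ("paco2", "lab", _LAB_FILL, IMPUTE_POPULATION_MEAN, None, 5, 200),
    ("base_excess", "lab", _LAB_FILL, IMPUTE_POPULATION_MEAN, None, -40, 40),
    ("fio2", "vent", _LAB_FILL, IMPUTE_CONSTANT, 0.21, 0.21, 1.0),
    ("mawp", "vent", _LAB_FILL, IMPUTE_LEAVE_ABSENT, None, 0, 60),
    ("pip", "vent", _LAB_FILL, IMPUTE_LEAVE_ABSENT, None, 0, 100),
    ("age", "demographic", math.inf, IMPUTE_POPULATION_MEAN, None, 0, 130),
    ("shock_index", "derived", _VITAL_FILL, IMPUTE_POPULATION_MEAN, None, 0.05, 10),
]


@dataclass
class Registry:
    """Ordered collection of :class:`VariableSpec` plus mode definitions."""

    specs: list[VariableSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for spec in self.specs:
            if spec.name in seen:
                raise ValueError(f"duplicate variable {spec.name!r}")
            seen.add(spec.name)
        for req in REQUIRED_VARIABLES:
            if req not in seen:
                raise ValueError(f"registry must include {req!r}")
        self._by_name = {s.name: s for s in self.specs}

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __len__(self) -> int:
        return len(self.specs)

    def __getitem__(self, name: str) -> VariableSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown variable {name!r}") from None

    def names_of_class(self, var_class: str) -> list[str]:
        return [s.name for s in self.specs if s.var_class == var_class]

    def mode_variables(self, mode: str) -> set[str]:
        """Variables observable under an operating mode.

        Variables outside the mode are treated as never measured and fall
        back to their imputation policy at snapshot time.
        """
        if mode not in OPERATING_MODES:
            raise ValueError(
                f"unknown operating mode {mode!r}; expected one of {OPERATING_MODES}")
        if mode == "all":
            return set(self.names)
        basic = {n for n in _BASIC_MODE if n in self._by_name}
        if mode == "basic":
            return basic
        if mode == "basic+labs":
            return basic | set(self.names_of_class("lab"))
        return basic | {n for n in _VENT_VARS if n in self._by_name}

    def content_hash(self) -> str:
        """Stable hash of the registry definition, stored in saved models."""
        lines = [
            f"{s.name}|{s.var_class}|{s.fill_limit!r}|{s.impute}|{s.impute_value!r}"
            for s in self.specs
        ]
        return hashlib.sha256("\n".join(lines).encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        doc = [
            {
                "name": s.name,
                "class": s.var_class,
                "fill_limit": None if math.isinf(s.fill_limit) else s.fill_limit,
                "impute": s.impute,
                "impute_value": s.impute_value,
                "low": None if math.isinf(s.low) else s.low,
                "high": None if math.isinf(s.high) else s.high,
            }
            for s in self.specs
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Registry":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        specs = []
        for entry in doc:
            specs.append(VariableSpec(
                name=entry["name"],
                var_class=entry["class"],
                fill_limit=math.inf if entry.get("fill_limit") is None
                else float(entry["fill_limit"]),
                impute=entry["impute"],
                impute_value=entry.get("impute_value"),
                low=-math.inf if entry.get("low") is None else float(entry["low"]),
                high=math.inf if entry.get("high") is None else float(entry["high"]),
            ))
        return cls(specs)


def default_registry() -> Registry:
    """The built-in 33-variable registry."""
    return Registry([VariableSpec(*row) for row in _DEFAULT_TABLE])
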