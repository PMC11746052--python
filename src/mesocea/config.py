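"""Study configuration: schema, validation, and the sensitivity deck.

A study config mirrors the published input tables: survival model
parameters per arm, per-cycle drug and monitoring prices, utilities,
adverse-event incidences/costs/disutilities, the discount rate and the
willingness-to-pay threshold.  Three population-specific configs (whole,
non-epithelioid, epithelioid) ship with the package.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .distributions import ParametricModel, median_survival
from .engine import (
    AEItem,
    ArmConfig,
    DrugCost,
    EngineSettings,
    MonitoringCosts,
    SubsequentTreatment,
    UtilitySet,
)

__all__ = [
    "StudyConfig",
    "ParamSpec",
    "load_config",
    "builtin_config_path",
    "param_specs",
    "POPULATIONS",
]

logger = logging.getLogger(__name__)

POPULATIONS = ("whole", "non_epithelioid", "epithelioid")

_REQUIRED_TOP = {"population", "wtp", "discount_rate", "utilities", "costs", "adverse_events", "arms"}


@dataclass(frozen=True)
class ParamSpec:
    """One sensitivity parameter: baseline, range and PSA distribution."""

    name: str
    baseline: float
    low: float
    high: float
    psa_family: str  # beta | gamma | fixed

    def __post_init__(self) -> None:
        if not self.low <= self.baseline <= self.high:
            raise ValueError(f"{self.name}: range must bracket the baseline")
        if self.psa_family not in ("beta", "gamma", "fixed"):
            raise ValueError(f"{self.name}: unknown psa_family {self.psa_family}")
        if self.psa_family == "beta" and not (0 <= self.low and self.high <= 1):
            raise ValueError(f"{self.name}: beta requires a range within [0, 1]")


class StudyConfig:
    """Validated study configuration with engine-object construction."""

    def __init__(self, raw: dict):
        self.raw = raw
        self._validate()

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        missing = _REQUIRED_TOP - set(self.raw)
        if missing:
            raise ValueError(f"config missing required keys: {sorted(missing)}")
        arms = self.raw["arms"]
        if not isinstance(arms, dict) or len(arms) != 2:
            raise ValueError("config must define exactly two arms under 'arms'")
        u = self.raw["utilities"]
        if not 0 <= u["pd"] <= u["pfs"] <= 1:
            raise ValueError("utilities must satisfy 0 <= pd <= pfs <= 1")
        for name, value in self.raw["costs"].items():
            if value < 0:
                raise ValueError(f"cost '{name}' must be non-negative")
        for arm_name, arm in arms.items():
            for key in ("os_model", "pfs_model", "drugs", "subsequent"):
                if key not in arm:
                    raise ValueError(f"arm '{arm_name}' missing '{key}'")
            model = _build_model(arm["os_model"])
            med = median_survival(model)
            if not 5.0 <= med <= 40.0:
                logger.warning(
                    "arm %s: implied median OS %.1f months is outside the "
                    "plausible 5-40 month window; check parameterization",
                    arm_name,
                    med,
                )
        for ae_name, ae in self.raw["adverse_events"].items():
            for arm_name in arms:
                if arm_name not in ae["incidence"]:
                    raise ValueError(f"adverse event '{ae_name}' missing incidence for '{arm_name}'")

    # -- accessors ---------------------------------------------------------

    @property
    def population(self) -> str:
        return self.raw["population"]

    @property
    def wtp(self) -> float:
        return float(self.raw["wtp"])

    @property
    def arm_names(self) -> tuple[str, str]:
        names = list(self.raw["arms"])
        # intervention listed first by convention
        return names[0], names[1]

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    def config_hash(self) -> str:
        payload = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    # -- construction ------------------------------------------------------

    def settings(self, overrides: dict | None = None) -> EngineSettings:
        ov = overrides or {}
        return EngineSettings(
            horizon_years=float(self.raw.get("horizon_years", 10.0)),
            cycle_days=float(self.raw.get("cycle_days", 21.0)),
            discount_rate=float(ov.get("discount_rate", self.raw["discount_rate"])),
            curve_basis=self.raw.get("curve_basis", "cycle_months"),
            half_cycle=bool(self.raw.get("half_cycle", False)),
        )

    def utilities(self, overrides: dict | None = None) -> UtilitySet:
        ov = overrides or {}
        u = self.raw["utilities"]
        return UtilitySet(
            pfs=float(ov.get("utility_pfs", u["pfs"])),
            pd=float(ov.get("utility_pd", u["pd"])),
        )

    def arm(self, name: str, overrides: dict | None = None) -> ArmConfig:
        ov = overrides or {}
        raw_arm = self.raw["arms"][name]
        costs = self.raw["costs"]

        def cost_of(item: str) -> float:
            return float(ov.get(f"cost_{item}", costs[item]))

        drugs = tuple(
            DrugCost(d["name"], cost_of(d["name"]), int(d["paid_cycles"]))
            for d in raw_arm["drugs"]
        )
        sub_raw = raw_arm["subsequent"]
        sub = SubsequentTreatment(
            name=sub_raw["name"],
            cost_per_cycle=sum(cost_of(c) for c in sub_raw["components"]),
            n_cycles=float(sub_raw["n_cycles"]),
            mode=sub_raw.get("mode", "one_time"),
        )
        ae_profile = tuple(
            AEItem(
                name=ae_name,
                incidence=float(ov.get(f"incidence_{name}_{ae_name}", ae["incidence"][name])),
                cost_per_event=float(ov.get(f"cost_ae_{ae_name}", ae["cost"])),
                disutility=float(ov.get(f"disutility_ae_{ae_name}", ae["disutility"])),
            )
            for ae_name, ae in self.raw["adverse_events"].items()
        )
        monitoring = MonitoringCosts(
            laboratory_per_cycle=cost_of("laboratory"),
            ct_cost=cost_of("ct"),
        )
        return ArmConfig(
            name=name,
            os_model=_build_model(raw_arm["os_model"]),
            pfs_model=_build_model(raw_arm["pfs_model"]),
            drugs=drugs,
            subsequent=sub,
            ae_profile=ae_profile,
            monitoring=monitoring,
            chemo_cycles=int(raw_arm.get("chemo_cycles", 6)),
            antibody_cycles=int(raw_arm.get("antibody_cycles", 0)),
            admin_chemo_phase=cost_of("premedication") + cost_of("infusion"),
            admin_antibody_phase=cost_of("secondary_premedication"),
            end_of_life_cost=cost_of("end_of_life"),
        )

    def arms(self, overrides: dict | None = None) -> tuple[ArmConfig, ArmConfig]:
        a1, a0 = self.arm_names
        return self.arm(a1, overrides), self.arm(a0, overrides)

    def copy(self) -> "StudyConfig":
        return StudyConfig(copy.deepcopy(self.raw))


def _build_model(raw: dict) -> ParametricModel:
    return ParametricModel(raw["family"], {k: float(v) for k, v in raw["params"].items()})


def load_config(path) -> StudyConfig:
    """Load and validate a YAML study config."""
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    return StudyConfig(raw)


def builtin_config_path(population: str) -> Path:
    """Path to a shipped population config: whole | non_epithelioid | epithelioid."""
    if population not in POPULATIONS:
        raise ValueError(f"unknown population {population!r}; expected one of {POPULATIONS}")
    return Path(str(resources.files("mesocea").joinpath(f"data/{population}.yaml")))


# ---------------------------------------------------------------------------
# sensitivity deck

RANGE_FRACTION = 0.20  # default parameter variation around the baseline


def param_specs(cfg: StudyConfig) -> list[ParamSpec]:
    """The one-way/probabilistic sensitivity deck for a config.

    Every cost parameter is a gamma variable and every utility-scale or
    probability parameter a beta variable, varied over +/-20% of baseline
    unless the config's ``ranges`` section records a printed range.
    Survival-model parameters are deliberately not part of the deck (no
    ranges or distributions are published for them), and the discount rate
    is treated as a methodological scenario setting rather than a sampled
    quantity -- override ``discount_rate`` in the config to explore it.
    """
    ranges: dict = cfg.raw.get("ranges", {})
    specs: list[ParamSpec] = []

    def add(name: str, baseline: float, family: str) -> None:
        if name in ranges:
            low, high = (float(x) for x in ranges[name])
        else:
            low = baseline * (1 - RANGE_FRACTION)
            high = baseline * (1 + RANGE_FRACTION)
        if family == "beta":
            low, high = max(low, 0.0), min(high, 1.0)
        specs.append(ParamSpec(name, baseline, low, high, family))

    for item, value in cfg.raw["costs"].items():
        add(f"cost_{item}", float(value), "gamma")
    add("utility_pfs", float(cfg.raw["utilities"]["pfs"]), "beta")
    add("utility_pd", float(cfg.raw["utilities"]["pd"]), "beta")
    for ae_name, ae in cfg.raw["adverse_events"].items():
        add(f"cost_ae_{ae_name}", float(ae["cost"]), "gamma")
        add(f"disutility_ae_{ae_name}", float(ae["disutility"]), "beta")
        for arm_name in cfg.raw["arms"]:
            add(f"incidence_{arm_name}_{ae_name}", float(ae["incidence"][arm_name]), "beta")
    return specs
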