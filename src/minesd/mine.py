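"""The five-subsystem coal-mining-area model.

A coal mining area is modelled as five mutually independent pollution
subsystems — atmospheric, solid waste, water resource, vegetation cover and
land reclamation — each a single stock (pollution area, destroyed vegetation,
damaged land) fed by constant monthly production and drained by a treatment
flow.  A fixed monthly environmental-investment budget ``E`` (ten thousand
yuan) is split among the subsystems by an :class:`AllocationPolicy` of five
proportions; the treatment "technical factor" of a subsystem is its
investment share divided by the total budget, which algebraically reduces to
the bare proportion.

With the default (stock-proportional) treatment basis every subsystem is a
linear stock

    X(t+1) = X(t) + P - p * X(t)

with constant production ``P`` and removal fraction ``p``, so trajectories
saturate towards the equilibrium ``P / p``.

Environmental quality is scored per subsystem against the zero-investment
baseline, ``q_i(t) = (B_i(t) - S_i(t)) / B_i(t)``, and aggregated as the
arithmetic mean of the five subsystem scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from pydantic import AliasChoices, BaseModel, ConfigDict, Field, field_validator, model_validator

from .engine import (
    AuxiliaryDef,
    ConstantDef,
    ModelSpec,
    ModelValidationError,
    RateDef,
    SimConfig,
    StockDef,
    Trajectory,
    simulate,
    validate_model,
)

__all__ = [
    "SUBSYSTEMS",
    "SUBSYSTEM_STOCKS",
    "AllocationPolicy",
    "MineParams",
    "MineModelConfig",
    "QualitySeries",
    "ZERO_POLICY",
    "technical_factor",
    "build_air_subsystem",
    "build_solid_subsystem",
    "build_water_subsystem",
    "build_vegetation_subsystem",
    "build_land_subsystem",
    "assemble_full_model",
    "baseline_trajectory",
    "quality_assessment",
]

SUBSYSTEMS = ("air", "solid", "water", "vegetation", "land")

SUBSYSTEM_STOCKS = {
    "air": "air_pollution",
    "solid": "solid_waste_pollution",
    "water": "water_pollution",
    "vegetation": "vegetation_destruction_area",
    "land": "land_damage_area",
}

PROPORTION_FIELDS = {
    "air": "p_air",
    "solid": "p_solid",
    "water": "p_water",
    "vegetation": "p_green",
    "land": "p_land",
}

# Conversion factor: production constants are tabulated in m^2 while the
# vegetation and land stocks are carried in units of 10,000 m^2.
_AREA_UNIT = 10_000.0


class AllocationPolicy(BaseModel):
    """The five proportions splitting the environmental investment budget."""

    model_config = ConfigDict(frozen=True)

    p_air: float = Field(0.0, ge=0.0, le=1.0)
    p_solid: float = Field(0.0, ge=0.0, le=1.0)
    p_water: float = Field(0.0, ge=0.0, le=1.0)
    p_green: float = Field(0.0, ge=0.0, le=1.0)
    p_land: float = Field(0.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _budget(self) -> "AllocationPolicy":
        total = self.p_air + self.p_solid + self.p_water + self.p_green + self.p_land
        if total > 1.0 + 1e-9:
            raise ValueError(f"allocation proportions sum to {total:.6g} > 1")
        return self

    def proportion(self, subsystem: str) -> float:
        return getattr(self, PROPORTION_FIELDS[subsystem])

    def replace(self, **changes) -> "AllocationPolicy":
        return AllocationPolicy(**{**self.model_dump(), **changes})


ZERO_POLICY = AllocationPolicy()


class MineParams(BaseModel):
    """Model parameters: monthly production constants, the investment budget,
    and the initial pollution stocks.

    Production constants are monthly new pollution (m^2 except where noted);
    stocks are the accumulated pollution at month 0.  ``no2``/``so2``/``co``
    are optional: when all three are given they replace the aggregate
    ``waste_gas`` constant.
    """

    model_config = ConfigDict(frozen=True, populate_by_name=True)

    environmental_investment: float = Field(50.0, gt=0.0)

    # atmospheric subsystem
    dust: float = Field(3310.0, ge=0.0)
    waste_gas: float = Field(1514.0, ge=0.0)
    no2: float | None = Field(None, ge=0.0)
    so2: float | None = Field(None, ge=0.0)
    co: float | None = Field(None, ge=0.0)

    # solid waste subsystem (living garbage has no tabulated value; default 0)
    coal_gangue: float = Field(8750.0, ge=0.0)
    living_garbage: float = Field(0.0, ge=0.0)
    boiler_ash: float = Field(298.0, ge=0.0)

    # water resource subsystem
    life_wastewater: float = Field(980.0, ge=0.0)
    mine_water: float = Field(5392.0, ge=0.0)
    gangue_leaching: float = Field(73.0, ge=0.0)

    # vegetation cover subsystem
    construction_square: float = Field(30_000.0, ge=0.0)
    waste_rock_pile: float = Field(9833.0, ge=0.0)
    open_pit: float = Field(1500.0, ge=0.0)
    road: float = Field(80.0, ge=0.0)
    total_vegetation_area: float = Field(2645.2, gt=0.0)  # 10,000 m^2

    # land reclamation subsystem
    land_subsidence: float = Field(4400.0, ge=0.0)
    land_to_dig: float = Field(8800.0, ge=0.0)

    # initial stocks
    air_pollution_init: float = Field(300.0, ge=0.0)
    solid_waste_pollution_init: float = Field(25.6, ge=0.0)
    water_pollution_init: float = Field(35.0, ge=0.0)
    vegetation_destruction_init: float = Field(275.0, ge=0.0)  # 10,000 m^2
    land_damage_init: float = Field(
        450.0,
        ge=0.0,
        validation_alias=AliasChoices("land_damage_init", "land_area", "Land area"),
    )  # 10,000 m^2

    @property
    def waste_gas_components(self) -> tuple[float, float, float] | None:
        if self.no2 is not None and self.so2 is not None and self.co is not None:
            return (self.no2, self.so2, self.co)
        return None


class MineModelConfig(BaseModel):
    """Parameters plus the two structural switches.

    ``removal_basis``: ``stock`` drains every subsystem proportionally to its
    stock (the uniform default); ``literal`` drains solid waste and water
    proportionally to their *production* instead, following those subsystems'
    printed rate equations verbatim.  ``unit_harmonization`` divides the
    vegetation/land production constants (m^2) by 10^4 so they accumulate in
    the same 10,000 m^2 unit as their stocks.
    """

    model_config = ConfigDict(frozen=True)

    params: MineParams = Field(default_factory=MineParams)
    removal_basis: Literal["stock", "literal"] = "stock"
    unit_harmonization: bool = True

    @field_validator("unit_harmonization", mode="before")
    @classmethod
    def _on_off(cls, v):
        if isinstance(v, str):
            if v.lower() in ("on", "true", "yes"):
                return True
            if v.lower() in ("off", "false", "no"):
                return False
        return v


def technical_factor(proportion: float, env_investment: float) -> float:
    """Treatment technical factor: investment share over total budget.

    Computed as the chained form ``(proportion * E) / E`` and checked against
    the simplified form (the bare proportion); the two must agree to 1e-12.
    """
    if env_investment <= 0:
        raise ValueError("environmental investment must be positive")
    if not 0.0 <= proportion <= 1.0:
        raise ValueError(f"proportion must lie in [0, 1], got {proportion!r}")
    chained = (proportion * env_investment) / env_investment
    if abs(chained - proportion) > 1e-12:
        raise ArithmeticError(
            f"chained and simplified technical factors disagree: {chained!r} vs {proportion!r}"
        )
    return chained


def _investment_block(tag: str, proportion: float, env_investment: float):
    """Shared constants/auxiliaries wiring a subsystem's investment share."""
    constants = [
        ConstantDef("environmental_investment", float(env_investment), "ten thousand yuan"),
        ConstantDef(f"p_{tag}", float(proportion), "fraction"),
    ]
    auxiliaries = [
        AuxiliaryDef(f"investment_{tag}", f"p_{tag} * environmental_investment"),
        AuxiliaryDef(f"technical_factor_{tag}", f"investment_{tag} / environmental_investment"),
    ]
    return constants, auxiliaries


def build_air_subsystem(config: MineModelConfig, policy: AllocationPolicy) -> ModelSpec:
    """Atmospheric subsystem: air pollution stock, dust + waste-gas production,
    stock-proportional treatment (its printed rate equation is already
    stock-based, so both removal bases coincide here)."""
    p = config.params
    constants, auxiliaries = _investment_block("air", policy.p_air, p.environmental_investment)
    constants.append(ConstantDef("dust", p.dust, "m^2"))
    components = p.waste_gas_components
    if components is not None:
        no2, so2, co = components
        constants += [
            ConstantDef("no2", no2, "m^2"),
            ConstantDef("so2", so2, "m^2"),
            ConstantDef("co", co, "m^2"),
        ]
        auxiliaries.append(AuxiliaryDef("waste_gas", "no2 + so2 + co"))
    else:
        constants.append(ConstantDef("waste_gas", p.waste_gas, "m^2"))
    rates = [
        RateDef("air_pollution_production", "dust + waste_gas", "inflow", "air_pollution"),
        RateDef(
            "amount_of_air_pollution_control",
            "air_pollution * technical_factor_air",
            "outflow",
            "air_pollution",
        ),
    ]
    stocks = [StockDef("air_pollution", p.air_pollution_init, "m^2")]
    return ModelSpec(constants, auxiliaries, rates, stocks)


def build_solid_subsystem(config: MineModelConfig, policy: AllocationPolicy) -> ModelSpec:
    """Solid waste subsystem: coal gangue + living garbage + boiler ash."""
    p = config.params
    constants, auxiliaries = _investment_block("solid", policy.p_solid, p.environmental_investment)
    constants += [
        ConstantDef("coal_gangue", p.coal_gangue, "m^2"),
        ConstantDef("living_garbage", p.living_garbage, "m^2"),
        ConstantDef("boiler_ash", p.boiler_ash, "m^2"),
    ]
    auxiliaries.append(
        AuxiliaryDef("solid_waste_production_total", "coal_gangue + living_garbage + boiler_ash")
    )
    basis = (
        "solid_waste_pollution" if config.removal_basis == "stock" else "solid_waste_production_total"
    )
    rates = [
        RateDef("solid_waste_production", "solid_waste_production_total", "inflow", "solid_waste_pollution"),
        RateDef(
            "solid_waste_treatment_amount",
            f"{basis} * technical_factor_solid",
            "outflow",
            "solid_waste_pollution",
        ),
    ]
    stocks = [StockDef("solid_waste_pollution", p.solid_waste_pollution_init, "m^2")]
    return ModelSpec(constants, auxiliaries, rates, stocks)


def build_water_subsystem(config: MineModelConfig, policy: AllocationPolicy) -> ModelSpec:
    """Water resource subsystem: coal gangue + wastewater + mine water + leaching."""
    p = config.params
    constants, auxiliaries = _investment_block("water", policy.p_water, p.environmental_investment)
    constants += [
        ConstantDef("coal_gangue", p.coal_gangue, "m^2"),
        ConstantDef("life_wastewater", p.life_wastewater, "m^2"),
        ConstantDef("mine_water", p.mine_water, "m^2"),
        ConstantDef("gangue_leaching", p.gangue_leaching, "m^2"),
    ]
    auxiliaries.append(
        AuxiliaryDef(
            "water_pollution_production_total",
            "coal_gangue + life_wastewater + mine_water + gangue_leaching",
        )
    )
    basis = (
        "water_pollution" if config.removal_basis == "stock" else "water_pollution_production_total"
    )
    rates = [
        RateDef("water_pollution_production", "water_pollution_production_total", "inflow", "water_pollution"),
        RateDef(
            "amount_of_water_pollution_control",
            f"{basis} * technical_factor_water",
            "outflow",
            "water_pollution",
        ),
    ]
    stocks = [StockDef("water_pollution", p.water_pollution_init, "m^2")]
    return ModelSpec(constants, auxiliaries, rates, stocks)


def build_vegetation_subsystem(config: MineModelConfig, policy: AllocationPolicy) -> ModelSpec:
    """Vegetation cover subsystem.

    Destroyed-vegetation stock fed by mining construction, waste-rock piling,
    open-pit mining and roads; restoration drains it proportionally to the
    stock.  The greening rate auxiliary is the intact fraction of the total
    vegetation area.
    """
    p = config.params
    constants, auxiliaries = _investment_block("green", policy.p_green, p.environmental_investment)
    constants += [
        ConstantDef("construction_square", p.construction_square, "m^2"),
        ConstantDef("waste_rock_pile", p.waste_rock_pile, "m^2"),
        ConstantDef("open_pit", p.open_pit, "m^2"),
        ConstantDef("road", p.road, "m^2"),
        ConstantDef("total_vegetation_area", p.total_vegetation_area, "10,000 m^2"),
    ]
    production = "construction_square + waste_rock_pile + open_pit + road"
    if config.unit_harmonization:
        production = f"({production}) / {_AREA_UNIT}"
    auxiliaries += [
        AuxiliaryDef("vegetation_destruction_production", production),
        AuxiliaryDef(
            "vegetation_greening_rate",
            "(total_vegetation_area - vegetation_destruction_area) / total_vegetation_area",
        ),
    ]
    rates = [
        RateDef(
            "vegetation_destruction_rate",
            "vegetation_destruction_production",
            "inflow",
            "vegetation_destruction_area",
        ),
        RateDef(
            "vegetation_restoration",
            "vegetation_destruction_area * technical_factor_green",
            "outflow",
            "vegetation_destruction_area",
        ),
    ]
    stocks = [StockDef("vegetation_destruction_area", p.vegetation_destruction_init, "10,000 m^2")]
    return ModelSpec(constants, auxiliaries, rates, stocks)


def build_land_subsystem(config: MineModelConfig, policy: AllocationPolicy) -> ModelSpec:
    """Land reclamation subsystem: damage from subsidence and excavation,
    reclamation proportional to the damaged-land stock."""
    p = config.params
    constants, auxiliaries = _investment_block("land", policy.p_land, p.environmental_investment)
    constants += [
        ConstantDef("land_subsidence", p.land_subsidence, "m^2"),
        ConstantDef("land_to_dig", p.land_to_dig, "m^2"),
    ]
    production = "land_subsidence + land_to_dig"
    if config.unit_harmonization:
        production = f"({production}) / {_AREA_UNIT}"
    auxiliaries.append(AuxiliaryDef("land_damage_production", production))
    rates = [
        RateDef("land_damage_rate", "land_damage_production", "inflow", "land_damage_area"),
        RateDef(
            "land_reclamation",
            "land_damage_area * technical_factor_land",
            "outflow",
            "land_damage_area",
        ),
    ]
    stocks = [StockDef("land_damage_area", p.land_damage_init, "10,000 m^2")]
    return ModelSpec(constants, auxiliaries, rates, stocks)


_BUILDERS = {
    "air": build_air_subsystem,
    "solid": build_solid_subsystem,
    "water": build_water_subsystem,
    "vegetation": build_vegetation_subsystem,
    "land": build_land_subsystem,
}


def build_subsystem(subsystem: str, config: MineModelConfig, policy: AllocationPolicy) -> ModelSpec:
    """Build one named subsystem fragment."""
    return _BUILDERS[subsystem](config, policy)


def assemble_full_model(config: MineModelConfig, policy: AllocationPolicy) -> ModelSpec:
    """Union of the five subsystem fragments sharing the investment budget."""
    spec = ModelSpec.merge(*(_BUILDERS[s](config, policy) for s in SUBSYSTEMS))
    diags = validate_model(spec)
    if diags:
        raise ModelValidationError(diags)
    return spec


def baseline_trajectory(
    config: MineModelConfig, sim: SimConfig | None = None
) -> Trajectory:
    """Simulate the untreated model (all-zero allocation); the quality reference."""
    return simulate(assemble_full_model(config, ZERO_POLICY), sim)


@dataclass
class QualitySeries:
    """Per-subsystem and overall environmental quality over the horizon.

    ``overall`` is the arithmetic mean of the five subsystem series; every
    value lies in [0, 1].
    """

    per_subsystem: dict[str, np.ndarray]
    overall: np.ndarray


def quality_assessment(treated: Trajectory, baseline: Trajectory) -> QualitySeries:
    """Quality of a treated run against the zero-investment baseline.

    ``q_i(t) = (B_i(t) - S_i(t)) / B_i(t)`` per subsystem: the fraction of the
    untreated pollution stock removed by treatment, which is scale-invariant
    across subsystems with very different magnitudes and maps "no treatment"
    to 0.  The overall score is the mean of the five.
    """
    if treated.times.shape != baseline.times.shape or not np.array_equal(
        treated.times, baseline.times
    ):
        raise ValueError("treated and baseline trajectories must share one time grid")
    per: dict[str, np.ndarray] = {}
    for sub, stock in SUBSYSTEM_STOCKS.items():
        s = treated.series[stock]
        b = baseline.series[stock]
        if np.any(b <= 0):
            raise ZeroDivisionError(
                f"baseline stock {stock!r} is not strictly positive; quality undefined"
            )
        per[sub] = (b - s) / b
    overall = np.mean(np.stack(list(per.values())), axis=0)
    return QualitySeries(per_subsystem=per, overall=overall)
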