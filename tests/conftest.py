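import pytest

from minesd.engine import ConstantDef, ModelSpec, RateDef, SimConfig, StockDef
from minesd.mine import MineModelConfig


def linear_stock_spec(x0: float, production: float, removal: float) -> ModelSpec:
    """Single stock with constant inflow P and outflow p * stock."""
    return ModelSpec(
        constants=[ConstantDef("production", production), ConstantDef("removal", removal)],
        rates=[
            RateDef("inflow", "production", "inflow", "x"),
            RateDef("outflow", "x * removal", "outflow", "x"),
        ],
        stocks=[StockDef("x", x0)],
    )


def linear_closed_form(x0: float, production: float, removal: float, t: int, dt: float = 1.0):
    """Geometric-recursion solution of the linear stock under Euler stepping."""
    if removal == 0:
        return x0 + production * dt * t
    eq = production / removal
    return eq + (x0 - eq) * (1.0 - removal * dt) ** t


@pytest.fixture
def sim24() -> SimConfig:
    return SimConfig(initial_time=0, final_time=24, dt=1.0)


@pytest.fixture
def default_config() -> MineModelConfig:
    return MineModelConfig()
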