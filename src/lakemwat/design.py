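"""Training experiment design: Sobol quasi-random lake sampling crossed
factorially with climate locations and scenarios.

The lake design space (depth, area, extinction) is covered with a Sobol
low-discrepancy sequence rather than pseudo-random draws, so that a small
number of training lakes fills the response surface evenly. The standard
primitive-polynomial direction numbers (Joe-Kuo tables) for dimensions
1-10 are shipped as literal constants and the generator uses the
Antonov-Saleev Gray-code update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_lake import (
    AREA_RANGE,
    DEPTH_RANGE,
    EXTINCTION_RANGE,
    LOCATION_PRESETS,
    SCENARIO_PRESETS,
    LakeConfig,
)

#: Joe-Kuo ("new-joe-kuo-6") primitive polynomial degrees, coefficients and
#: initial direction numbers for dimensions 2..10; dimension 1 is the
#: van der Corput sequence in base 2.
_JOE_KUO = {
    2: (1, 0, (1,)),
    3: (2, 1, (1, 3)),
    4: (3, 1, (1, 3, 1)),
    5: (3, 2, (1, 1, 1)),
    6: (4, 1, (1, 1, 3, 3)),
    7: (4, 4, (1, 3, 5, 13)),
    8: (5, 2, (1, 1, 5, 5, 17)),
    9: (5, 4, (1, 1, 5, 5, 5)),
    10: (5, 7, (1, 1, 7, 11, 19)),
}

MAX_DIMENSION = 10
_NBITS = 30


def _direction_integers(dim: int):
    """Direction numbers of dimension ``dim`` scaled to integers * 2^NBITS."""
    if dim == 1:
        return [1 << (_NBITS - k - 1) for k in range(_NBITS)]
    s, a, m_init = _JOE_KUO[dim]
    m = list(m_init)
    for k in range(s, _NBITS):
        new = m[k - s] ^ (m[k - s] << s)
        for i in range(1, s):
            if (a >> (s - 1 - i)) & 1:
                new ^= m[k - i] << i
        m.append(new)
    return [m[k] << (_NBITS - k - 1) for k in range(_NBITS)]


@dataclass
class SobolState:
    """Mutable state of a Sobol sequence generator."""

    dimension: int
    skip_zero: bool = True
    index: int = field(default=0)
    _x: list = field(default=None, repr=False)
    _directions: list = field(default=None, repr=False)

    def __post_init__(self):
        if not (1 <= self.dimension <= MAX_DIMENSION):
            raise ValueError(f"dimension must be in 1..{MAX_DIMENSION} "
                             "(shipped direction-number tables)")
        self._x = [0] * self.dimension
        self._directions = [_direction_integers(j + 1) for j in range(self.dimension)]


def sobol_next(state: SobolState) -> np.ndarray:
    """Emit the next point of the standard Sobol sequence in [0,1)^d.

    With ``skip_zero`` (the default) the initial all-zeros point is skipped,
    so the first emitted point is (0.5, ..., 0.5).
    """
    if state.index == 0 and not state.skip_zero:
        state.index += 1
        return np.zeros(state.dimension)
    i = state.index - (0 if state.skip_zero else 1)
    c = 0
    while (i >> c) & 1:
        c += 1
    for j in range(state.dimension):
        state._x[j] ^= state._directions[j][c]
    state.index += 1
    return np.array([xj / float(1 << _NBITS) for xj in state._x])


def sobol_points(n: int, dimension: int, skip_zero: bool = True) -> np.ndarray:
    """First ``n`` points of the Sobol sequence as an (n, d) array."""
    state = SobolState(dimension, skip_zero=skip_zero)
    return np.array([sobol_next(state) for _ in range(n)])


# ---------------------------------------------------------------------------
# mapping the unit cube to lake characteristics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LakeRanges:
    """Design ranges: depth linear, area and extinction log-uniform."""

    depth: tuple = DEPTH_RANGE           # m
    area: tuple = AREA_RANGE             # m^2
    extinction: tuple = EXTINCTION_RANGE  # m^-1


DEFAULT_RANGES = LakeRanges()


def map_to_lake_space(u, ranges: LakeRanges = DEFAULT_RANGES,
                      lake_id: str = "lake") -> LakeConfig:
    """Map a unit-cube triplet (depth, area, extinction axes) to a lake.

    Depth is linear on its range; area and extinction are log-uniform, since
    both span more than an order of magnitude.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (3,) or np.any(u < 0) or np.any(u >= 1):
        raise ValueError("u must be a triplet in [0,1)^3")
    depth = ranges.depth[0] + u[0] * (ranges.depth[1] - ranges.depth[0])
    area = math.exp(math.log(ranges.area[0])
                    + u[1] * (math.log(ranges.area[1]) - math.log(ranges.area[0])))
    ext = math.exp(math.log(ranges.extinction[0])
                   + u[2] * (math.log(ranges.extinction[1]) - math.log(ranges.extinction[0])))
    return LakeConfig(lake_id=lake_id, max_depth=float(depth),
                      surface_area=float(area), extinction=float(ext))


def sobol_lake_configs(n: int, ranges: LakeRanges = DEFAULT_RANGES):
    """First ``n`` Sobol-designed training lakes."""
    return [map_to_lake_space(u, ranges, lake_id=f"sobol{i + 1:03d}")
            for i, u in enumerate(sobol_points(n, 3))]


def factorial_lake_configs(levels: int = 3, ranges: LakeRanges = DEFAULT_RANGES):
    """Full-factorial archetype grid (``levels`` per factor, e.g. 3^3 = 27).

    Levels are placed at cell midpoints of the unit cube and mapped through
    the same transforms as the Sobol design.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    grid = (np.arange(levels) + 0.5) / levels
    out = []
    i = 0
    for ud in grid:
        for ua in grid:
            for ue in grid:
                i += 1
                out.append(map_to_lake_space((ud, ua, ue), ranges,
                                             lake_id=f"grid{i:03d}"))
    return out


# ---------------------------------------------------------------------------
# full training design
# ---------------------------------------------------------------------------

@dataclass
class TrainingDesign:
    """Cross-product of locations x scenarios x lake configurations."""

    locations: list            # of LocationParams
    scenarios: list            # of ScenarioDelta, baseline included
    lake_configs: list         # of LakeConfig
    runs: list                 # of (location, scenario, lake) tuples

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def manifest(self) -> pd.DataFrame:
        rows = []
        for run_id, (loc, scen, lake) in enumerate(self.runs, start=1):
            rows.append({
                "run_id": run_id,
                "location_id": loc.location_id,
                "scenario_id": scen.scenario_id,
                "lake_id": lake.lake_id,
                "max_depth_m": lake.max_depth,
                "surface_area_m2": lake.surface_area,
                "extinction_m1": lake.extinction,
            })
        return pd.DataFrame(rows)


def build_training_design(n_locations: int, n_scenarios: int, n_lakes: int,
                          seed: int = 0, mode: str = "sobol",
                          ranges: LakeRanges = DEFAULT_RANGES,
                          locations=None, scenarios=None) -> TrainingDesign:
    """Assemble the factorial training experiment.

    ``n_locations`` location presets are crossed with ``n_scenarios``
    scenario presets (the unperturbed baseline always first) and ``n_lakes``
    lake configurations, drawn from the Sobol sequence (default) or, in
    ``mode="factorial"``, from the archetype grid with
    ``round(n_lakes**(1/3))`` levels per factor. ``seed`` is carried for
    interface symmetry; the Sobol design itself is deterministic.
    """
    if min(n_locations, n_scenarios, n_lakes) < 1:
        raise ValueError("all design counts must be >= 1")
    del seed  # quasi-random design: no randomness to seed
    if locations is None:
        locations = list(LOCATION_PRESETS.values())
    if scenarios is None:
        scenarios = list(SCENARIO_PRESETS.values())
    if n_locations > len(locations) or n_scenarios > len(scenarios):
        raise ValueError("not enough presets for the requested design")
    locations = locations[:n_locations]
    scenarios = scenarios[:n_scenarios]
    if not any(s.is_baseline for s in scenarios):
        raise ValueError("scenario list must include the unperturbed baseline")

    if mode == "sobol":
        lakes = sobol_lake_configs(n_lakes, ranges)
    elif mode == "factorial":
        levels = round(n_lakes ** (1.0 / 3.0))
        if levels ** 3 != n_lakes:
            raise ValueError("factorial mode needs a cubic number of lakes")
        lakes = factorial_lake_configs(levels, ranges)
    else:
        raise ValueError("mode must be 'sobol' or 'factorial'")

    runs = [(loc, scen, lake)
            for loc in locations for scen in scenarios for lake in lakes]
    return TrainingDesign(locations=locations, scenarios=scenarios,
                          lake_configs=lakes, runs=runs)
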