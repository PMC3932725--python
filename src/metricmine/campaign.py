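"""Parameter-grid bookkeeping for evaluation campaigns.

A campaign is a set of algorithms, each with a discrete grid of parameter
settings; every grid point is one run producing one candidate image.  This
module enumerates grids deterministically, counts campaign sizes, and builds
the run records the store logs.  It never executes any external registration
tool — candidates may come from anywhere, including the synthetic module.

A ready-made fixture (:func:`reference_campaign`) describes the four-tool
neuroimaging registration sweep used throughout the docs: AIR Linear
(5 blurs x 3 models x 2 costs = 30), AIR Warp (3 warp models x the linear
grid = 90), FSL FLIRT (3 interpolations x 4 dof x 5 costs = 60) and MINC
Tracc (6 dof values), 186 runs in total.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence, Union

__all__ = [
    "ParameterGrid",
    "RunRecord",
    "enumerate_grid",
    "campaign_size",
    "make_run_records",
    "load_campaign",
    "save_campaign",
    "reference_campaign",
]


@dataclass
class ParameterGrid:
    """A named algorithm with discrete, ordered parameter axes."""

    algorithm_name: str
    axes: Dict[str, List[Any]]
    multiplier: int = 1

    def __post_init__(self) -> None:
        if not self.axes:
            raise ValueError(f"{self.algorithm_name}: grid has no axes")
        for name, values in self.axes.items():
            if len(values) == 0:
                raise ValueError(f"{self.algorithm_name}: axis {name!r} is empty")
            if len(set(map(repr, values))) != len(values):
                raise ValueError(f"{self.algorithm_name}: axis {name!r} has duplicate values")
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1")

    @property
    def size(self) -> int:
        n = 1
        for values in self.axes.values():
            n *= len(values)
        return n


@dataclass
class RunRecord:
    """One campaign run: a parameter assignment plus execution metadata."""

    run_id: str
    algorithm_name: str
    parameters: Dict[str, Any]
    image_path: Optional[str] = None
    created_at: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    status: str = "pending"


def enumerate_grid(grid: ParameterGrid) -> List[Dict[str, Any]]:
    """Full Cartesian product of the grid's axes.

    Order is deterministic: lexicographic over the axes in declared order,
    each axis cycling through its values as declared (itertools.product).
    """
    names = list(grid.axes)
    combos = itertools.product(*(grid.axes[n] for n in names))
    return [dict(zip(names, c)) for c in combos]


def campaign_size(
    grids: Sequence[ParameterGrid],
    multipliers: Optional[Sequence[int]] = None,
) -> int:
    """Total number of runs: sum over grids of multiplier * |grid|.

    ``multipliers`` overrides each grid's own multiplier attribute when given
    (e.g. a warp family re-running a base linear grid under 3 warp models).
    """
    if multipliers is None:
        multipliers = [g.multiplier for g in grids]
    if len(multipliers) != len(grids):
        raise ValueError("one multiplier per grid required")
    return sum(int(m) * g.size for g, m in zip(grids, multipliers))


def make_run_records(grid: ParameterGrid) -> List[RunRecord]:
    """RunRecords for every grid point; run_id = algorithm/ordinal for
    reproducible joins with the store."""
    return [
        RunRecord(
            run_id=f"{grid.algorithm_name}/{i:04d}",
            algorithm_name=grid.algorithm_name,
            parameters=assignment,
        )
        for i, assignment in enumerate(enumerate_grid(grid))
    ]


def load_campaign(path: Union[str, Path]) -> List[ParameterGrid]:
    """Read a campaign specification (list of {algorithm, axes, multiplier})."""
    with open(path) as fh:
        spec = json.load(fh)
    return _grids_from_spec(spec)


def save_campaign(grids: Sequence[ParameterGrid], path: Union[str, Path]) -> None:
    spec = [
        {"algorithm": g.algorithm_name, "axes": g.axes, "multiplier": g.multiplier}
        for g in grids
    ]
    with open(path, "w") as fh:
        json.dump(spec, fh, indent=2, sort_keys=False)


def _grids_from_spec(spec: List[Dict[str, Any]]) -> List[ParameterGrid]:
    return [
        ParameterGrid(
            algorithm_name=entry["algorithm"],
            axes={k: list(v) for k, v in entry["axes"].items()},
            multiplier=int(entry.get("multiplier", 1)),
        )
        for entry in spec
    ]


def reference_campaign() -> List[ParameterGrid]:
    """The shipped four-tool registration campaign (186 runs)."""
    text = resources.files("metricmine.data").joinpath("four_tool_campaign.json").read_text()
    return _grids_from_spec(json.loads(text))
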