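"""Scheduled MRM method tables and internal-standard mixture assembly.

Route defaults follow the two LC-MRM methods the assay runs on: a 160-min
gradient with 3-s cycle time for IMAC-enriched samples and a 120-min gradient
with 1.5-s cycle time for pY-antibody-enriched samples, both with Q1/Q3
resolutions of 0.4/0.7 FWHM and a 10-min retention-time scheduling window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    METHOD_DEFAULTS,
    MIXTURE_BOUNDS,
    MIXTURE_CONCENTRATION,
    Q1_RESOLUTION,
    Q3_RESOLUTION,
    RT_WINDOW_MIN,
)
from .masses import Transition
from .panel import PanelEntry


class MethodError(ValueError):
    pass


@dataclass
class MethodConfig:
    route: str
    duration: float = 0.0  # minutes; 0 -> route default
    rt_window: float = RT_WINDOW_MIN
    cycle_time: float = 0.0  # seconds; 0 -> route default
    q1_resolution: float = Q1_RESOLUTION
    q3_resolution: float = Q3_RESOLUTION

    def __post_init__(self) -> None:
        if self.route not in METHOD_DEFAULTS:
            raise MethodError(f"unknown route {self.route!r}")
        if not self.duration:
            self.duration = METHOD_DEFAULTS[self.route]["duration_min"]
        if not self.cycle_time:
            self.cycle_time = METHOD_DEFAULTS[self.route]["cycle_time_s"]
        if self.rt_window <= 0 or self.duration <= 0:
            raise MethodError("rt_window and duration must be positive")


@dataclass
class Mixture:
    name: str
    route: str
    members: list[PanelEntry] = field(default_factory=list)
    concentration: float = MIXTURE_CONCENTRATION  # pmol/ul, equimolar


def build_method(
    entries: list[tuple[PanelEntry, list[Transition]]],
    config: MethodConfig,
    library_rts: dict[str, float],
) -> tuple[pd.DataFrame, int]:
    """Scheduled method table plus the max-concurrency diagnostic.

    One row per transition with the RT window [RT - w/2, RT + w/2] clipped to
    the gradient.  The diagnostic is the maximum number of transitions
    monitored at any instant, from a 0.1-min grid sweep.
    """
    rows = []
    half = config.rt_window / 2.0
    for entry, transitions in entries:
        key = entry.modified_sequence
        if key not in library_rts:
            raise MethodError(f"no library retention time for {key}")
        rt = library_rts[key]
        if not 0 <= rt <= config.duration:
            raise MethodError(
                f"retention time {rt} min of {key} outside gradient "
                f"[0, {config.duration}]"
            )
        lo, hi = max(0.0, rt - half), min(config.duration, rt + half)
        for t in transitions:
            rows.append(
                {
                    "protein": entry.gene_symbol,
                    "modified_sequence": key,
                    "precursor_mz": round(t.precursor_mz, 5),
                    "product_mz": round(t.product_mz, 5),
                    "fragment_ion": t.fragment_ion,
                    "collision_energy": t.collision_energy,
                    "rt": rt,
                    "rt_window_start": lo,
                    "rt_window_end": hi,
                    "cycle_time_s": config.cycle_time,
                    "q1_resolution": config.q1_resolution,
                    "q3_resolution": config.q3_resolution,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table, 0
    grid = np.arange(0.0, config.duration + 1e-9, 0.1)
    starts = table["rt_window_start"].to_numpy()[:, None]
    ends = table["rt_window_end"].to_numpy()[:, None]
    concurrency = ((grid >= starts) & (grid <= ends)).sum(axis=0)
    return table, int(concurrency.max())


def _partition_sizes(n: int, bounds: tuple[int, int]) -> list[int] | None:
    """Smallest number of parts with every size in ``bounds`` and sizes as
    equal as possible (max - min <= 1); None if infeasible."""
    lo, hi = bounds
    k = max(1, -(-n // hi))  # ceil; fewer parts would overflow hi
    if k * lo > n or n > k * hi:
        # More parts only raises the total lower bound, so k is the only try.
        return None
    base, rem = divmod(n, k)
    return [base + 1] * rem + [base] * (k - rem)


def assemble_mixtures(
    panel: list[PanelEntry],
    bounds: dict[str, tuple[int, int]] | None = None,
) -> list[Mixture]:
    """Group selected entries by route, sort alphabetically by gene symbol and
    partition contiguously into equimolar mixtures within per-route size
    bounds.  Infeasible bounds relax to one mixture with a warning."""
    bounds = bounds or MIXTURE_BOUNDS
    mixtures: list[Mixture] = []
    for route in ("IMAC", "pY", "IMACpY"):
        members = sorted(
            (e for e in panel if e.is_selected and e.enrichment_route == route),
            key=lambda e: (e.gene_symbol, e.modified_sequence),
        )
        if not members:
            continue
        if route == "IMACpY":
            sizes = [len(members)]
        else:
            sizes = _partition_sizes(len(members), bounds[route])
            if sizes is None:
                warnings.warn(
                    f"{route}: {len(members)} entries infeasible for bounds "
                    f"{bounds[route]}; relaxing to a single mixture",
                    stacklevel=2,
                )
                sizes = [len(members)]
        pos = 0
        for i, size in enumerate(sizes, start=1):
            name = route if len(sizes) == 1 else f"{route}-{i}"
            mixtures.append(
                Mixture(name=name, route=route, members=members[pos : pos + size])
            )
            pos += size
    return mixtures
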