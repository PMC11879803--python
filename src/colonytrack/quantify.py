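"""Biological read-outs from classified trajectories.

Turns tracks into the colony-forming assay's quantities: unique-object
counts per stack, plating efficiency (PE), survival fraction (SF), stack
geometry, and replicate time series with mean +/- SEM.

Two PE denominators are in routine use: the number of cells seeded, and
the number of single cells actually observed at the start timepoint. Both
are supported through ``denominator_mode``; the automated per-ROI
workflow defaults to ``observed_start``, and results carry the mode so
the two are never silently mixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classes import CANDIDATE, CELL, CLUSTER, COLONY
from .ztrack import Track, classify_track

__all__ = [
    "StackCounts",
    "PEResult",
    "count_objects",
    "plating_efficiency",
    "survival_fraction",
    "stack_height",
    "assemble_time_series",
]


@dataclass(frozen=True)
class StackCounts:
    """Unique-object tallies for one stack (one well/ROI/timepoint).

    Candidate-only trajectories are bookkept separately: they never enter
    the cell/cluster/colony totals.
    """

    well: str = ""
    roi: str = ""
    timepoint: float = 0.0
    n_cells: int = 0
    n_clusters: int = 0
    n_colonies: int = 0
    n_candidates: int = 0

    @property
    def n_objects(self) -> int:
        return self.n_cells + self.n_clusters + self.n_colonies

    @property
    def clusters_and_colonies(self) -> int:
        """The dose-response read-out: clusters + colonies."""
        return self.n_clusters + self.n_colonies


@dataclass(frozen=True)
class PEResult:
    pe_percent: float
    colonies_end: int
    denominator: int
    denominator_mode: str


def count_objects(
    tracks: list[Track], well: str = "", roi: str = "", timepoint: float = 0.0
) -> StackCounts:
    """Tally tracks by their final hierarchical class."""
    tally = {CANDIDATE: 0, CELL: 0, CLUSTER: 0, COLONY: 0}
    for track in tracks:
        tally[classify_track(track)] += 1
    return StackCounts(
        well=well,
        roi=roi,
        timepoint=timepoint,
        n_cells=tally[CELL],
        n_clusters=tally[CLUSTER],
        n_colonies=tally[COLONY],
        n_candidates=tally[CANDIDATE],
    )


def plating_efficiency(
    colonies_end: int, denominator: int, mode: str = "observed_start"
) -> PEResult:
    """PE (%) = 100 x colonies at the final timepoint / denominator.

    ``mode`` records whether the denominator is the number of cells seeded
    ("seeded") or the single cells observed at the start ("observed_start").
    """
    if mode not in ("seeded", "observed_start"):
        raise ValueError(f"unknown denominator mode {mode!r}")
    if denominator <= 0:
        raise ValueError("PE denominator must be positive")
    if colonies_end < 0:
        raise ValueError("colony count must be non-negative")
    return PEResult(
        pe_percent=100.0 * colonies_end / denominator,
        colonies_end=colonies_end,
        denominator=denominator,
        denominator_mode=mode,
    )


def survival_fraction(
    colonies_treated: int, cells_seeded: int, pe: float
) -> float:
    """SF = colonies after treatment / (cells seeded x PE), PE a fraction
    in (0, 1]. The untreated control evaluated with its own PE gives 1."""
    if cells_seeded <= 0:
        raise ValueError("cells_seeded must be positive")
    if not (0.0 < pe <= 1.0):
        raise ValueError("pe must be a fraction in (0, 1]")
    if colonies_treated < 0:
        raise ValueError("colony count must be non-negative")
    return colonies_treated / (cells_seeded * pe)


def stack_height(n_slices: int, spacing_um: float) -> float:
    """Total axial height covered by a stack: n_slices x spacing (the
    assay protocol's convention, e.g. 25 slices x 30 µm = 750 µm)."""
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if spacing_um <= 0:
        raise ValueError("spacing must be positive")
    return n_slices * spacing_um


def assemble_time_series(
    counts: list[StackCounts], condition: str = ""
) -> pd.DataFrame:
    """Tidy per-class time series with mean and SEM across replicates.

    Replicates are the (well, roi) pairs sharing a timepoint. SEM is the
    sample sd / sqrt(n); for a single replicate it is reported as 0.0 with
    ``sem_defined`` False (the convention is explicit, not imputed).
    Missing timepoints stay missing. Duplicate (well, roi, timepoint)
    entries are an input error.
    """
    if not counts:
        return pd.DataFrame(
            columns=["condition", "timepoint_h", "class", "mean", "sem", "n", "sem_defined"]
        )
    keys = [(c.well, c.roi, c.timepoint) for c in counts]
    if len(keys) != len(set(keys)):
        raise ValueError("duplicate (well, roi, timepoint) entries")
    rows = []
    for c in counts:
        for cls, value in (
            (CELL, c.n_cells),
            (CLUSTER, c.n_clusters),
            (COLONY, c.n_colonies),
            (CANDIDATE, c.n_candidates),
        ):
            rows.append(
                {"timepoint_h": c.timepoint, "class": cls, "count": value}
            )
    long = pd.DataFrame(rows)
    grouped = (
        long.groupby(["timepoint_h", "class"], sort=True)["count"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    grouped["sem_defined"] = grouped["n"] > 1
    grouped["sem"] = np.where(
        grouped["sem_defined"], grouped["sd"] / np.sqrt(grouped["n"]), 0.0
    )
    grouped["condition"] = condition
    return grouped[
        ["condition", "timepoint_h", "class", "mean", "sem", "n", "sem_defined"]
    ]
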