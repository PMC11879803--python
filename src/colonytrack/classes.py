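"""The hierarchical four-class scheme shared by the whole pipeline.

Classes are ordered by relevance: an out-of-focus *candidate* is only a
hypothesis; a *cell* is a single cell; a *cluster* is a group of 2-14 cells;
a *colony* is a group of 15 or more. A trajectory's final class is the
maximum over this order of the per-slice labels.
"""

from __future__ import annotations

CANDIDATE = "candidate"
CELL = "cell"
CLUSTER = "cluster"
COLONY = "colony"

#: Hierarchical order: candidate < cell < cluster < colony.
CLASS_ORDER: dict[str, int] = {CANDIDATE: 0, CELL: 1, CLUSTER: 2, COLONY: 3}

#: Index -> name, matching the annotation-file class indices.
CLASS_NAMES: tuple[str, ...] = (CANDIDATE, CELL, CLUSTER, COLONY)

#: Minimum cell count at which a group is called a colony.
COLONY_MIN_CELLS = 15


def class_from_cell_count(cell_count: int) -> str:
    """Map a cell count to {cell, cluster, colony}.

    1 cell -> cell, 2-14 -> cluster, >= 15 -> colony. The partition is total:
    a count of exactly 15 is a colony.
    """
    if cell_count < 1:
        raise ValueError(f"cell_count must be >= 1, got {cell_count}")
    if cell_count == 1:
        return CELL
    if cell_count < COLONY_MIN_CELLS:
        return CLUSTER
    return COLONY


def max_class(labels: list[str]) -> str:
    """Maximum label under the hierarchical order; errors on empty input."""
    if not labels:
        raise ValueError("cannot take the maximum class of an empty label list")
    return max(labels, key=lambda lbl: CLASS_ORDER[lbl])
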