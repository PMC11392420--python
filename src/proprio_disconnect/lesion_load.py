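"""Tract lesion load, grey-matter lesion volume and the tract-inclusion filter.

Lesion load to a white-matter tract is the fraction of the tract's voxels
overlapped by the lesion, expressed as a percentage.  The tract mask is the
probabilistic atlas map binarised at a configurable threshold (default: any
support, probability > 0).  Homologous tracts are paired by a
``_left``/``_right`` label suffix; a tract family enters the group analysis
only when strictly more than ``min_n`` participants show damage (load > 0)
on the left homologue and strictly more than ``min_n`` on the right.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .volumes import VolumeGrid, require_compatible

__all__ = [
    "tract_lesion_load",
    "grey_matter_lesion_volume",
    "tract_load_table",
    "tract_inclusion_filter",
    "split_homologue",
]


class EmptyTractError(ValueError):
    """The binarised tract mask has no voxels; lesion load is undefined."""


def tract_lesion_load(
    lesion: VolumeGrid, tract: VolumeGrid, threshold: float = 0.0
) -> float:
    """Percentage of the tract's voxels damaged by the lesion.

    ``100 * |lesion AND (tract > threshold)| / |tract > threshold|``.
    """
    require_compatible(lesion, tract)
    lesion_mask = lesion.as_mask()
    tract_mask = np.asarray(tract.values) > threshold
    total = int(tract_mask.sum())
    if total == 0:
        raise EmptyTractError("tract mask is empty at this threshold")
    damaged = int(np.count_nonzero(lesion_mask & tract_mask))
    return 100.0 * damaged / total


def grey_matter_lesion_volume(lesion: VolumeGrid, gm_mask: VolumeGrid) -> float:
    """Overlap of the lesion with the grey-matter segmentation, in cc."""
    require_compatible(lesion, gm_mask)
    overlap = int(np.count_nonzero(lesion.as_mask() & gm_mask.as_mask()))
    return overlap * lesion.voxel_volume_mm3 / 1000.0


def split_homologue(label: str) -> tuple[str, str]:
    """Split a tract label into (family, side) by the _left/_right suffix."""
    for side in ("left", "right"):
        suffix = f"_{side}"
        if label.endswith(suffix):
            return label[: -len(suffix)], side
    raise ValueError(f"tract label {label!r} has no _left/_right suffix")


def tract_load_table(
    lesions: Mapping[str, VolumeGrid],
    tract_maps: Mapping[str, VolumeGrid],
    gm_mask: VolumeGrid | None = None,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-participant lesion loads (%) for every tract, plus volumes (cc).

    Rows are participants; columns are tract labels, ``total_volume_cc`` and
    (when a grey-matter mask is given) ``gm_volume_cc``.
    """
    rows = {}
    for pid, lesion in lesions.items():
        row = {
            label: tract_lesion_load(lesion, tract, threshold)
            for label, tract in tract_maps.items()
        }
        row["total_volume_cc"] = lesion.volume_cc()
        if gm_mask is not None:
            row["gm_volume_cc"] = grey_matter_lesion_volume(lesion, gm_mask)
        rows[pid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def tract_inclusion_filter(
    loads: pd.DataFrame, min_n: int = 25, tract_labels: Iterable[str] | None = None
) -> list[str]:
    """Tract families with enough bilaterally damaged participants.

    A family is included iff more than ``min_n`` participants have load > 0
    on its left homologue AND more than ``min_n`` on its right homologue
    (strict inequality: 26/26 is in, 26/25 is out).
    """
    if loads.empty:
        raise ValueError("empty lesion-load table")
    labels = list(
        tract_labels
        if tract_labels is not None
        else [c for c in loads.columns if c.endswith(("_left", "_right"))]
    )
    families: dict[str, dict[str, str]] = {}
    for label in labels:
        family, side = split_homologue(label)
        families.setdefault(family, {})[side] = label
    included = []
    for family in sorted(families):
        sides = families[family]
        if set(sides) != {"left", "right"}:
            raise ValueError(f"tract family {family!r} is missing a homologue")
        counts = {
            side: int((loads[sides[side]] > 0).sum()) for side in ("left", "right")
        }
        if counts["left"] > min_n and counts["right"] > min_n:
            included.append(family)
    return included
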