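"""Two-level union/intersection merging of CEG sets.

The merge is strictly sequential: CEG sets of the queried lncRNAs are
first merged *within* each dataset, then the per-dataset merged sets are
merged *across* datasets. A union reflects coordinated correlation by
all lncRNAs; an intersection reflects cooperative correlation of shared
targets. The two levels are kept separate because their order matters
when the modes differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from functools import reduce
from typing import Mapping, Sequence

from .coexpression import CEGSet
from .errors import ValidationError

logger = logging.getLogger(__name__)


class MergeMode(str, Enum):
    UNION = "union"
    INTERSECTION = "intersection"


@dataclass(frozen=True)
class MergeSpec:
    within_mode: MergeMode
    across_mode: MergeMode
    lnc_ids: tuple[str, ...]
    dataset_ids: tuple[str, ...]

    def __post_init__(self):
        if not self.lnc_ids:
            raise ValidationError("MergeSpec needs at least one lncRNA")
        if not self.dataset_ids:
            raise ValidationError("MergeSpec needs at least one dataset")


@dataclass
class MergedCEGs:
    members: frozenset[str]
    spec: MergeSpec
    #: merged set per dataset, before the cross-dataset merge
    per_dataset_members: dict[str, frozenset[str]]


def _combine(sets: Sequence[frozenset[str]], mode: MergeMode) -> frozenset[str]:
    op = frozenset.union if mode is MergeMode.UNION else frozenset.intersection
    return reduce(op, sets)


def merge_within_dataset(
    ceg_sets: Sequence[CEGSet], mode: MergeMode | str
) -> frozenset[str]:
    """Merge the CEG sets of several lncRNAs from one dataset."""
    mode = MergeMode(mode)
    if not ceg_sets:
        raise ValidationError("no CEG sets to merge")
    dataset_ids = {c.dataset_id for c in ceg_sets}
    if len(dataset_ids) > 1:
        raise ValidationError(
            f"within-dataset merge got mixed datasets: {sorted(dataset_ids)}"
        )
    merged = _combine([c.members for c in ceg_sets], mode)
    if not merged:
        logger.warning(
            "%s merge of %d lncRNA CEG sets in %s is empty",
            mode.value,
            len(ceg_sets),
            next(iter(dataset_ids)),
        )
    return merged


def merge_across_datasets(
    per_dataset: Mapping[str, frozenset[str]],
    mode: MergeMode | str,
    spec: MergeSpec | None = None,
) -> MergedCEGs:
    """Merge per-dataset CEG sets into the integrative set."""
    mode = MergeMode(mode)
    if not per_dataset:
        raise ValidationError("no datasets to merge")
    members = _combine([frozenset(v) for v in per_dataset.values()], mode)
    if not members:
        logger.warning(
            "%s merge across %d datasets is empty", mode.value, len(per_dataset)
        )
    if spec is None:
        spec = MergeSpec(
            within_mode=mode,
            across_mode=mode,
            lnc_ids=("*",),
            dataset_ids=tuple(per_dataset),
        )
    return MergedCEGs(
        members=members,
        spec=spec,
        per_dataset_members={k: frozenset(v) for k, v in per_dataset.items()},
    )
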