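"""Descriptor naming and aggregation of detected interactions.

Every hit maps to a descriptor name encoding the partner class::

    M#CH_O#Ab          direct hit, antibody partner
    M#CH_O#Ag          direct hit, antigen partner
    M#HB_NH_O#S        direct hit with a water
    M#HB_NH_O#S#HB_OH_O#Ag   water-mediated bridge

For learning, descriptors are aggregated in one of two modes:

``grouped``
    Partner identity is erased (``M#CH_O#``), all target-water hits pool
    into ``M##S`` and all bridges into ``M##S##`` — 28 direct keys + 2
    water keys = 30 descriptors (appending the rotamer energy makes 31).

``individual``
    Water-related descriptors stay separate: ``M#X#S`` for each
    water-capable label X, ``M#X#S#X#`` for same-label bridges and
    ``M#X#S#Y#`` for mixed bridges (unordered label pairs), plus the 28
    direct keys.

Metal and ion labels are excluded from feature vectors by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Union

import pandas as pd

from .engine import InteractionHit, WaterBridge
from .rules import RuleRegistry, build_registry, water_can_participate

__all__ = [
    "DescriptorVector",
    "descriptor_name",
    "aggregate",
    "water_capable_labels",
    "grouped_descriptor_keys",
    "individual_descriptor_keys",
    "write_descriptor_table",
    "read_descriptor_table",
]

_VALID_CLASSES = ("Ab", "Ag", "S", "M")


def descriptor_name(item: Union[InteractionHit, WaterBridge]) -> str:
    """Full descriptor name of a hit or water bridge."""
    if isinstance(item, WaterBridge):
        return f"M#{item.leg1.label}#S#{item.leg2.label}#{item.partner_class}"
    if item.partner_class not in _VALID_CLASSES:
        raise ValueError(f"unknown partner class {item.partner_class!r}")
    if item.partner_class == "S":
        return f"M#{item.label}#S"
    return f"M#{item.label}#{item.partner_class}"


def water_capable_labels(registry: Optional[RuleRegistry] = None) -> List[str]:
    """Direct labels whose participant constraints admit a water side."""
    registry = registry or build_registry()
    return [label for label in registry.direct_labels
            if water_can_participate(registry[label])]


def grouped_descriptor_keys(registry: Optional[RuleRegistry] = None) -> List[str]:
    registry = registry or build_registry()
    return [f"M#{label}#" for label in registry.direct_labels] + ["M##S", "M##S##"]


def individual_descriptor_keys(registry: Optional[RuleRegistry] = None) -> List[str]:
    registry = registry or build_registry()
    water = water_capable_labels(registry)
    keys = [f"M#{label}#" for label in registry.direct_labels]
    keys += [f"M#{x}#S" for x in water]
    keys += [f"M#{x}#S#{x}#" for x in water]
    keys += [f"M#{x}#S#{y}#" for x, y in combinations(water, 2)]
    return keys


@dataclass
class DescriptorVector:
    mode: str
    counts: Dict[str, int]
    metadata: Dict[str, object] = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, dtype=int)

    def with_rotamer_energy(self, energy: float) -> "DescriptorVector":
        meta = dict(self.metadata)
        meta["rotamer_energy"] = float(energy)
        return DescriptorVector(mode=self.mode, counts=dict(self.counts), metadata=meta)


def aggregate(
    hits: Sequence[InteractionHit],
    bridges: Sequence[WaterBridge] = (),
    mode: str = "grouped",
    exclusions: Optional[Iterable[str]] = None,
    registry: Optional[RuleRegistry] = None,
    metadata: Optional[dict] = None,
) -> DescriptorVector:
    """Count hits/bridges into an ordered descriptor vector.

    ``exclusions`` defaults to the metal + ion labels.
    """
    registry = registry or build_registry()
    if exclusions is None:
        exclusions = set(registry.metal_labels) | set(registry.ion_labels)
    else:
        exclusions = set(exclusions)
    if mode == "grouped":
        keys = grouped_descriptor_keys(registry)
    elif mode == "individual":
        keys = individual_descriptor_keys(registry)
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    counts = {k: 0 for k in keys}
    water_order = water_capable_labels(registry)

    for h in hits:
        if h.label in exclusions:
            continue
        if h.partner_class == "S":
            if mode == "grouped":
                counts["M##S"] += 1
            else:
                counts[f"M#{h.label}#S"] += 1
        else:
            counts[f"M#{h.label}#"] += 1
    for b in bridges:
        if b.leg1.label in exclusions or b.leg2.label in exclusions:
            continue
        if mode == "grouped":
            counts["M##S##"] += 1
        else:
            x, y = sorted((b.leg1.label, b.leg2.label), key=water_order.index)
            counts[f"M#{x}#S#{y}#"] += 1
    return DescriptorVector(mode=mode, counts=counts, metadata=dict(metadata or {}))


_META_COLUMNS = ("structure_id", "target", "label", "cluster", "rotamer_energy")


def write_descriptor_table(vectors: Sequence[DescriptorVector], path,
                           registry: Optional[RuleRegistry] = None):
    """One CSV row per vector: metadata columns then descriptor counts."""
    if vectors:
        modes = {v.mode for v in vectors}
        if len(modes) > 1:
            raise ValueError(f"mixed descriptor modes in one table: {sorted(modes)}")
        keys = list(vectors[0].counts)
    else:
        keys = grouped_descriptor_keys(registry)
    rows = []
    for v in vectors:
        row = {c: v.metadata.get(c) for c in _META_COLUMNS}
        row.update(v.counts)
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(_META_COLUMNS) + keys)
    df.to_csv(path, index=False)


def read_descriptor_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
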