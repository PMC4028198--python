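"""Van Krevelen projection (O/C vs H/C) and CH2/O rhombus motif search.

Only carbon, hydrogen and oxygen enter the projection; other elements in a
chosen formula are ignored.  Points outside the conventional window
(O/C in [0, 1], H/C in [0, 2]) are flagged, never dropped.
"""
from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass

from .formula import ElementalComposition
from .matching import Feature, TransformationEdge

__all__ = ["VanKrevelenPoint", "van_krevelen", "find_rhombic_motifs", "CH2", "O1"]

logger = logging.getLogger(__name__)

CH2 = ElementalComposition({"C": 1, "H": 2})
O1 = ElementalComposition({"O": 1})

OC_BOUNDS = (0.0, 1.0)
HC_BOUNDS = (0.0, 2.0)


@dataclass(frozen=True)
class VanKrevelenPoint:
    feature_id: str
    formula: ElementalComposition
    oc_ratio: float
    hc_ratio: float
    time_label: str | None = None
    in_bounds: bool = True


def _choose_formula(
    feature: Feature, edges: list[TransformationEdge] | None
) -> ElementalComposition | None:
    """Pick the candidate with the most edge support, falling back to rank 1."""
    if not feature.candidates:
        return None
    if edges:
        support: dict[ElementalComposition, int] = {}
        for edge in edges:
            for source_comp, target_comp in edge.support:
                if edge.source == feature.id:
                    support[source_comp] = support.get(source_comp, 0) + 1
                if edge.target == feature.id:
                    support[target_comp] = support.get(target_comp, 0) + 1
        if support:
            best = max(
                feature.candidates,
                key=lambda c: (support.get(c.composition, 0), -c.rank),
            )
            if support.get(best.composition, 0) > 0:
                return best.composition
    return feature.candidates[0].composition


def van_krevelen(
    features: list[Feature],
    edges: list[TransformationEdge] | None = None,
) -> list[VanKrevelenPoint]:
    """One (O/C, H/C) point per feature with a carbon-containing formula.

    The plotted formula is the candidate participating in the most
    transformation edges when ``edges`` is provided, else the top-ranked
    candidate.  Features whose chosen formula lacks carbon are skipped with
    a warning (the ratios are undefined).
    """
    points: list[VanKrevelenPoint] = []
    for feature in features:
        comp = _choose_formula(feature, edges)
        if comp is None:
            logger.warning("feature %s has no candidate formulas; no point emitted", feature.id)
            continue
        carbons = comp.get("C")
        if carbons <= 0:
            logger.warning("feature %s formula has no carbon; no point emitted", feature.id)
            continue
        oc = comp.get("O") / carbons
        hc = comp.get("H") / carbons
        points.append(
            VanKrevelenPoint(
                feature_id=feature.id,
                formula=comp,
                oc_ratio=oc,
                hc_ratio=hc,
                time_label=str(feature.first_time),
                in_bounds=(OC_BOUNDS[0] <= oc <= OC_BOUNDS[1] and HC_BOUNDS[0] <= hc <= HC_BOUNDS[1]),
            )
        )
    return points


def find_rhombic_motifs(
    formulas: Mapping[str, ElementalComposition],
) -> list[tuple[str, str, str, str]]:
    """Find quadruples (a, b, c, d) with b = a+CH2, c = a+O, d = a+CH2+O.

    Such quadruples form a rhombus in van Krevelen space (interconnected by
    net CH2 and O shifts).  Exact composition arithmetic; returns sorted
    feature-id quadruples.
    """
    by_comp: dict[ElementalComposition, list[str]] = {}
    for fid, comp in formulas.items():
        by_comp.setdefault(comp, []).append(fid)
    motifs: list[tuple[str, str, str, str]] = []
    for comp, ids_a in sorted(by_comp.items(), key=lambda kv: sorted(kv[1])):
        ids_b = by_comp.get(comp + CH2, [])
        ids_c = by_comp.get(comp + O1, [])
        ids_d = by_comp.get(comp + CH2 + O1, [])
        for a in sorted(ids_a):
            for b in sorted(ids_b):
                for c in sorted(ids_c):
                    for d in sorted(ids_d):
                        motifs.append((a, b, c, d))
    return motifs
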