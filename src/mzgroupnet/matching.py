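"""Pairwise transformation detection between m/z features.

For every ordered feature pair and every candidate-formula pair, an edge is
emitted when the exact integer elemental difference equals a rule delta.
Matching is deliberately composition-based, not mass-tolerance-based: two
candidates connect only if ``target_formula - source_formula`` equals a
rule's delta element-wise, which is what lets a shared transformation pick
the right formula out of an ambiguous candidate list.

An optional chronology filter discards edges that run backwards in time
(a feature first seen later cannot be the precursor of one seen earlier).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .candidates import CandidateFormula
from .formula import ElementalComposition, MzValue, delta_mass, format_delta
from .rules import TransformationRule

__all__ = [
    "Feature",
    "TransformationEdge",
    "UnlistedDifference",
    "detect_transformations",
    "rank_rule_frequencies",
    "discover_unlisted",
]

logger = logging.getLogger(__name__)


@dataclass
class Feature:
    """One observed m/z with its time points and ranked candidate formulas."""

    id: str
    mz: MzValue
    time_points: frozenset[int]
    candidates: list[CandidateFormula] = field(default_factory=list)
    intensity: float | None = None

    def __post_init__(self) -> None:
        if not self.time_points:
            raise ValueError(f"feature {self.id!r} has no time points")
        self.time_points = frozenset(self.time_points)

    @property
    def first_time(self) -> int:
        """Smallest time-point index at which the feature was observed."""
        return min(self.time_points)


@dataclass
class TransformationEdge:
    """A directed match source -> target under one rule.

    ``source_formula``/``target_formula`` hold the best-ranked supporting
    candidate pair; ``support`` lists every candidate pair consistent with
    the rule (the edge itself is per feature pair, not per formula pair).
    """

    source: str
    target: str
    rule: str
    source_formula: ElementalComposition
    target_formula: ElementalComposition
    support: tuple[tuple[ElementalComposition, ElementalComposition], ...] = ()


@dataclass(frozen=True)
class UnlistedDifference:
    """A recurrent composition difference not covered by the rule set."""

    delta: ElementalComposition
    occurrence_count: int
    example_pairs: tuple[tuple[str, str], ...]


def detect_transformations(
    features: list[Feature],
    rules: list[TransformationRule],
    time_filter: bool = True,
) -> list[TransformationEdge]:
    """Find all rule-matching edges between feature pairs.

    For ordered pair (A, B) and candidate pair (fA, fB), an edge A -> B
    under rule r exists iff ``fB - fA == r.delta`` exactly.  Multiple
    candidate pairs supporting the same (A, B, rule) collapse into a single
    edge.  With ``time_filter`` on, edges with ``A.first_time >
    B.first_time`` are discarded.
    """
    if not rules:
        raise ValueError("empty rule set")
    ids = [f.id for f in features]
    if len(set(ids)) != len(ids):
        raise ValueError("feature ids are not unique")

    matchable: list[Feature] = []
    for feat in features:
        if not feat.candidates:
            logger.warning("feature %s has no candidate formulas; skipped", feat.id)
            continue
        matchable.append(feat)

    # Index every candidate composition -> features that carry it.
    comp_index: dict[ElementalComposition, list[Feature]] = {}
    for feat in matchable:
        for cand in feat.candidates:
            comp_index.setdefault(cand.composition, []).append(feat)

    feature_order = {feat.id: i for i, feat in enumerate(matchable)}
    rule_order = {rule.name: i for i, rule in enumerate(rules)}
    found: dict[tuple[str, str, str], TransformationEdge] = {}
    for rule in rules:
        for feat in matchable:
            for cand in feat.candidates:  # rank order: first support is best-ranked
                target_comp = cand.composition + rule.delta
                if not target_comp.is_nonnegative():
                    continue
                for other in comp_index.get(target_comp, ()):
                    if other.id == feat.id:
                        continue
                    if time_filter and feat.first_time > other.first_time:
                        continue
                    key = (feat.id, other.id, rule.name)
                    edge = found.get(key)
                    if edge is None:
                        found[key] = TransformationEdge(
                            source=feat.id,
                            target=other.id,
                            rule=rule.name,
                            source_formula=cand.composition,
                            target_formula=target_comp,
                            support=((cand.composition, target_comp),),
                        )
                    else:
                        edge.support = edge.support + ((cand.composition, target_comp),)

    return sorted(
        found.values(),
        key=lambda e: (feature_order[e.source], feature_order[e.target], rule_order[e.rule]),
    )


def rank_rule_frequencies(
    edges: list[TransformationEdge],
    rules: list[TransformationRule] | None = None,
) -> list[tuple[str, int]]:
    """Count edges per rule, sorted by count descending.

    Ties are broken by rule-file order when ``rules`` is given, otherwise by
    order of first appearance in the edge list.
    """
    counts: dict[str, int] = {}
    for edge in edges:
        counts[edge.rule] = counts.get(edge.rule, 0) + 1
    if rules is not None:
        tie_order = {rule.name: i for i, rule in enumerate(rules)}
    else:
        tie_order = {name: i for i, name in enumerate(counts)}
    return sorted(counts.items(), key=lambda item: (-item[1], tie_order.get(item[0], len(tie_order))))


def discover_unlisted(
    features: list[Feature],
    rules: list[TransformationRule],
    min_count: int = 2,
    max_delta_mass: float = 300.0,
) -> list[UnlistedDifference]:
    """Mine recurrent candidate-pair differences not present in the rule set.

    Pairs are oriented from the lower to the higher observed m/z; only
    differences with ``0 < delta mass <= max_delta_mass`` are counted, and a
    feature pair contributes at most once per distinct delta.  Returned
    sorted by occurrence count descending (ties: delta string).
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    known = {rule.delta for rule in rules}
    ordered = sorted((f for f in features if f.candidates), key=lambda f: f.mz.mz)
    groups: dict[ElementalComposition, set[tuple[str, str]]] = {}
    for i, low in enumerate(ordered):
        for high in ordered[i + 1 :]:
            # candidate masses track the observed m/z to within the ppm
            # window, so the observed difference prescreens the pair
            if high.mz.mz - low.mz.mz > max_delta_mass + 1.0:
                break
            deltas_seen: set[ElementalComposition] = set()
            for ca in low.candidates:
                for cb in high.candidates:
                    delta = cb.composition - ca.composition
                    if not delta or delta in known or delta in deltas_seen:
                        continue
                    mass = delta_mass(delta)
                    if not 0 < mass <= max_delta_mass:
                        continue
                    deltas_seen.add(delta)
                    groups.setdefault(delta, set()).add((low.id, high.id))
    out = [
        UnlistedDifference(
            delta=delta,
            occurrence_count=len(pairs),
            example_pairs=tuple(sorted(pairs)),
        )
        for delta, pairs in groups.items()
        if len(pairs) >= min_count
    ]
    out.sort(key=lambda u: (-u.occurrence_count, format_delta(u.delta)))
    return out
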