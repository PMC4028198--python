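"""Feature-table readers, result-file writers and the pipeline orchestrator.

Input is one delimited table per time point (columns: optional ``id``,
``mz``, optional ``rt``/``intensity``, then ``formula_k``/``ppm_k`` pairs).
Rows are merged across time points by m/z proximity.  A pipeline run
produces five result artifacts: the transformations table, the
rule-frequency ranking, the unlisted-difference suggestions, a JSON results
bundle, and a Pajek network file (plus pathway and van Krevelen CSVs).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .candidates import DEFAULT_BOUNDS, CandidateFormula, generate_candidates
from .formula import (
    ElementalComposition,
    FormulaError,
    MzValue,
    format_delta,
    format_formula,
    monoisotopic_mz,
    parse_formula,
)
from .matching import (
    Feature,
    TransformationEdge,
    UnlistedDifference,
    detect_transformations,
    discover_unlisted,
    rank_rule_frequencies,
)
from .network import (
    Pathway,
    TransformationNetwork,
    build_network,
    enumerate_pathways,
    export_pajek,
    filter_pathways,
)
from .rules import TransformationRule, default_rules, load_rules
from .vankrevelen import VanKrevelenPoint, van_krevelen

__all__ = [
    "RunConfig",
    "PipelineResult",
    "read_feature_tables",
    "write_transformations",
    "read_transformations",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed for one pipeline run."""

    inputs: list[str | Path]
    out_dir: str | Path
    rules_path: str | Path | None = None
    tolerance_ppm: float = 1.0
    bounds: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    max_candidates: int = 10
    time_filter: bool = True
    max_path_length: int = 20
    novel_min_count: int = 2
    novel_max_delta_mass: float = 300.0
    mz_range: tuple[float, float] | None = None
    time_points: set[int] | None = None
    merge_ppm: float = 2.0
    strict: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tolerance_ppm > 0:
            raise ValueError("tolerance_ppm must be positive")


@dataclass
class PipelineResult:
    features: list[Feature]
    edges: list[TransformationEdge]
    network: TransformationNetwork
    pathways: list[Pathway]
    frequencies: list[tuple[str, int]]
    unlisted: list[UnlistedDifference]
    vk_points: list[VanKrevelenPoint]
    output_files: dict[str, Path]


def _parse_candidates(row: pd.Series, columns: list[str]) -> list[CandidateFormula]:
    cands = []
    k = 1
    while f"formula_{k}" in columns:
        text = row.get(f"formula_{k}")
        if text is None or (isinstance(text, float) and pd.isna(text)) or not str(text).strip():
            k += 1
            continue
        comp = parse_formula(str(text))
        ppm_raw = row.get(f"ppm_{k}")
        ppm = float(ppm_raw) if ppm_raw is not None and str(ppm_raw).strip() != "" and not pd.isna(ppm_raw) else 0.0
        cands.append(
            CandidateFormula(
                composition=comp,
                theoretical_mz=monoisotopic_mz(comp, 1),
                ppm_error=ppm,
                rank=len(cands) + 1,
            )
        )
        k += 1
    return cands


def read_feature_tables(
    paths: list[str | Path],
    merge_ppm: float = 2.0,
    strict: bool = False,
) -> list[Feature]:
    """Read per-time-point tables and merge rows into features by m/z.

    The time-point index of a row is the position of its file in ``paths``.
    Rows whose m/z matches an existing feature within ``merge_ppm`` merge
    into it (adding the time point); candidate lists come from the first
    table that provides them.  Malformed rows are logged and skipped
    (``strict=True`` turns any skip into an error).
    """
    if not paths:
        raise ValueError("empty file list")
    features: list[Feature] = []
    skipped = 0
    for time_index, path in enumerate(paths):
        table = pd.read_csv(path, sep=None, engine="python")
        table.columns = [str(c).strip() for c in table.columns]
        if "mz" not in table.columns:
            raise ValueError(f"{path}: no 'mz' column")
        columns = list(table.columns)
        ids_in_file: set[str] = set()
        for _, row in table.iterrows():
            try:
                mz = float(row["mz"])
                if not mz > 0:
                    raise ValueError(f"non-positive m/z {mz}")
                explicit_id = None
                if "id" in columns and not pd.isna(row["id"]) and str(row["id"]).strip():
                    explicit_id = str(row["id"]).strip()
                    if explicit_id in ids_in_file:
                        raise ValueError(f"duplicate feature id {explicit_id!r} in {path}")
                    ids_in_file.add(explicit_id)
                cands = _parse_candidates(row, columns)
                intensity = None
                if "intensity" in columns and not pd.isna(row.get("intensity")):
                    intensity = float(row["intensity"])
            except (ValueError, FormulaError) as exc:
                if "duplicate feature id" in str(exc):
                    raise
                logger.warning("%s: skipping malformed row: %s", path, exc)
                skipped += 1
                continue

            merged = False
            for feat in features:
                if abs(feat.mz.mz - mz) / feat.mz.mz * 1e6 <= merge_ppm:
                    feat.time_points = frozenset(feat.time_points | {time_index})
                    if not feat.candidates and cands:
                        feat.candidates = cands
                    merged = True
                    break
            if not merged:
                features.append(
                    Feature(
                        id=explicit_id or f"{mz:.5f}@t{time_index}",
                        mz=MzValue(mz, 1),
                        time_points=frozenset({time_index}),
                        candidates=cands,
                        intensity=intensity,
                    )
                )
    if not features:
        raise ValueError("no parsable feature rows in the given tables")
    if strict and skipped:
        raise ValueError(f"{skipped} malformed rows skipped in strict mode")
    return features


def write_transformations(
    edges: list[TransformationEdge], features: list[Feature], path: str | Path
) -> None:
    """Result file 1: the transformations table."""
    by_id = {f.id: f for f in features}
    rows = []
    for edge in edges:
        src, tgt = by_id[edge.source], by_id[edge.target]
        rows.append(
            {
                "source_id": edge.source,
                "target_id": edge.target,
                "rule": edge.rule,
                "source_formula": format_formula(edge.source_formula),
                "target_formula": format_formula(edge.target_formula),
                "source_mz": round(src.mz.mz, 6),
                "target_mz": round(tgt.mz.mz, 6),
                "source_first_time": src.first_time,
                "target_first_time": tgt.first_time,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "source_id", "target_id", "rule", "source_formula", "target_formula",
            "source_mz", "target_mz", "source_first_time", "target_first_time",
        ],
    ).to_csv(path, index=False)


def read_transformations(path: str | Path) -> list[TransformationEdge]:
    """Re-read a transformations table written by :func:`write_transformations`."""
    table = pd.read_csv(path)
    edges = []
    for _, row in table.iterrows():
        source_comp = parse_formula(row["source_formula"])
        target_comp = parse_formula(row["target_formula"])
        edges.append(
            TransformationEdge(
                source=str(row["source_id"]),
                target=str(row["target_id"]),
                rule=str(row["rule"]),
                source_formula=source_comp,
                target_formula=target_comp,
                support=((source_comp, target_comp),),
            )
        )
    return edges


def _write_frequencies(freqs: list[tuple[str, int]], path: Path) -> None:
    pd.DataFrame(freqs, columns=["rule", "count"]).to_csv(path, index=False)


def _write_unlisted(unlisted: list[UnlistedDifference], path: Path) -> None:
    from .formula import delta_mass

    rows = [
        {
            "delta": format_delta(u.delta),
            "delta_mass": round(delta_mass(u.delta), 5),
            "count": u.occurrence_count,
            "example_pairs": ";".join(f"{a}->{b}" for a, b in u.example_pairs),
        }
        for u in unlisted
    ]
    pd.DataFrame(rows, columns=["delta", "delta_mass", "count", "example_pairs"]).to_csv(
        path, index=False
    )


def _write_pathways(paths_: list[Pathway], net: TransformationNetwork, path: Path) -> None:
    rows = [
        {
            "n_nodes": len(p.nodes),
            "nodes": ";".join(p.nodes),
            "rules": ";".join(p.rules),
            "mz_sequence": ";".join(
                f"{net.graph.nodes[n].get('mz', float('nan')):.4f}" for n in p.nodes
            ),
        }
        for p in paths_
    ]
    pd.DataFrame(rows, columns=["n_nodes", "nodes", "rules", "mz_sequence"]).to_csv(
        path, index=False
    )


def _write_vk(points: list[VanKrevelenPoint], path: Path) -> None:
    rows = [
        {
            "feature_id": p.feature_id,
            "formula": format_formula(p.formula),
            "oc_ratio": round(p.oc_ratio, 6),
            "hc_ratio": round(p.hc_ratio, 6),
            "group": p.time_label or "",
            "in_bounds": p.in_bounds,
        }
        for p in points
    ]
    pd.DataFrame(
        rows, columns=["feature_id", "formula", "oc_ratio", "hc_ratio", "group", "in_bounds"]
    ).to_csv(path, index=False)


def _write_bundle(result: "PipelineResult", rules: list[TransformationRule], path: Path) -> None:
    """Result file 4: a documented JSON container of all run products."""
    bundle = {
        "features": [
            {
                "id": f.id,
                "mz": f.mz.mz,
                "charge": f.mz.charge,
                "first_time": f.first_time,
                "time_points": sorted(f.time_points),
                "candidates": [
                    {
                        "formula": format_formula(c.composition),
                        "theoretical_mz": c.theoretical_mz,
                        "ppm_error": c.ppm_error,
                        "rank": c.rank,
                    }
                    for c in f.candidates
                ],
            }
            for f in result.features
        ],
        "rules": [
            {"name": r.name, "delta": format_delta(r.delta), "delta_mass": r.delta_mass}
            for r in rules
        ],
        "edges": [
            {
                "source": e.source,
                "target": e.target,
                "rule": e.rule,
                "source_formula": format_formula(e.source_formula),
                "target_formula": format_formula(e.target_formula),
            }
            for e in result.edges
        ],
        "pathways": [
            {"nodes": list(p.nodes), "rules": list(p.rules)} for p in result.pathways
        ],
        "rule_frequencies": [{"rule": name, "count": n} for name, n in result.frequencies],
    }
    path.write_text(json.dumps(bundle, indent=1, sort_keys=True), encoding="utf-8")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis: read, match, network, pathways, exports.

    Writes the five result artifacts (plus pathway and van Krevelen CSVs)
    into ``config.out_dir`` and returns everything in memory as well.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rules = load_rules(config.rules_path) if config.rules_path else default_rules()
    if not rules:
        raise ValueError("empty rule set")
    logger.info("loaded %d rules", len(rules))

    features = read_feature_tables(
        config.inputs, merge_ppm=config.merge_ppm, strict=config.strict
    )
    logger.info("read %d features from %d tables", len(features), len(config.inputs))

    for feat in features:
        if not feat.candidates:
            feat.candidates = generate_candidates(
                feat.mz,
                config.tolerance_ppm,
                config.bounds,
                max_candidates=config.max_candidates,
            )
    logger.info(
        "features with candidates: %d", sum(1 for f in features if f.candidates)
    )

    edges = detect_transformations(features, rules, time_filter=config.time_filter)
    logger.info("detected %d transformation edges", len(edges))

    net = build_network(edges, features)
    pathways = enumerate_pathways(net, max_length=config.max_path_length)
    pathways = filter_pathways(
        pathways, net, mz_range=config.mz_range, time_points=config.time_points
    )
    logger.info("extracted %d non-redundant pathways", len(pathways))

    frequencies = rank_rule_frequencies(edges, rules)
    unlisted = discover_unlisted(
        features,
        rules,
        min_count=config.novel_min_count,
        max_delta_mass=config.novel_max_delta_mass,
    )
    logger.info("%d unlisted-difference suggestions", len(unlisted))

    vk_points = van_krevelen(features, edges)

    files = {
        "transformations": out_dir / "transformations.csv",
        "rule_frequency": out_dir / "rule_frequency.csv",
        "unlisted": out_dir / "unlisted_differences.csv",
        "bundle": out_dir / "mzstructure.json",
        "pajek": out_dir / "network.net",
        "pathways": out_dir / "pathways.csv",
        "vankrevelen": out_dir / "vankrevelen.csv",
    }
    result = PipelineResult(
        features=features,
        edges=edges,
        network=net,
        pathways=pathways,
        frequencies=frequencies,
        unlisted=unlisted,
        vk_points=vk_points,
        output_files=files,
    )
    write_transformations(edges, features, files["transformations"])
    _write_frequencies(frequencies, files["rule_frequency"])
    _write_unlisted(unlisted, files["unlisted"])
    _write_bundle(result, rules, files["bundle"])
    export_pajek(net, files["pajek"])
    _write_pathways(pathways, net, files["pathways"])
    _write_vk(vk_points, files["vankrevelen"])
    return result
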