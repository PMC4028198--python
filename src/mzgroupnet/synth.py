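"""Deterministic synthetic fixtures: a planted anthocyanin-like chain plus decoys.

The default fixture plants a seven-member acylated-glycoside chain whose
cation m/z values are nominally 287, 449, 595, 727, 889, 975 and 1121, with
an appearance schedule over six sampling days (287 from the start, 449 from
day 2, the rest from day 4).  Decoy features are random CHO formulas whose
observed masses are rejection-sampled so that no default rule can connect
them - directly or via any 1 ppm candidate - to any other feature.  Every
draw is governed by a single seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .candidates import DEFAULT_BOUNDS, CandidateFormula, generate_candidates
from .formula import ElementalComposition, MzValue, format_formula, monoisotopic_mz, parse_formula
from .matching import Feature
from .rules import default_rules

__all__ = ["FixtureSpec", "generate_fixture", "write_fixture", "PLANTED_CHAIN", "CHAIN_RULES"]

#: The planted chain: (formula, first time-point index).  Intermediate
#: members are the anchor formulas minus the corresponding rule deltas.
PLANTED_CHAIN: tuple[tuple[str, int], ...] = (
    ("C15H11O6", 0),   # nominal m/z 287, present from day 0
    ("C21H21O11", 1),  # 449, from day 2
    ("C30H27O13", 2),  # 595, from day 4
    ("C35H35O17", 2),  # 727
    ("C41H45O22", 2),  # 889
    ("C44H47O25", 2),  # 975
    ("C53H53O27", 2),  # 1121
)

#: Rule names joining consecutive chain members.
CHAIN_RULES: tuple[str, ...] = (
    "hexosylation",
    "coumaroylation",
    "pentosylation",
    "hexosylation",
    "malonylation",
    "coumaroylation",
)

#: Sampling-day labels for the six default time points.
DEFAULT_TIME_POINTS: tuple[int, ...] = (0, 2, 4, 8, 14, 20)

# Guard bands for decoy rejection sampling (Da).  An exact composition match
# to a rule forces the observed mass difference to sit within the combined
# ppm windows (< 4e-3 Da up to m/z 2000), so these margins make decoys
# unconnectable by construction.
_MASS_GUARD = 0.05
_RULE_GUARD = 0.02


@dataclass
class FixtureSpec:
    """Parameters fully determining a synthetic data set."""

    time_points: tuple[int, ...] = DEFAULT_TIME_POINTS
    planted_chain: tuple[tuple[str, int], ...] = PLANTED_CHAIN
    n_decoys: int = 50
    decoy_mass_range: tuple[float, float] = (150.0, 1500.0)
    ppm_noise_sd: float = 0.3
    n_false_candidates: int = 9
    seed: int = 0
    tolerance_ppm: float = 1.0
    bounds: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))

    def __post_init__(self) -> None:
        firsts = [t for _, t in self.planted_chain]
        if firsts != sorted(firsts):
            raise ValueError("planted first_times must be non-decreasing along the chain")
        if any(t >= len(self.time_points) for t in firsts):
            raise ValueError("planted first_time index outside the time grid")


def _candidate_list(
    observed_mz: float, true_comp: ElementalComposition, spec: FixtureSpec
) -> list[CandidateFormula]:
    cands = generate_candidates(
        observed_mz,
        spec.tolerance_ppm,
        spec.bounds,
        max_candidates=spec.n_false_candidates + 1,
    )
    if all(c.composition != true_comp for c in cands):
        # the true formula always sits within the window; keep it in the
        # list even when crowded out by closer-ppm decoy formulas
        theo = monoisotopic_mz(true_comp, 1)
        truth = CandidateFormula(
            composition=true_comp,
            theoretical_mz=theo,
            ppm_error=(observed_mz - theo) / observed_mz * 1e6,
            rank=len(cands) or 1,
        )
        cands = cands[: max(len(cands) - 1, 0)] + [truth]
        cands = [
            CandidateFormula(c.composition, c.theoretical_mz, c.ppm_error, rank=i + 1)
            for i, c in enumerate(sorted(cands, key=lambda c: abs(c.ppm_error)))
        ]
    return cands


def _noisy(theo: float, rng: np.random.Generator, sd_ppm: float) -> float:
    if sd_ppm == 0:
        return theo
    eps = rng.normal(0.0, sd_ppm)
    while abs(eps) > 0.9:  # stay safely inside the 1 ppm candidate window
        eps = rng.normal(0.0, sd_ppm)
    return theo * (1.0 + eps * 1e-6)


def generate_fixture(spec: FixtureSpec) -> tuple[list[Feature], dict[int, pd.DataFrame]]:
    """Build the fixture features and their per-time-point tables.

    Returns ``(features, tables)`` where ``tables`` maps each time-point
    label to a feature table in the package CSV schema.  Identical specs
    (same seed) produce identical output.
    """
    rng = np.random.default_rng(spec.seed)
    rules = default_rules()
    rule_masses = np.array([r.delta_mass for r in rules])

    features: list[Feature] = []
    masses: list[float] = []

    for formula_text, first in spec.planted_chain:
        comp = parse_formula(formula_text)
        theo = monoisotopic_mz(comp, 1)
        observed = _noisy(theo, rng, spec.ppm_noise_sd)
        features.append(
            Feature(
                id=f"M{round(theo)}",
                mz=MzValue(observed, 1),
                time_points=frozenset(range(first, len(spec.time_points))),
                candidates=_candidate_list(observed, comp, spec),
                intensity=float(np.round(rng.lognormal(12, 1), 2)),
            )
        )
        masses.append(observed)

    n_accepted = 0
    attempts = 0
    while n_accepted < spec.n_decoys:
        attempts += 1
        if attempts > 200 * max(spec.n_decoys, 1):
            raise RuntimeError("decoy rejection sampling failed to converge")
        c = int(rng.integers(8, 61))
        h = int(rng.integers(max(c // 2, 1), 2 * c + 3))
        o = int(rng.integers(0, min(50, c) + 1))
        comp = ElementalComposition({"C": c, "H": h, "O": o})
        theo = monoisotopic_mz(comp, 1)
        if not spec.decoy_mass_range[0] <= theo <= spec.decoy_mass_range[1]:
            continue
        observed = _noisy(theo, rng, spec.ppm_noise_sd)
        if masses:
            diffs = observed - np.array(masses)
            if np.min(np.abs(diffs)) < _MASS_GUARD:
                continue
            gaps = np.abs(np.concatenate([diffs, -diffs])[:, None] - rule_masses[None, :])
            if gaps.min() < _RULE_GUARD:
                continue
        first = int(rng.integers(0, len(spec.time_points)))
        n_accepted += 1
        features.append(
            Feature(
                id=f"D{n_accepted:03d}",
                mz=MzValue(observed, 1),
                time_points=frozenset(range(first, len(spec.time_points))),
                candidates=_candidate_list(observed, comp, spec),
                intensity=float(np.round(rng.lognormal(10, 1), 2)),
            )
        )
        masses.append(observed)

    features.sort(key=lambda f: f.mz.mz)
    tables = {
        label: _table_for_time(features, index)
        for index, label in enumerate(spec.time_points)
    }
    return features, tables


def _table_for_time(features: list[Feature], index: int) -> pd.DataFrame:
    rows = []
    width = max((len(f.candidates) for f in features), default=0)
    for feat in features:
        if index not in feat.time_points:
            continue
        row: dict[str, object] = {
            "id": feat.id,
            "mz": round(feat.mz.mz, 6),
            "intensity": feat.intensity,
        }
        for k in range(width):
            if k < len(feat.candidates):
                cand = feat.candidates[k]
                row[f"formula_{k + 1}"] = format_formula(cand.composition)
                row[f"ppm_{k + 1}"] = round(cand.ppm_error, 4)
            else:
                row[f"formula_{k + 1}"] = ""
                row[f"ppm_{k + 1}"] = ""
        rows.append(row)
    return pd.DataFrame(rows)


def write_fixture(
    tables: dict[int, pd.DataFrame], out_dir: str | Path
) -> list[Path]:
    """Write one CSV per time point; returns the paths in time order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, (label, table) in enumerate(tables.items()):
        path = out_dir / f"t{i}_day{label:02d}.csv"
        table.to_csv(path, index=False)
        paths.append(path)
    return paths
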