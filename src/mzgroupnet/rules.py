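"""Transformation-rule representation and the rules-file reader/writer.

A rule is a named, signed elemental-composition delta (e.g. methylation =
+1C+2H).  Rules are applied as directed deltas; a reverse reaction must be
listed as its own entry.  A default set of 56 biochemically common rules
ships with the package and can be replaced by any user-edited CSV with the
same layout (``name,delta,note``).
"""
from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from . import formula
from .formula import ElementalComposition, FormulaError, format_delta, parse_delta

__all__ = ["TransformationRule", "RulesError", "load_rules", "write_rules", "default_rules", "rule_by_name"]


class RulesError(ValueError):
    """Raised when a rules file fails validation."""


@dataclass(frozen=True)
class TransformationRule:
    """A named chemical/biochemical modification expressed as a composition delta."""

    name: str
    delta: ElementalComposition
    note: str = ""

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise RulesError("rule name must be nonempty")
        if not self.delta:
            raise RulesError(f"rule {self.name!r} has a zero delta")

    @property
    def delta_mass(self) -> float:
        """Signed monoisotopic mass shift of this rule in Da."""
        return formula.delta_mass(self.delta)


def _parse_rows(rows: Iterable[list[str]], origin: str) -> list[TransformationRule]:
    rules: list[TransformationRule] = []
    seen: set[str] = set()
    header_skipped = False
    for lineno, row in enumerate(rows, start=1):
        if not row or not any(cell.strip() for cell in row):
            continue
        cells = [cell.strip() for cell in row]
        if not header_skipped:
            header_skipped = True
            if cells[0].lower() == "name":
                continue  # header row
        name = cells[0]
        delta_text = cells[1] if len(cells) > 1 else ""
        note = cells[2] if len(cells) > 2 else ""
        try:
            delta = parse_delta(delta_text)
        except FormulaError as exc:
            raise RulesError(f"{origin}, row {lineno}: bad delta for rule {name!r}: {exc}") from exc
        if not delta:
            raise RulesError(f"{origin}, row {lineno}: rule {name!r} has a zero delta")
        if name in seen:
            raise RulesError(f"{origin}, row {lineno}: duplicate rule name {name!r}")
        seen.add(name)
        rules.append(TransformationRule(name=name, delta=delta, note=note))
    return rules


def load_rules(path: str | Path) -> list[TransformationRule]:
    """Load and validate a rules CSV, preserving file order.

    Layout: header ``name,delta,note``; the delta column uses the signed
    token dialect (``+1C+2H``, ``-2H+1O``) or a plain formula (``C1H2``).
    Zero deltas, duplicate names and unparsable tokens are rejected with
    the offending row number.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        sample = handle.read()
    dialect_delim = "\t" if ("\t" in sample.splitlines()[0] if sample.splitlines() else False) else ","
    reader = csv.reader(io.StringIO(sample), delimiter=dialect_delim)
    rules = _parse_rows(reader, origin=str(path))
    if not rules:
        raise RulesError(f"{path}: no rules found")
    return rules


def write_rules(rules: Iterable[TransformationRule], path: str | Path) -> None:
    """Write rules to CSV in the canonical ``name,delta,note`` layout."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["name", "delta", "note"])
        for rule in rules:
            writer.writerow([rule.name, format_delta(rule.delta), rule.note])


def default_rules() -> list[TransformationRule]:
    """The packaged default rule set (56 transformations)."""
    source = resources.files("mzgroupnet").joinpath("data/default_rules.csv")
    reader = csv.reader(io.StringIO(source.read_text(encoding="utf-8")))
    return _parse_rows(reader, origin="default_rules.csv")


def rule_by_name(rules: Iterable[TransformationRule], name: str) -> TransformationRule:
    """Look a rule up by name, raising ``KeyError`` if absent."""
    for rule in rules:
        if rule.name == name:
            return rule
    raise KeyError(name)
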