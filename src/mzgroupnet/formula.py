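"""Elemental-composition algebra and exact monoisotopic mass computation.

All downstream matching is integer arithmetic on element counts; masses are
only needed to reproduce exact m/z values and to screen candidate formulas.
Monoisotopic masses follow CODATA/IUPAC recommendations; ions are handled
with an explicit electron-mass correction (intrinsic cations such as
flavylium ions are [M]+, not [M+H]+).
"""
from __future__ import annotations

import re
from collections.abc import Mapping
from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "FormulaError",
    "ElementalComposition",
    "MzValue",
    "parse_formula",
    "parse_delta",
    "format_formula",
    "format_delta",
    "monoisotopic_mz",
    "delta_mass",
    "composition_difference",
]

#: Monoisotopic atomic masses in Da (most abundant isotope).
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "F": 18.99840322,
    "Cl": 34.96885271,
    "Br": 78.9183376,
    "I": 126.904468,
    "Na": 22.98976928,
    "K": 38.9637069,
    "Si": 27.9769265327,
    "Se": 79.9165218,
    "B": 11.0093055,
}

#: Electron rest mass in Da.
ELECTRON_MASS = 0.00054857990946


class FormulaError(ValueError):
    """Raised for malformed formula/delta strings or invalid compositions."""


class ElementalComposition(Mapping):
    """Immutable map from element symbol to a signed integer count.

    Canonical form: elements with count zero are absent.  Supports
    element-wise ``+``, ``-``, unary negation and integer scaling, so it
    doubles as both a molecular formula (non-negative counts) and a
    transformation delta (signed counts).
    """

    __slots__ = ("_counts", "_hash")

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        merged: dict[str, int] = {}
        for source in (counts or {}), kwargs:
            for element, n in source.items():
                if not isinstance(element, str) or not re.fullmatch(r"[A-Z][a-z]?", element):
                    raise FormulaError(f"invalid element symbol: {element!r}")
                if not isinstance(n, (int,)) or isinstance(n, bool):
                    raise FormulaError(f"count for {element} must be an integer, got {n!r}")
                merged[element] = merged.get(element, 0) + n
        self._counts = {el: n for el, n in sorted(merged.items()) if n != 0}
        self._hash = hash(tuple(self._counts.items()))

    # -- Mapping protocol -------------------------------------------------
    def __getitem__(self, element: str) -> int:
        return self._counts[element]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def get(self, element: str, default: int = 0) -> int:  # type: ignore[override]
        return self._counts.get(element, default)

    # -- algebra ----------------------------------------------------------
    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        if not isinstance(other, ElementalComposition):
            return NotImplemented
        keys = set(self._counts) | set(other._counts)
        return ElementalComposition({k: self.get(k) + other.get(k) for k in keys})

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        if not isinstance(other, ElementalComposition):
            return NotImplemented
        keys = set(self._counts) | set(other._counts)
        return ElementalComposition({k: self.get(k) - other.get(k) for k in keys})

    def __neg__(self) -> "ElementalComposition":
        return ElementalComposition({k: -n for k, n in self._counts.items()})

    def __mul__(self, factor: int) -> "ElementalComposition":
        if not isinstance(factor, int):
            return NotImplemented
        return ElementalComposition({k: n * factor for k, n in self._counts.items()})

    __rmul__ = __mul__

    # -- identity ---------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementalComposition):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {k: v for k, v in other.items() if v != 0}
        return NotImplemented

    def __hash__(self) -> int:
        return self._hash

    def __bool__(self) -> bool:
        return bool(self._counts)

    def is_nonnegative(self) -> bool:
        return all(n >= 0 for n in self._counts.values())

    def __repr__(self) -> str:
        return f"ElementalComposition({self._counts!r})"

    def __str__(self) -> str:
        if not self._counts:
            return ""
        if self.is_nonnegative():
            return format_formula(self)
        return format_delta(self)


@dataclass(frozen=True)
class MzValue:
    """A mass-to-charge ratio in Da per unit charge with its signed charge."""

    mz: float
    charge: int = 1

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"m/z must be positive, got {self.mz}")
        if abs(self.charge) < 1 or not isinstance(self.charge, int):
            raise ValueError(f"charge must be a nonzero integer, got {self.charge}")


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_FORMULA_SHAPE = re.compile(r"(?:[A-Z][a-z]?\d*)+")
_DELTA_TOKEN = re.compile(r"([+-])\s*(\d*)\s*([A-Z][a-z]?)")


def _hill_order(elements) -> list[str]:
    """Hill convention: C first, H second when carbon present, else alphabetical."""
    elements = sorted(elements)
    if "C" in elements:
        head = [el for el in ("C", "H") if el in elements]
        return head + [el for el in elements if el not in ("C", "H")]
    return elements


def parse_formula(text: str) -> ElementalComposition:
    """Parse a molecular formula string into a composition.

    Accepts the plain dialect ``C32H39O20`` and the underscore-delimited
    dialect ``C_32_H_39_O_20_``; an element without a number counts once.
    """
    if text is None or not str(text).strip():
        raise FormulaError("empty formula string")
    cleaned = str(text).strip().replace("_", "").replace(" ", "")
    if not _FORMULA_SHAPE.fullmatch(cleaned):
        raise FormulaError(f"malformed formula string: {text!r}")
    counts: dict[str, int] = {}
    for element, digits in _FORMULA_TOKEN.findall(cleaned):
        if element not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    return ElementalComposition(counts)


def parse_delta(text: str) -> ElementalComposition:
    """Parse a signed composition delta.

    Accepts the signed-token dialect ``+1C+2H`` / ``-2H+1O`` (count defaults
    to 1, e.g. ``+C``) as well as the plain all-positive formula dialect
    ``C1H2``.
    """
    if text is None or not str(text).strip():
        raise FormulaError("empty delta string")
    cleaned = str(text).strip().replace(" ", "")
    if cleaned[0] not in "+-":
        return parse_formula(cleaned)
    pos = 0
    counts: dict[str, int] = {}
    for match in _DELTA_TOKEN.finditer(cleaned):
        if match.start() != pos:
            raise FormulaError(f"malformed delta string: {text!r}")
        sign, digits, element = match.groups()
        if element not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {element!r} in {text!r}")
        n = int(digits) if digits else 1
        counts[element] = counts.get(element, 0) + (n if sign == "+" else -n)
        pos = match.end()
    if pos != len(cleaned):
        raise FormulaError(f"malformed delta string: {text!r}")
    return ElementalComposition(counts)


def format_formula(comp: ElementalComposition) -> str:
    """Format a non-negative composition in Hill order (``C32H39O20``)."""
    if not comp.is_nonnegative():
        raise FormulaError(f"cannot format negative counts as a formula: {dict(comp)}; use format_delta")
    return "".join(
        f"{el}{comp[el]}" if comp[el] != 1 else el for el in _hill_order(comp)
    )


def format_delta(comp: ElementalComposition) -> str:
    """Format a signed delta in the ``+1C+2H`` token dialect."""
    return "".join(f"{comp[el]:+d}{el}" for el in _hill_order(comp))


def delta_mass(delta: ElementalComposition) -> float:
    """Signed monoisotopic mass of a composition delta in Da (no electron term)."""
    try:
        return sum(n * MONOISOTOPIC_MASS[el] for el, n in delta.items())
    except KeyError as exc:  # pragma: no cover - compositions are validated upstream
        raise FormulaError(f"no monoisotopic mass for element {exc.args[0]!r}") from exc


def monoisotopic_mz(comp: ElementalComposition, charge: int = 1) -> float:
    """Exact m/z of an intact ion with the given composition and charge.

    The composition describes the ion itself (all atoms present, counts
    >= 0); the electron imbalance implied by ``charge`` is corrected:

        m/z = (sum of atomic masses - charge * electron mass) / |charge|
    """
    if charge == 0:
        raise ValueError("charge must be nonzero")
    if not comp.is_nonnegative():
        raise FormulaError(
            "composition has negative counts; it is a delta, not a molecule (use delta_mass)"
        )
    return (delta_mass(comp) - charge * ELECTRON_MASS) / abs(charge)


def composition_difference(
    a: ElementalComposition, b: ElementalComposition
) -> ElementalComposition:
    """Signed element-wise difference ``b - a`` (so that ``a + diff == b``)."""
    return b - a
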