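"""Candidate sum-formula generation for an observed m/z.

Exhaustively enumerates the bounded element-count lattice and keeps every
composition whose ion m/z falls inside a ppm window around the observed
value.  No chemical-plausibility filtering is applied by default: ambiguity
is meant to be resolved downstream by transformation matching, not here.
An optional ring-and-double-bond-equivalents (RDBE >= 0) filter is
available but off by default.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .formula import (
    ELECTRON_MASS,
    MONOISOTOPIC_MASS,
    ElementalComposition,
    FormulaError,
    MzValue,
    format_formula,
)

__all__ = ["CandidateFormula", "generate_candidates", "DEFAULT_BOUNDS"]

#: Element bounds used throughout: 100 C, 200 H, 50 O, 10 N.
DEFAULT_BOUNDS: dict[str, int] = {"C": 100, "H": 200, "O": 50, "N": 10}

_MAX_LATTICE = 50_000_000  # guard against accidental combinatorial blow-up


@dataclass(frozen=True)
class CandidateFormula:
    """One candidate elemental composition for an observed m/z."""

    composition: ElementalComposition
    theoretical_mz: float
    ppm_error: float
    rank: int


def _rdbe(comp: ElementalComposition) -> float:
    return comp.get("C") - comp.get("H") / 2.0 + comp.get("N") / 2.0 + 1.0


def generate_candidates(
    mz: float | MzValue,
    tolerance_ppm: float,
    bounds: dict[str, int],
    max_candidates: int = 10,
    charge: int = 1,
    rdbe_filter: bool = False,
) -> list[CandidateFormula]:
    """Enumerate all compositions within ``tolerance_ppm`` of ``mz``.

    The search is exhaustive over the lattice ``0..bounds[el]`` per element;
    the hydrogen count, when H is bounded, is solved from the mass remainder
    (every H value consistent with the window is checked, so no valid
    composition can be missed).  Results are sorted by \\|ppm error\\|
    ascending (ties: lexicographic formula string) and truncated to
    ``max_candidates`` with 1-based ranks.
    """
    if isinstance(mz, MzValue):
        charge = mz.charge
        mz = mz.mz
    if not mz > 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    if not tolerance_ppm > 0:
        raise ValueError("tolerance_ppm must be positive")
    if not bounds:
        raise ValueError("element bounds must be nonempty")
    if max_candidates < 1:
        raise ValueError("max_candidates must be >= 1")
    if charge == 0:
        raise ValueError("charge must be nonzero")
    for element in bounds:
        if element not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {element!r} in bounds")

    # Total atomic mass of the ion, reconstructed from m/z and charge.
    target = mz * abs(charge) + charge * ELECTRON_MASS
    tol_da = tolerance_ppm * 1e-6 * mz * abs(charge)

    others = [el for el in sorted(bounds) if el != "H"]
    lattice = math.prod(bounds[el] + 1 for el in others)
    if lattice > _MAX_LATTICE:
        raise ValueError(f"bounded search space too large ({lattice} grid points)")
    if lattice == 0 or any(bounds[el] < 0 for el in bounds):
        return []

    if others:
        grids = np.meshgrid(
            *[np.arange(bounds[el] + 1, dtype=np.int64) for el in others], indexing="ij"
        )
        cols = [g.ravel() for g in grids]
        base = np.zeros(lattice, dtype=np.float64)
        for col, el in zip(cols, others):
            base += col * MONOISOTOPIC_MASS[el]
    else:
        cols = []
        base = np.zeros(1, dtype=np.float64)

    hits: list[tuple[ElementalComposition, float]] = []

    def _collect(idx: np.ndarray, h_counts: np.ndarray | None) -> None:
        for pos_n, i in enumerate(idx):
            counts = {el: int(col[i]) for col, el in zip(cols, others)}
            if h_counts is not None:
                counts["H"] = int(h_counts[pos_n])
            comp = ElementalComposition(counts)
            if not comp:
                continue
            if rdbe_filter and _rdbe(comp) < 0:
                continue
            theo = (sum(n * MONOISOTOPIC_MASS[el] for el, n in comp.items())
                    - charge * ELECTRON_MASS) / abs(charge)
            hits.append((comp, theo))

    if "H" in bounds:
        m_h = MONOISOTOPIC_MASS["H"]
        h_lo = np.ceil((target - tol_da - base) / m_h).astype(np.int64)
        h_hi = np.floor((target + tol_da - base) / m_h).astype(np.int64)
        h_lo = np.maximum(h_lo, 0)
        h_hi = np.minimum(h_hi, bounds["H"])
        span = int((h_hi - h_lo).max(initial=-1)) + 1
        for offset in range(max(span, 0)):
            h = h_lo + offset
            ok = np.nonzero(h <= h_hi)[0]
            if ok.size == 0:
                continue
            _collect(ok, h[ok])
    else:
        ok = np.nonzero(np.abs(base - target) <= tol_da)[0]
        _collect(ok, None)

    hits.sort(key=lambda item: (abs((mz - item[1]) / mz * 1e6), format_formula(item[0])))
    out: list[CandidateFormula] = []
    for rank, (comp, theo) in enumerate(itertools.islice(hits, max_candidates), start=1):
        out.append(
            CandidateFormula(
                composition=comp,
                theoretical_mz=theo,
                ppm_error=(mz - theo) / mz * 1e6,
                rank=rank,
            )
        )
    return out
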