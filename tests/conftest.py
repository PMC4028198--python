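from __future__ import annotations

import pytest

from mzgroupnet.candidates import CandidateFormula
from mzgroupnet.formula import MzValue, monoisotopic_mz, parse_formula
from mzgroupnet.matching import Feature
from mzgroupnet.rules import default_rules


def make_feature(fid, formulas, time_points=(0,), mz=None, extra_ppm=0.0):
    """Build a Feature whose candidates are the given formula strings.

    The observed m/z defaults to the exact cation m/z of the first formula.
    """
    comps = [parse_formula(f) for f in formulas]
    observed = mz if mz is not None else monoisotopic_mz(comps[0], 1)
    candidates = [
        CandidateFormula(
            composition=comp,
            theoretical_mz=monoisotopic_mz(comp, 1),
            ppm_error=extra_ppm,
            rank=i + 1,
        )
        for i, comp in enumerate(comps)
    ]
    return Feature(
        id=fid,
        mz=MzValue(observed, 1),
        time_points=frozenset(time_points),
        candidates=candidates,
    )


@pytest.fixture(scope="session")
def all_rules():
    return default_rules()
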