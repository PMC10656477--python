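"""LTR retrotransposon insertion-time dating.

The two long terminal repeats of a full-length element are identical at
insertion and diverge neutrally afterwards, so their pairwise distance dates
the insertion. The 5' and 3' LTR sequences are globally aligned (affine
gaps), the Kimura two-parameter distance is computed from transition and
transversion proportions,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q),

and the insertion time follows time = distance / (mu * 2 * 100) with the
distance expressed in percent (equivalently time = d/(2 mu) on the per-site
scale) and mu = 1.3e-8 substitutions per site per generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from Bio import Align

DNA = set("ACGTN")
PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}

SATURATED = "saturated"


@dataclass
class LtrDating:
    element_id: str
    subfamily: str
    p_transition: float
    q_transversion: float
    d_k2p: Optional[float]          # None when saturated
    insertion_time: Optional[float]  # generations; None when saturated


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def align_ltr_pair(seq5: str, seq3: str) -> tuple[str, str]:
    """Global affine-gap alignment of an LTR pair (match +1, mismatch -2,
    gap open -5, gap extend -1; a length-L gap costs 5 + (L-1)).

    Returns the two gapped strings of equal length; the first optimal
    traceback is taken, which is deterministic for fixed inputs.
    """
    for s in (seq5, seq3):
        if not s:
            raise ValueError("empty LTR sequence")
        bad = set(s.upper()) - DNA
        if bad:
            raise ValueError(f"non-DNA characters {sorted(bad)}")
    aligner = _make_aligner()
    aln = aligner.align(seq5.upper(), seq3.upper())[0]
    a, b = str(aln[0]), str(aln[1])
    return a, b


def alignment_score(seq5: str, seq3: str) -> float:
    """Optimal global alignment score under the module's scoring scheme."""
    return float(_make_aligner().score(seq5.upper(), seq3.upper()))


def kimura_2p(aligned5: str, aligned3: str) -> tuple[float, float, Optional[float]]:
    """(P, Q, d) from an aligned pair; gap/N columns are excluded from sites.

    Returns d = None (saturated) when 1-2P-Q <= 0 or 1-2Q <= 0, where the
    correction's logarithms leave their domain.
    """
    if len(aligned5) != len(aligned3):
        raise ValueError("aligned sequences must have equal length")
    sites = transitions = transversions = 0
    for x, y in zip(aligned5.upper(), aligned3.upper()):
        if x in "-N" or y in "-N":
            continue
        sites += 1
        if x == y:
            continue
        same_class = (x in PURINES) == (y in PURINES)
        if same_class:
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        raise ValueError("no comparable (ungapped, non-N) sites")
    P = transitions / sites
    Q = transversions / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return P, Q, None
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return P, Q, d


def insertion_time(d_percent: float, mu: float = 1.3e-8) -> float:
    """Generations since insertion: time = d_percent / (mu * 2 * 100).

    ``d_percent`` is the K2P distance in percent (100 * d); the divisor 100
    converts back to substitutions per site, so the formula is equivalently
    d/(2 mu). One generation per year puts the result on a years scale.
    """
    if d_percent < 0:
        raise ValueError("distance must be non-negative")
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    return d_percent / (mu * 2.0 * 100.0)


def date_element(
    element_id: str, subfamily: str, seq5: str, seq3: str, mu: float = 1.3e-8
) -> LtrDating:
    """Full dating of one element: align, K2P-correct, convert to time."""
    a, b = align_ltr_pair(seq5, seq3)
    P, Q, d = kimura_2p(a, b)
    time = None if d is None else insertion_time(100.0 * d, mu)
    return LtrDating(element_id, subfamily, P, Q, d, time)
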