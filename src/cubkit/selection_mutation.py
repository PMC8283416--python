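"""Parity-rule-2 coordinates and the neutrality-plot decomposition.

PR2 places a gene at (GC-bias, AU-bias) = (G3/(G3+C3), A3/(A3+U3)),
tallied at third positions of the eight fourfold codon boxes (Ala, Arg,
Gly, Leu, Pro, Ser, Thr, Val; only the fourfold box of the sixfold
families contributes).  The centre (0.5, 0.5), where A = U and G = C,
is the expectation under strand-symmetric mutation with no selection.

The neutrality plot regresses GC12 (mean G+C of codon positions 1 and 2)
on GC3 across strains.  Its slope is read as the mutation-selection
equilibrium coefficient: 100*slope percent of the covariation is
attributed to mutation pressure and 100*(1-slope) percent to selective
constraint on the first two positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genetics import FOURFOLD_BOXES
from .sequence_io import CodonCountTable


@dataclass(frozen=True)
class PR2Point:
    """One gene's parity-rule-2 coordinates; undefined when a strand pair is absent."""

    au_bias: float
    gc_bias: float
    n_codons: int

    @property
    def defined(self) -> bool:
        return not (np.isnan(self.au_bias) or np.isnan(self.gc_bias))


@dataclass(frozen=True)
class NeutralityFit:
    """OLS fit of GC12 on GC3 with the mutation/selection percentage split."""

    slope: float
    intercept: float
    r: float
    p_value: float
    n_points: int

    @property
    def mutation_pct(self) -> float:
        return 100.0 * self.slope

    @property
    def selection_pct(self) -> float:
        return 100.0 * (1.0 - self.slope)


def pr2_coordinates(counts: CodonCountTable) -> PR2Point:
    """PR2 (AU-bias, GC-bias) of one codon count table."""
    third = {b: 0 for b in "ACGT"}
    for box in FOURFOLD_BOXES:
        for b in "ACGT":
            third[b] += counts.counts[box + b]
    n = sum(third.values())
    au_den = third["A"] + third["T"]
    gc_den = third["G"] + third["C"]
    au = third["A"] / au_den if au_den else float("nan")
    gc = third["G"] / gc_den if gc_den else float("nan")
    return PR2Point(au_bias=au, gc_bias=gc, n_codons=n)


def neutrality_fit(points: Sequence[tuple[float, float]]) -> NeutralityFit:
    """Fit the neutrality regression on (gc12, gc3) pairs.

    Both axes may be fractions or percentages as long as they agree; the
    slope (and hence the percentage split) is unit-invariant.  Requires at
    least 3 points with non-constant gc3.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (gc12, gc3) pairs")
    gc12, gc3 = arr[:, 0], arr[:, 1]
    if np.ptp(gc3) == 0:
        raise ValueError("gc3 values are all identical; regression undefined")
    res = stats.linregress(gc3, gc12)
    return NeutralityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        n_points=int(arr.shape[0]),
    )


def decomposition_from_slope(slope: float) -> tuple[float, float]:
    """(mutation %, selection %) implied by a neutrality-plot slope."""
    return 100.0 * slope, 100.0 * (1.0 - slope)
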