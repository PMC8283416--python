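"""Wright's effective number of codons (ENC) and the ENC-plot expectation.

ENC summarises codon-usage bias on a scale from 20 (extreme bias, a single
codon per amino acid) to 61 (all synonymous codons used equally).  With
amino acids grouped by degeneracy (2-fold: F,Y,H,Q,N,K,D,E,C; 3-fold: I;
4-fold: V,P,T,A,G; 6-fold: L,S,R),

    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

where Fk is the unweighted mean over the class of the per-amino-acid
homozygosity F = (n * sum((n_i/n)^2) - 1) / (n - 1), n being the amino
acid's codon total and n_i the count of its i-th codon.  F is computable
only when n >= 2; non-positive F values (possible at small n) are dropped
from the class mean.  If the 3-fold class (Ile) has no usable F it is
imputed as (F2 + F4)/2; an empty 2-, 4- or 6-fold class leaves ENC
undefined.  Values above 61 are capped.

The ENC-plot compares observed ENC with the value expected were codon
choice driven purely by third-position G+C content s:

    ENC_expected(s) = 2 + s + 29 / (s^2 + (1 - s)^2)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .composition import composition_summary
from .genetics import AA_TO_CODONS, ENC_CLASSES
from .sequence_io import CodingSequence, CodonCountTable, count_codons

logger = logging.getLogger(__name__)

#: Observed-vs-expected ENC agreement band for the on-curve judgement.
#: Uniform usage within families gives ENC -> 61 while the expectation at
#: s = 0.5 is 60.5, so the curve itself is only exact in the biased tails.
ON_CURVE_TOL = 1.0


@dataclass(frozen=True)
class ENCRecord:
    """One sequence's ENC-plot entry."""

    enc: float
    gc3s: float
    enc_expected: float
    below_curve: bool
    class_F: dict[int, float]
    imputed_classes: frozenset[int] = frozenset()


def _family_F(counts: CodonCountTable, aa: str) -> float | None:
    ns = [counts.counts[c] for c in AA_TO_CODONS[aa]]
    n = sum(ns)
    if n < 2:
        return None
    s2 = sum((ni / n) ** 2 for ni in ns)
    return (n * s2 - 1.0) / (n - 1.0)


def compute_enc(counts: CodonCountTable) -> float:
    """Wright's ENC of one codon count table; nan when undefined."""
    class_F, _ = _class_means(counts)
    if class_F is None:
        return math.nan
    enc = 2.0 + sum(k_size / class_F[k] for k, k_size in ((2, 9.0), (3, 1.0), (4, 5.0), (6, 3.0)))
    return min(enc, 61.0)


def _class_means(
    counts: CodonCountTable,
) -> tuple[dict[int, float] | None, frozenset[int]]:
    means: dict[int, float] = {}
    for k, aas in ENC_CLASSES.items():
        fs = [f for aa in aas if (f := _family_F(counts, aa)) is not None and f > 0]
        if fs:
            means[k] = sum(fs) / len(fs)
    imputed: set[int] = set()
    if 3 not in means and 2 in means and 4 in means:
        means[3] = (means[2] + means[4]) / 2.0
        imputed.add(3)
    if not all(k in means for k in (2, 3, 4, 6)):
        logger.warning("ENC undefined: empty degeneracy class(es) %s",
                       sorted(set((2, 3, 4, 6)) - set(means)))
        return None, frozenset()
    return means, frozenset(imputed)


def expected_enc(s: float) -> float:
    """Expected ENC under pure third-position compositional constraint."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"GC3s fraction must lie in [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def enc_record(counts: CodonCountTable) -> ENCRecord:
    """Full ENC-plot record (ENC, GC3s, expectation, below-curve flag)."""
    means, imputed = _class_means(counts)
    if means is None:
        raise ValueError("ENC undefined for this table (empty degeneracy class)")
    enc = min(
        2.0 + 9.0 / means[2] + 1.0 / means[3] + 5.0 / means[4] + 3.0 / means[6],
        61.0,
    )
    gc3s = composition_summary(counts).GC3s / 100.0
    exp = expected_enc(gc3s)
    return ENCRecord(
        enc=enc, gc3s=gc3s, enc_expected=exp,
        below_curve=enc < exp, class_F=means, imputed_classes=imputed,
    )


def enc_plot_table(seqs: Sequence[CodingSequence]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ENC-plot rows for a panel of sequences, plus the sampled expected curve.

    Returns ``(points, curve)``: one row per sequence with enc, gc3s,
    enc_expected and below_curve, and the expectation sampled on a 0.01
    grid of s for plotting.
    """
    rows = []
    for seq in seqs:
        counts = count_codons(seq)
        try:
            rec = enc_record(counts)
        except ValueError as err:
            logger.warning("skipping %s: %s", seq.id, err)
            continue
        rows.append({
            "strain_id": seq.id, "segment": seq.segment, "clade": seq.clade,
            "gc3s": rec.gc3s, "enc": rec.enc,
            "enc_expected": rec.enc_expected, "below_curve": rec.below_curve,
        })
    if not rows:
        logger.warning("empty ENC-plot table")
    grid = np.round(np.arange(0.0, 1.0001, 0.01), 2)
    curve = pd.DataFrame({"s": grid, "enc_expected": [expected_enc(s) for s in grid]})
    cols = ["strain_id", "segment", "clade", "gc3s", "enc", "enc_expected", "below_curve"]
    return pd.DataFrame(rows, columns=cols), curve
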