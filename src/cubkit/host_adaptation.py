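"""Virus-host codon adaptation indices: CAI, RCDI and SiD.

CAI (codon adaptation index) scores a gene against a reference organism's
usage: each codon's relative adaptiveness w is its reference frequency
divided by the largest frequency in its synonymous family (so the optimal
codon has w = 1), and CAI is the geometric mean of w over the gene's
scoreable codons.  CAI = 1 means every codon is the reference-optimal one.

RCDI (relative codon deoptimization index) is the usage-weighted mean
ratio of per-amino-acid relative codon frequencies between query and
reference,

    RCDI = sum_c (CiFa_c / CiFh_c * N_c) / N,

where CiFa is the codon's frequency within its amino acid in the query,
CiFh the same in the reference, N_c the query count and N the query
total.  RCDI = 1 for identical usage; larger values mean deoptimization.

SiD (similarity index) compares 59-codon RSCU vectors by cosine:
R(A,B) = <a,b>/(|a||b|) and D(A,B) = (1 - R)/2, so D is 0 for
proportional usage and grows with angular separation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .genetics import (
    AA_TO_CODONS,
    CODON_TO_AA,
    DEGENERATE_AAS,
    SENSE_CODONS,
    SYNONYMOUS_CODONS,
)
from .rscu import RSCUVector
from .sequence_io import CodonCountTable, ReferenceUsage

logger = logging.getLogger(__name__)

#: Floor applied to w for codons unobserved in the reference, so the
#: geometric mean stays finite (CAIcal's convention).
W_FLOOR = 0.01


@dataclass(frozen=True)
class AdaptivenessTable:
    """Relative adaptiveness w per synonymous codon, derived from a reference."""

    organism: str
    w: Mapping[str, float]
    smoothed: frozenset[str] = frozenset()


@dataclass(frozen=True)
class AdaptationRecord:
    """CAI / RCDI (and optionally SiD) of one query against one reference."""

    reference_organism: str
    cai: float
    rcdi: float
    sid: float | None = None


def relative_adaptiveness(
    ref: ReferenceUsage, floor: float = W_FLOOR
) -> AdaptivenessTable:
    """Per-codon relative adaptiveness w from a reference usage table.

    w(c) = freq(c) / max frequency in c's synonymous family; codons with
    zero reference frequency are floored to ``floor`` and flagged.  A
    family with no observed codon at all raises, naming the amino acid.
    """
    w: dict[str, float] = {}
    smoothed: set[str] = set()
    for aa in DEGENERATE_AAS:
        codons = AA_TO_CODONS[aa]
        fmax = max(ref.frequencies[c] for c in codons)
        if fmax <= 0:
            raise ValueError(
                f"reference {ref.organism!r}: amino acid {aa} has no observed codon"
            )
        for c in codons:
            val = ref.frequencies[c] / fmax
            if val <= 0:
                val = floor
                smoothed.add(c)
            w[c] = val
    return AdaptivenessTable(organism=ref.organism, w=w, smoothed=frozenset(smoothed))


def compute_cai(counts: CodonCountTable, w: AdaptivenessTable) -> float:
    """CAI: geometric mean of w over the query's scoreable codon occurrences.

    Scoreable codons are the 59 synonymous sense codons; ATG and TGG carry
    no choice and are excluded, as are stops.
    """
    log_sum = 0.0
    n = 0
    for c in SYNONYMOUS_CODONS:
        cnt = counts.counts[c]
        if cnt:
            log_sum += cnt * math.log(w.w[c])
            n += cnt
    if n == 0:
        raise ValueError("no scoreable codons for CAI")
    return math.exp(log_sum / n)


def compute_rcdi(counts: CodonCountTable, ref: ReferenceUsage) -> float:
    """RCDI of a query codon count table against a reference usage table.

    Reference within-family relative frequencies of zero are floored to
    0.01 times the smallest positive frequency in the family (flagged via
    a logged warning) so the ratio stays finite.
    """
    sense = counts.sense_counts()
    total = sum(sense.values())
    if total == 0:
        raise ValueError("empty query: RCDI undefined")
    acc = 0.0
    for aa, codons in AA_TO_CODONS.items():
        q_tot = sum(sense[c] for c in codons)
        if q_tot == 0:
            continue
        r_freqs = {c: ref.frequencies[c] for c in codons}
        r_tot = sum(r_freqs.values())
        if r_tot <= 0:
            raise ValueError(
                f"reference {ref.organism!r}: amino acid {aa} unobserved, RCDI undefined"
            )
        pos = [f for f in r_freqs.values() if f > 0]
        floor = min(pos) * 0.01
        for c in codons:
            n_c = sense[c]
            if n_c == 0:
                continue
            cifa = n_c / q_tot
            cifh = r_freqs[c] / r_tot
            if cifh <= 0:
                logger.warning("reference %s: codon %s unobserved, flooring", ref.organism, c)
                cifh = floor / r_tot
            acc += cifa / cifh * n_c
    return acc / total


def reference_from_counts(counts: CodonCountTable, organism: str = "self") -> ReferenceUsage:
    """Build a reference usage table from a query's own codon counts."""
    return ReferenceUsage.from_counts(organism, counts.sense_counts())


def compute_sid(rscu_a: RSCUVector, rscu_b: RSCUVector) -> float:
    """SiD between two RSCU vectors (virus A against host B).

    Missing (nan) entries are treated as 0 with a warning; a zero-norm
    vector raises.
    """
    a = np.array(rscu_a.as_list(), dtype=float)
    b = np.array(rscu_b.as_list(), dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        logger.warning("SiD: missing RSCU entries treated as 0")
        a = np.nan_to_num(a)
        b = np.nan_to_num(b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm RSCU vector: SiD undefined")
    r = float(np.dot(a, b) / (na * nb))
    # cosine can drift a hair outside [-1, 1] in floating point
    return min(max((1.0 - r) / 2.0, 0.0), 1.0)
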