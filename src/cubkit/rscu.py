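"""Relative synonymous codon usage (RSCU) and codon classification.

RSCU of a codon is its observed count divided by the count expected if all
synonymous codons of that amino acid were used equally:

    RSCU(c) = x_c / ((1/n_i) * sum of x over the amino acid's codons)

where n_i is the family's degeneracy.  A value of 1 means no preference;
within each present amino acid the values sum to the degeneracy.  Codons
with RSCU above a high threshold (default 1.6) are called over-represented
and below a low threshold (default 0.6) under-represented; the codon with
the maximal RSCU per amino acid is its preferred codon.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .genetics import (
    AA_TO_CODONS,
    CODON_TO_AA,
    DEGENERACY,
    DEGENERATE_AAS,
    SYNONYMOUS_CODONS,
    to_rna,
)
from .sequence_io import CodonCountTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RSCUVector:
    """RSCU values over the 59 synonymous sense codons.

    Codons of amino acids absent from the source counts are recorded in
    ``missing_aas`` and their values are ``nan`` — absence of evidence,
    not evidence of zero usage.
    """

    values: Mapping[str, float]
    missing_aas: frozenset[str] = frozenset()

    def __getitem__(self, codon: str) -> float:
        return self.values[codon]

    def as_list(self, codons: Sequence[str] = SYNONYMOUS_CODONS) -> list[float]:
        """Values in a fixed codon order, with nan for missing families."""
        return [self.values[c] for c in codons]


@dataclass(frozen=True)
class CodonClassification:
    """Preferred / over- / under-represented codon sets from one RSCU vector."""

    preferred: Mapping[str, tuple[str, ...]]  # amino acid -> argmax codon(s)
    over_represented: frozenset[str]
    under_represented: frozenset[str]
    ending_class: Mapping[str, str]  # codon -> "A-ended" etc. (RNA base)
    tied_aas: frozenset[str] = frozenset()

    def preferred_codons(self) -> set[str]:
        return {c for cs in self.preferred.values() for c in cs}

    def count_endings(self, which: str = "preferred") -> dict[str, int]:
        """Tally third-base endings over a codon set ('preferred', 'over', 'under')."""
        pool = {
            "preferred": self.preferred_codons(),
            "over": set(self.over_represented),
            "under": set(self.under_represented),
        }[which]
        out: dict[str, int] = {}
        for codon in pool:
            out[self.ending_class[codon]] = out.get(self.ending_class[codon], 0) + 1
        return out


def compute_rscu(counts: CodonCountTable) -> RSCUVector:
    """RSCU vector of one codon count table (ATG, TGG and stops excluded)."""
    values: dict[str, float] = {}
    missing: set[str] = set()
    for aa in DEGENERATE_AAS:
        codons = AA_TO_CODONS[aa]
        total = sum(counts.counts[c] for c in codons)
        if total == 0:
            missing.add(aa)
            for c in codons:
                values[c] = math.nan
            continue
        expected = total / DEGENERACY[aa]
        for c in codons:
            values[c] = counts.counts[c] / expected
    return RSCUVector(values=values, missing_aas=frozenset(missing))


def mean_rscu(
    items: Sequence[CodonCountTable] | Sequence[RSCUVector],
    mode: str = "pooled-counts",
) -> RSCUVector:
    """Group-level RSCU.

    ``pooled-counts`` (default) sums the codon count tables and takes RSCU
    of the pooled table — the convention for "overall" usage of a set of
    genomes.  ``mean-of-vectors`` averages per-sequence RSCU vectors
    instead (nan-aware), retained as a sensitivity check.
    """
    if len(items) == 0:
        raise ValueError("empty input")
    if mode == "pooled-counts":
        if not all(isinstance(t, CodonCountTable) for t in items):
            raise TypeError("pooled-counts mode needs CodonCountTable inputs")
        pooled = items[0]
        for t in items[1:]:
            pooled = pooled + t
        return compute_rscu(pooled)
    if mode == "mean-of-vectors":
        vectors = [
            v if isinstance(v, RSCUVector) else compute_rscu(v) for v in items
        ]
        values: dict[str, float] = {}
        missing: set[str] = set()
        for aa in DEGENERATE_AAS:
            for c in AA_TO_CODONS[aa]:
                vals = [v[c] for v in vectors if not math.isnan(v[c])]
                if vals:
                    values[c] = sum(vals) / len(vals)
                else:
                    values[c] = math.nan
                    missing.add(aa)
        return RSCUVector(values=values, missing_aas=frozenset(missing))
    raise ValueError(f"unknown mode {mode!r}")


def classify_codons(
    rscu: RSCUVector, hi: float = 1.6, lo: float = 0.6
) -> CodonClassification:
    """Classify codons as preferred / over- / under-represented.

    Thresholds are strict inequalities on the unrounded values.  A tie for
    the family maximum reports all tied codons and flags the amino acid.
    """
    over: set[str] = set()
    under: set[str] = set()
    preferred: dict[str, tuple[str, ...]] = {}
    tied: set[str] = set()
    for aa in DEGENERATE_AAS:
        codons = AA_TO_CODONS[aa]
        vals = {c: rscu[c] for c in codons}
        if all(math.isnan(v) for v in vals.values()):
            continue
        for c, v in vals.items():
            if math.isnan(v):
                continue
            if v > hi:
                over.add(c)
            elif v < lo:
                under.add(c)
        vmax = max(v for v in vals.values() if not math.isnan(v))
        argmax = tuple(c for c, v in vals.items() if v == vmax)
        preferred[aa] = argmax
        if len(argmax) > 1:
            tied.add(aa)
    ending = {c: f"{to_rna(c)[2]}-ended" for c in rscu.values}
    return CodonClassification(
        preferred=preferred,
        over_represented=frozenset(over),
        under_represented=frozenset(under),
        ending_class=ending,
        tied_aas=frozenset(tied),
    )


@dataclass(frozen=True)
class PreferredAgreement:
    """Per-amino-acid preferred-codon agreement between two usage profiles."""

    matches: Mapping[str, bool]
    shared_codons: frozenset[str]

    @property
    def n_shared(self) -> int:
        return len(self.shared_codons)


def compare_to_reference(
    rscu_query: RSCUVector, rscu_ref: RSCUVector
) -> PreferredAgreement:
    """Compare preferred codons of a query (e.g. virus) against a reference (host).

    An amino acid counts as a match only when both profiles have a unique
    preferred codon and it is the same codon; families tied in either
    profile are reported as non-matches.
    """
    cq = classify_codons(rscu_query)
    cr = classify_codons(rscu_ref)
    matches: dict[str, bool] = {}
    shared: set[str] = set()
    for aa in DEGENERATE_AAS:
        pq = cq.preferred.get(aa)
        pr = cr.preferred.get(aa)
        if pq is None or pr is None:
            continue
        ok = len(pq) == 1 and len(pr) == 1 and pq[0] == pr[0]
        matches[aa] = ok
        if ok:
            shared.add(pq[0])
    return PreferredAgreement(matches=matches, shared_codons=frozenset(shared))


def rscu_from_reference(ref_frequencies: Mapping[str, float]) -> RSCUVector:
    """RSCU vector implied by a reference organism's codon frequencies."""
    values: dict[str, float] = {}
    missing: set[str] = set()
    for aa in DEGENERATE_AAS:
        codons = AA_TO_CODONS[aa]
        total = sum(ref_frequencies.get(c, 0.0) for c in codons)
        if total <= 0:
            missing.add(aa)
            for c in codons:
                values[c] = math.nan
            continue
        for c in codons:
            values[c] = ref_frequencies.get(c, 0.0) / (total / DEGENERACY[aa])
    return RSCUVector(values=values, missing_aas=frozenset(missing))


def rscu_table(
    vectors: Mapping[str, RSCUVector], decimals: int = 2
) -> "pd.DataFrame":
    """Wide RSCU table (amino acid, codon in RNA spelling, one column per group)."""
    import pandas as pd

    rows = []
    for aa in DEGENERATE_AAS:
        for c in AA_TO_CODONS[aa]:
            row = {"amino_acid": aa, "codon": to_rna(c)}
            for name, vec in vectors.items():
                row[name] = round(vec[c], decimals)
            rows.append(row)
    return pd.DataFrame(rows)
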