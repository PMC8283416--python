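"""Nucleotide-composition constraints and protein-level indices.

Computes the compositional-constraint set standard in codon-usage work —
overall base percentages, third-position base shares among synonymous
codons (A3s/U3s/G3s/C3s), positional G+C (GC1s/GC2s/GC3s, GC12s) and
overall GC/AU — plus GRAVY (mean Kyte-Doolittle hydropathy) and ARO
(aromatic residue fraction) of the encoded protein.

The synonymous pool is the 59 sense codons: ATG and TGG have no synonym
and are excluded, as are the three stop codons.  X3s is the raw share of
base X at third positions of that pool; GC1s and GC2s are computed over
the same pool for internal consistency.  Overall base percentages include
stop codons by default (they are part of the coding sequence); pass
``include_stops=False`` to restrict them to sense codons.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genetics import (
    AROMATIC_AAS,
    CODON_TO_AA,
    KYTE_DOOLITTLE,
    SENSE_CODONS,
    SYNONYMOUS_CODONS,
)
from .sequence_io import CodonCountTable


@dataclass(frozen=True)
class CompositionSummary:
    """Compositional constraints of one sequence or pooled group, in percent."""

    pct_A: float
    pct_U: float
    pct_G: float
    pct_C: float
    A3s: float
    U3s: float
    G3s: float
    C3s: float
    GC1s: float
    GC2s: float
    GC3s: float
    GC12s: float
    GC: float
    AU: float
    AU3s: float


@dataclass(frozen=True)
class ProteinIndices:
    """GRAVY (mean hydropathy) and ARO (aromatic fraction) of the encoded protein."""

    gravy: float
    aro: float


def composition_summary(
    counts: CodonCountTable, include_stops: bool = True
) -> CompositionSummary:
    """Compute all compositional constraints from a codon count table."""
    syn = {c: counts.counts[c] for c in SYNONYMOUS_CODONS}
    n_syn = sum(syn.values())
    if n_syn == 0:
        raise ValueError("no synonymous codons: composition undefined")

    overall_pool = (
        counts.counts
        if include_stops
        else {c: counts.counts[c] for c in SENSE_CODONS}
    )
    base_tot = {b: 0 for b in "ACGT"}
    for codon, n in overall_pool.items():
        for b in codon:
            base_tot[b] += n
    n_nt = sum(base_tot.values())
    if n_nt == 0:
        raise ValueError("empty codon table")

    third = {b: 0 for b in "ACGT"}
    pos_gc = [0, 0, 0]
    for codon, n in syn.items():
        third[codon[2]] += n
        for i in range(3):
            if codon[i] in "GC":
                pos_gc[i] += n

    pct = {b: 100.0 * base_tot[b] / n_nt for b in "ACGT"}
    x3s = {b: 100.0 * third[b] / n_syn for b in "ACGT"}
    gc1s, gc2s, gc3s = (100.0 * g / n_syn for g in pos_gc)
    gc = pct["G"] + pct["C"]
    return CompositionSummary(
        pct_A=pct["A"], pct_U=pct["T"], pct_G=pct["G"], pct_C=pct["C"],
        A3s=x3s["A"], U3s=x3s["T"], G3s=x3s["G"], C3s=x3s["C"],
        GC1s=gc1s, GC2s=gc2s, GC3s=gc3s, GC12s=(gc1s + gc2s) / 2.0,
        GC=gc, AU=100.0 - gc, AU3s=100.0 - gc3s,
    )


def gravy_and_aro(counts: CodonCountTable) -> ProteinIndices:
    """GRAVY and aromaticity of the protein encoded by a codon count table.

    Codon counts are translated to residue counts under the standard code
    (stop codons excluded); GRAVY is the count-weighted mean hydropathy
    and ARO the fraction of Phe+Tyr+Trp residues.
    """
    aa_counts: dict[str, int] = {}
    for codon in SENSE_CODONS:
        n = counts.counts[codon]
        if n:
            aa = CODON_TO_AA[codon]
            aa_counts[aa] = aa_counts.get(aa, 0) + n
    total = sum(aa_counts.values())
    if total == 0:
        raise ValueError("no translatable codons")
    gravy = sum(KYTE_DOOLITTLE[aa] * n for aa, n in aa_counts.items()) / total
    aro = sum(n for aa, n in aa_counts.items() if aa in AROMATIC_AAS) / total
    return ProteinIndices(gravy=gravy, aro=aro)
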