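"""Reading, validating and codon-counting coding sequences.

The core containers of the toolkit live here:

``CodingSequence``
    one CDS with strain / segment / clade / host metadata;
``CodonCountTable``
    counts of all 64 codons for one sequence or a pooled group;
``ReferenceUsage``
    a host organism's codon-usage table (counts and sense-codon
    frequencies), the reference side of CAI / RCDI computations.

Sequences are normalized to the upper-case DNA alphabet on input; report
output elsewhere uses RNA spelling.  Codons containing ambiguity symbols
are dropped (and tallied) rather than imputed, so they cannot bias
composition statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import ALL_CODONS, SENSE_CODONS, STOP_CODONS, to_dna

logger = logging.getLogger(__name__)

SEGMENTS = ("L", "M", "S", "WG")

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class CodingSequence:
    """A single coding sequence with strain-level metadata."""

    id: str
    nt: str
    segment: str = "WG"
    clade: str | None = None
    host: str | None = None
    country: str | None = None

    @property
    def length_nt(self) -> int:
        return len(self.nt)

    def codons(self) -> list[str]:
        """The in-frame codons (complete triplets only)."""
        n = len(self.nt) - len(self.nt) % 3
        return [self.nt[i : i + 3] for i in range(0, n, 3)]


@dataclass(frozen=True)
class ValidationReport:
    """What :func:`validate_cds` changed or noticed."""

    trimmed_nt: int = 0
    dropped_codons: int = 0
    missing_start: bool = False
    internal_stop: bool = False

    @property
    def clean(self) -> bool:
        return self.trimmed_nt == 0 and self.dropped_codons == 0


@dataclass
class CodonCountTable:
    """Counts of all 64 codons, for one sequence or a pooled group."""

    counts: dict[str, int]
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        full = {c: 0 for c in ALL_CODONS}
        for codon, n in self.counts.items():
            codon = to_dna(codon)
            if codon not in full:
                raise ValueError(f"not a codon: {codon!r}")
            if n < 0:
                raise ValueError(f"negative count for {codon}")
            full[codon] += int(n)
        self.counts = full

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def sense_counts(self) -> dict[str, int]:
        """Counts restricted to the 61 sense codons."""
        return {c: self.counts[c] for c in SENSE_CODONS}

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        merged = {c: self.counts[c] + other.counts[c] for c in ALL_CODONS}
        return CodonCountTable(merged, self.source_ids + other.source_ids)


@dataclass(frozen=True)
class ReferenceUsage:
    """A host organism's codon-usage table.

    ``frequencies`` are fractions of the 61 sense codons and sum to 1;
    stop codons carry zero weight.
    """

    organism: str
    counts: Mapping[str, float]
    frequencies: Mapping[str, float]

    @classmethod
    def from_counts(cls, organism: str, counts: Mapping[str, float]) -> "ReferenceUsage":
        full = {c: 0.0 for c in ALL_CODONS}
        for codon, n in counts.items():
            codon = to_dna(codon)
            if codon not in full:
                raise ValueError(f"not a codon: {codon!r}")
            full[codon] = float(n)
        total = sum(full[c] for c in SENSE_CODONS)
        if total <= 0:
            raise ValueError(f"reference {organism!r} has no sense-codon counts")
        freqs = {c: full[c] / total for c in SENSE_CODONS}
        return cls(organism=organism, counts=full, frequencies=freqs)


def read_fasta_cds(
    path: str | Path, metadata: pd.DataFrame | str | Path | None = None
) -> list[CodingSequence]:
    """Read coding sequences from a FASTA file, optionally joining metadata.

    Sequences are upper-cased and U is mapped to T.  ``metadata`` may be a
    DataFrame or a TSV path with columns ``strain_id, segment, clade,
    host, country`` (only ``strain_id`` is required); records absent from
    the table keep their metadata unset, with a logged warning.  Record
    order follows the file.  Duplicate record ids raise a ``ValueError``.
    """
    path = Path(path)
    if metadata is not None and not isinstance(metadata, pd.DataFrame):
        metadata = read_metadata(metadata)
    meta_by_id: dict[str, dict] = {}
    if metadata is not None:
        for _, row in metadata.iterrows():
            meta_by_id[str(row["strain_id"])] = row.to_dict()

    seqs: list[CodingSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA record id: {rec.id!r}")
        seen.add(rec.id)
        nt = str(rec.seq).upper().replace("U", "T")
        row = meta_by_id.get(rec.id)
        if metadata is not None and row is None:
            logger.warning("record %s not found in metadata table", rec.id)
        kwargs = {}
        if row is not None:
            for key in ("segment", "clade", "host", "country"):
                val = row.get(key)
                if val is not None and not pd.isna(val):
                    kwargs[key] = str(val)
        seqs.append(CodingSequence(id=rec.id, nt=nt, **kwargs))
    if not seqs:
        logger.warning("no records in FASTA file %s", path)
    return seqs


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a strain metadata TSV (columns strain_id, segment, clade, host, country)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "strain_id" not in df.columns:
        raise ValueError(f"metadata table {path} lacks a strain_id column")
    return df


def write_fasta(seqs: Iterable[CodingSequence], path: str | Path) -> None:
    """Write sequences to FASTA (single-line records, deterministic output)."""
    records = [
        SeqRecord(Seq(s.nt), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def validate_cds(seq: CodingSequence) -> tuple[CodingSequence, ValidationReport]:
    """Clean a CDS for codon analysis and report what was changed.

    A trailing incomplete codon is trimmed; codons containing non-ACGT
    symbols are removed and tallied.  Missing ATG start and internal stop
    codons are flagged but not altered — stop codons stay in ``nt`` and
    are excluded later, by the synonymous-codon statistics themselves.
    An empty sequence after cleaning raises a ``ValueError``.
    """
    nt = seq.nt.upper().replace("U", "T")
    trimmed = len(nt) % 3
    if trimmed:
        logger.warning("%s: trimming %d trailing nt (incomplete codon)", seq.id, trimmed)
        nt = nt[: len(nt) - trimmed]
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    kept = [c for c in codons if set(c) <= _VALID_BASES]
    dropped = len(codons) - len(kept)
    if dropped:
        logger.warning("%s: dropped %d codon(s) with ambiguity symbols", seq.id, dropped)
    if not kept:
        raise ValueError(f"sequence {seq.id!r} empty after cleaning")
    missing_start = kept[0] != "ATG"
    internal_stop = any(c in STOP_CODONS for c in kept[:-1])
    report = ValidationReport(
        trimmed_nt=trimmed,
        dropped_codons=dropped,
        missing_start=missing_start,
        internal_stop=internal_stop,
    )
    return replace(seq, nt="".join(kept)), report


def count_codons(
    seqs: CodingSequence | Sequence[CodingSequence], pool: bool = False
) -> CodonCountTable | list[CodonCountTable]:
    """Count codons per sequence, or pooled into one table when ``pool=True``.

    Pooled tables back the group-level ("overall") statistics; per-sequence
    tables back the per-strain ones.
    """
    if isinstance(seqs, CodingSequence):
        seqs = [seqs]
    tables = []
    for s in seqs:
        counts: dict[str, int] = {}
        for codon in s.codons():
            counts[codon] = counts.get(codon, 0) + 1
        tables.append(CodonCountTable(counts, source_ids=[s.id]))
    if not pool:
        return tables if len(tables) > 1 else tables[0]
    if not tables:
        raise ValueError("no sequences to pool")
    pooled = tables[0]
    for t in tables[1:]:
        pooled = pooled + t
    return pooled


def concatenate_segments(
    L: CodingSequence, M: CodingSequence, S: CodingSequence
) -> CodingSequence:
    """Join the three genomic segments of one strain into a whole-genome CDS.

    The join happens at the codon level, so no reading frame is broken:
    each segment's stop codons are removed before concatenation, and the
    resulting WG sequence's codon counts equal the sum of the segments'
    sense-codon counts.  All three inputs must carry the same strain id.
    """
    ids = {L.id, M.id, S.id}
    if len(ids) > 1:
        raise ValueError(f"segment ids differ: {sorted(ids)}")
    for seg in (L, M, S):
        if not seg.nt:
            raise ValueError(f"empty segment for strain {seg.id!r}")
    joined = []
    for seg in (L, M, S):
        joined.extend(c for c in seg.codons() if c not in STOP_CODONS)
    return CodingSequence(
        id=L.id, nt="".join(joined), segment="WG",
        clade=L.clade, host=L.host, country=L.country,
    )


def read_reference_usage(path: str | Path, organism: str | None = None) -> ReferenceUsage:
    """Read a host codon-usage TSV (columns ``codon``, ``count``).

    Codons may be spelled in the RNA or DNA alphabet.  Stop-codon rows are
    ignored with a warning; sense codons missing from the file are treated
    as count 0 with a warning.  The table layout matches what codon-usage
    databases such as CoCoPUTs export.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"codon": str})
    if not {"codon", "count"} <= set(df.columns):
        raise ValueError(f"{path} must have columns 'codon' and 'count'")
    counts: dict[str, float] = {}
    for _, row in df.iterrows():
        codon = to_dna(str(row["codon"]).strip())
        n = float(row["count"])
        if codon in STOP_CODONS:
            logger.warning("%s: ignoring stop-codon row %s", path.name, codon)
            continue
        counts[codon] = counts.get(codon, 0.0) + n
    missing = [c for c in SENSE_CODONS if c not in counts]
    if missing:
        logger.warning("%s: %d sense codon(s) missing, treated as 0: %s",
                       path.name, len(missing), ", ".join(missing[:5]))
    name = organism if organism is not None else path.stem
    return ReferenceUsage.from_counts(name, counts)
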