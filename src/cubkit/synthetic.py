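"""Synthetic coding-sequence panels with controllable mutation and selection.

The generator emulates the statistical structure codon-usage inference
relies on, without mimicking any real genome beyond its codon statistics.
Each strain's codons are drawn amino acid by amino acid from a mixture of
two kernels:

* a *mutation* kernel, which splits a per-strain GC3 parameter over the
  family's third-position bases: the G/C-ending codons share total mass
  gc3 equally and the A/T-ending codons share 1 - gc3, so every family's
  third-position G+C marginal equals the parameter exactly;
* a *selection* kernel, which weights them by a target RSCU profile.

``selection_weight`` in [0, 1] mixes the two: 0 is pure mutation pressure,
1 is pure selection toward the target.  First and second codon positions
are fixed by the amino-acid choice; an optional ``mutation_gc12`` target
tilts amino-acid sampling (exponential tilting, solved numerically) so
panels with a prescribed GC12/GC3 relationship can be produced — the
construction behind the neutrality-plot validation bed.

Default panel dimensions follow the organism the toolkit was built
around: 88 strains with L/M/S coding sequences of 2151, 1135 and 429
codons, the size of a hantavirus whole-genome panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genetics import AA_TO_CODONS, DEGENERATE_AAS
from .rscu import RSCUVector
from .sequence_io import CodingSequence, write_fasta

logger = logging.getLogger(__name__)

_DEFAULT_SEGMENTS = {"L": 2151, "M": 1135, "S": 429}


def default_protein_model() -> dict[str, float]:
    """Uniform over the 18 degenerate amino acids plus low-rate Met/Trp.

    Keeps every ENC degeneracy class populated while acknowledging that
    Met and Trp occur (they carry no synonymous information).
    """
    model = {aa: 1.0 for aa in DEGENERATE_AAS}
    model["M"] = 0.2
    model["W"] = 0.2
    return model


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings for one synthetic panel; see the module docstring."""

    n_strains: int = 88
    segments: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_SEGMENTS))
    protein_model: Mapping[str, float] = field(default_factory=default_protein_model)
    mutation_gc3: float | tuple[float, float] = 0.31
    mutation_gc12: float | None = None
    selection_target: RSCUVector | None = None
    selection_weight: float = 0.0
    groups: Sequence[tuple[str, Mapping]] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.selection_weight <= 1.0:
            raise ValueError("selection_weight must lie in [0, 1]")
        if self.n_strains < 1:
            raise ValueError("n_strains must be >= 1")
        for seg, length in self.segments.items():
            if length < 1:
                raise ValueError(f"segment {seg} length must be >= 1 codon")
        gc3 = self.mutation_gc3
        vals = gc3 if isinstance(gc3, tuple) else (gc3,)
        if not all(0.0 <= v <= 1.0 for v in vals):
            raise ValueError("mutation_gc3 must lie in [0, 1]")


def _codon_kernels(
    aas: Sequence[str],
    gc3: float,
    target: RSCUVector | None,
    weight: float,
) -> dict[str, tuple[list[str], np.ndarray]]:
    """Per-amino-acid codon lists and mixed sampling probabilities."""
    kernels = {}
    for aa in aas:
        codons = list(AA_TO_CODONS[aa])
        is_gc = np.array([c[2] in "GC" for c in codons])
        n_gc, n_at = int(is_gc.sum()), int((~is_gc).sum())
        if n_gc and n_at:
            mut = np.where(is_gc, gc3 / n_gc, (1.0 - gc3) / n_at)
        else:  # single-base-class family (Met, Trp)
            mut = np.full(len(codons), 1.0 / len(codons))
        mut = mut / mut.sum()
        if weight > 0 and len(codons) > 1:
            if target is None:
                raise ValueError("selection_weight > 0 requires a selection_target")
            sel = np.array([target[c] for c in codons], dtype=float)
            if np.isnan(sel).any():
                raise ValueError(f"selection_target missing amino acid {aa}")
            if sel.sum() <= 0:
                raise ValueError(f"selection_target all-zero for amino acid {aa}")
            sel = sel / sel.sum()
            p = (1.0 - weight) * mut + weight * sel
        else:
            p = mut
        kernels[aa] = (codons, p)
    return kernels


def _aa_gc12(kernels: Mapping[str, tuple[list[str], np.ndarray]]) -> dict[str, float]:
    """Expected G+C fraction at codon positions 1-2 per amino acid, under its kernel."""
    out = {}
    for aa, (codons, p) in kernels.items():
        gc = np.array([sum(b in "GC" for b in c[:2]) / 2.0 for c in codons])
        out[aa] = float(np.dot(gc, p))
    return out


def _tilt_protein_model(
    model: Mapping[str, float], gc12_by_aa: Mapping[str, float], target: float
) -> dict[str, float]:
    """Exponentially tilt amino-acid weights so the expected GC12 of the
    synonymous pool hits ``target``.

    Only the degenerate amino acids are tilted (they alone enter measured
    GC12s); Met/Trp keep their share of the total mass.  Targets outside
    the achievable range are clamped to it.
    """
    deg = [a for a in model if a in DEGENERATE_AAS]
    rest = {a: model[a] for a in model if a not in DEGENERATE_AAS}
    w = np.array([model[a] for a in deg], dtype=float)
    g = np.array([gc12_by_aa[a] for a in deg], dtype=float)
    lo, hi = g.min(), g.max()
    eps = 1e-4
    target = min(max(target, lo + eps), hi - eps)

    def mean_gc12(theta: float) -> float:
        z = w * np.exp(theta * (g - g.mean()))
        return float(np.dot(z, g) / z.sum())

    theta = brentq(lambda t: mean_gc12(t) - target, -200.0, 200.0)
    tilted = w * np.exp(theta * (g - g.mean()))
    tilted = tilted * (w.sum() / tilted.sum())  # preserve Met/Trp share
    out = dict(zip(deg, tilted))
    out.update(rest)
    return out


def _draw_cds(
    rng: np.random.Generator,
    n_codons: int,
    model: Mapping[str, float],
    kernels: Mapping[str, tuple[list[str], np.ndarray]],
) -> str:
    aas = list(model)
    probs = np.array([model[a] for a in aas], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(aas), size=n_codons, p=probs)
    codons = np.empty(n_codons, dtype=object)
    for i, aa in enumerate(aas):
        pos = np.nonzero(idx == i)[0]
        if pos.size == 0:
            continue
        fam, p = kernels[aa]
        codons[pos] = rng.choice(fam, size=pos.size, p=p)
    return "".join(codons.tolist())


def generate_panel(
    config: GeneratorConfig,
) -> tuple[list[CodingSequence], pd.DataFrame]:
    """Generate a strain panel and its metadata table.

    Strains are split evenly over ``config.groups`` (one group ``all``
    when none are given); group overrides may replace any GeneratorConfig
    field that affects sampling (``mutation_gc3``, ``selection_target``,
    ``selection_weight``, ``mutation_gc12``, ``protein_model``).  One
    seeded random stream drives the whole panel, so output is
    reproducible byte for byte.
    """
    rng = np.random.default_rng(config.seed)
    groups = list(config.groups) or [("all", {})]
    seqs: list[CodingSequence] = []
    meta_rows = []
    for i in range(config.n_strains):
        label, overrides = groups[i % len(groups)]
        cfg = replace(config, **dict(overrides)) if overrides else config
        gc3 = cfg.mutation_gc3
        if isinstance(gc3, tuple):
            gc3 = float(rng.uniform(*gc3))
        kernels = _codon_kernels(
            list(cfg.protein_model), gc3, cfg.selection_target, cfg.selection_weight
        )
        model = dict(cfg.protein_model)
        if cfg.mutation_gc12 is not None:
            model = _tilt_protein_model(model, _aa_gc12(kernels), cfg.mutation_gc12)
        strain = f"syn{i:04d}"
        for seg, length in cfg.segments.items():
            body = _draw_cds(rng, int(length), model, kernels)
            nt = "ATG" + body + "TAA"
            seqs.append(CodingSequence(
                id=f"{strain}_{seg}", nt=nt, segment=seg, clade=label, host=None,
            ))
        meta_rows.append({
            "strain_id": strain, "clade": label, "gc3_param": gc3,
            "selection_weight": cfg.selection_weight,
        })
    return seqs, pd.DataFrame(meta_rows)


def generate_neutrality_panel(
    slope: float,
    n: int,
    seed: int,
    sigma: float = 0.02,
    intercept: float | None = None,
    gc3_range: tuple[float, float] = (0.3, 0.7),
    length_codons: int = 1000,
) -> tuple[list[tuple[float, float]], list[CodingSequence]]:
    """Panel with a prescribed GC12-on-GC3 regression structure.

    Per strain, gc3 is uniform on ``gc3_range`` and
    gc12 = intercept + slope * gc3 + N(0, sigma); sequences are generated
    with the mutation kernel at that gc3 and amino-acid tilting toward
    that gc12.  Returns the (gc12, gc3) target pairs and the sequences.
    The default intercept centres gc12 at 0.425 for a slope-independent
    operating point.
    """
    if not 0.0 <= slope <= 1.0:
        raise ValueError("slope must lie in [0, 1]")
    if n < 3:
        raise ValueError("need at least 3 strains")
    if intercept is None:
        intercept = 0.425 - slope * 0.5
    rng = np.random.default_rng(seed)
    model = default_protein_model()
    points: list[tuple[float, float]] = []
    seqs: list[CodingSequence] = []
    for i in range(n):
        gc3 = float(rng.uniform(*gc3_range))
        gc12 = float(intercept + slope * gc3 + rng.normal(0.0, sigma))
        gc12 = min(max(gc12, 0.05), 0.95)
        points.append((gc12, gc3))
        kernels = _codon_kernels(list(model), gc3, None, 0.0)
        tilted = _tilt_protein_model(model, _aa_gc12(kernels), gc12)
        body = _draw_cds(rng, length_codons, tilted, kernels)
        seqs.append(CodingSequence(
            id=f"neu{i:04d}", nt="ATG" + body + "TAA", segment="WG",
        ))
    return points, seqs


def write_panel(
    seqs: Sequence[CodingSequence], meta: pd.DataFrame, outdir: str | Path
) -> tuple[Path, Path]:
    """Write a generated panel as FASTA + metadata TSV (the dialects the readers use)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "panel.fasta"
    meta_path = outdir / "metadata.tsv"
    write_fasta(seqs, fasta)
    rows = []
    for s in seqs:
        strain = s.id.rsplit("_", 1)[0] if "_" in s.id else s.id
        sub = meta.loc[meta["strain_id"] == strain]
        clade = sub["clade"].iloc[0] if len(sub) else s.clade
        rows.append({
            "strain_id": s.id, "segment": s.segment, "clade": clade,
            "host": s.host or "", "country": s.country or "",
        })
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)
    return fasta, meta_path
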