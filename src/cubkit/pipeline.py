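"""End-to-end codon-usage analysis pipeline and group-comparison tests.

``run_pipeline`` executes the full analysis on a panel of coding
sequences: composition -> RSCU -> ENC -> PR2/neutrality -> host
adaptation (CAI/RCDI/SiD, when references are supplied) -> correspondence
analysis -> Spearman correlations -> group tests, writing every stage as
a TSV plus a plain-text manifest that ties each table to its stage and
formula.  Whole-genome (WG) statistics are computed on pooled L+M+S codon
counts per strain when all three segments are present.

``group_compare`` wraps the two routine tests used for group contrasts:
Mann-Whitney U (two groups, two-sided, normal approximation with
continuity correction) and one-way ANOVA (any number of groups), at the
conventional 0.05 threshold.  No multiple-testing correction is applied
by default.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import composition as comp
from . import enc as enc_mod
from . import host_adaptation as ha
from . import multivariate as mv
from . import rscu as rscu_mod
from . import selection_mutation as sm
from .sequence_io import (
    CodingSequence,
    CodonCountTable,
    count_codons,
    read_fasta_cds,
    read_reference_usage,
    validate_cds,
)

logger = logging.getLogger(__name__)

_FORMULAS = {
    "composition": "X3s = 100*count(base X at pos3 of 59 synonymous codons)/n_syn; GC12s=(GC1s+GC2s)/2",
    "rscu": "RSCU = x_ij / ((1/n_i) * sum_j x_ij)",
    "enc": "ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6; F=(n*sum((ni/n)^2)-1)/(n-1)",
    "enc_curve": "ENC_expected = 2 + s + 29/(s^2 + (1-s)^2)",
    "pr2": "AU-bias = A3/(A3+U3), GC-bias = G3/(G3+C3) over fourfold boxes",
    "neutrality": "OLS GC12 ~ GC3; mutation% = 100*slope, selection% = 100*(1-slope)",
    "cai": "CAI = geometric mean of w; w = f(c)/max family f",
    "rcdi": "RCDI = sum(CiFa/CiFh * N_c)/N",
    "sid": "R = <a,b>/(|a||b|); D = (1-R)/2 on 59-codon RSCU vectors",
    "coa": "CA: SVD of Dr^-1/2 (P - r c^T) Dc^-1/2 on strains x 59 RSCU",
    "correlation": "Spearman rho, average ranks, two-sided p",
    "group_tests": "Mann-Whitney U / one-way ANOVA, alpha = 0.05",
}


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending record."""


@dataclass
class RunConfig:
    """Settings for one pipeline run."""

    fasta: Sequence[str | Path]
    metadata: str | Path | None = None
    references: Mapping[str, str | Path] = field(default_factory=dict)
    group_by: str = "clade"
    rscu_hi: float = 1.6
    rscu_lo: float = 0.6
    include_stops: bool = True
    outdir: str | Path = "cubkit_out"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)


def group_compare(
    values: Sequence[float],
    groups: Sequence[str],
    method: str = "anova",
    alpha: float = 0.05,
) -> dict:
    """Compare a per-strain statistic across groups.

    ``mann-whitney`` handles exactly two groups; ``anova`` any number.
    Every group needs at least two values.  Returns statistic, two-sided
    p and a significance flag at ``alpha``.
    """
    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    samples = [g["value"].to_numpy() for _, g in df.groupby("group", sort=True)]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 values")
    if method == "mann-whitney":
        if len(samples) != 2:
            raise ValueError("mann-whitney requires exactly 2 groups")
        res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        stat, p = float(res.statistic), float(res.pvalue)
    elif method == "anova":
        res = stats.f_oneway(*samples)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"method": method, "statistic": stat, "p": p,
            "significant": bool(p < alpha), "n_groups": len(samples)}


def _write(df: pd.DataFrame, path: Path, float_format: str = "%.4f") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def _stage(name: str, record: str = ""):
    def wrap(err: Exception) -> PipelineError:
        where = f"stage {name}" + (f", record {record}" if record else "")
        return PipelineError(f"{where}: {err}")
    return wrap


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis; returns a name -> path map of the bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    bundle: dict[str, Path] = {}

    def emit(stage: str, df: pd.DataFrame, fname: str, params: str = "") -> None:
        path = outdir / fname
        _write(df, path)
        bundle[fname[:-4]] = path
        manifest.append(
            f"{stage}\t{fname}\trows={len(df)}\tformula={_FORMULAS.get(stage, 'n/a')}"
            + (f"\tparams={params}" if params else "")
        )

    # ---- ingest & validate -------------------------------------------------
    seqs: list[CodingSequence] = []
    for path in config.fasta:
        try:
            seqs.extend(read_fasta_cds(path, config.metadata))
        except Exception as err:
            raise _stage("ingest", str(path))(err)
    if not seqs:
        raise PipelineError("stage ingest: no sequences")
    validated: list[CodingSequence] = []
    for s in seqs:
        try:
            v, report = validate_cds(s)
        except Exception as err:
            raise _stage("validate", s.id)(err)
        if not report.clean:
            logger.warning("%s: trimmed=%d dropped=%d", s.id,
                           report.trimmed_nt, report.dropped_codons)
        validated.append(v)

    group_of = {}
    for s in validated:
        label = getattr(s, config.group_by, None)
        group_of[s.id] = label if label else "ungrouped"
    if set(group_of.values()) == {"ungrouped"} and config.metadata is not None:
        raise PipelineError(f"stage grouping: column {config.group_by!r} empty in metadata")

    # per-record counts + pooled WG per strain
    counts: dict[str, CodonCountTable] = {}
    for s in validated:
        counts[s.id] = count_codons(s)
    by_strain: dict[str, list[CodingSequence]] = {}
    for s in validated:
        strain = s.id.rsplit("_", 1)[0] if s.segment in ("L", "M", "S") else s.id
        by_strain.setdefault(strain, []).append(s)
    wg_counts: dict[str, CodonCountTable] = {}
    wg_group: dict[str, str] = {}
    pooled_strains: set[str] = set()
    for strain, members in by_strain.items():
        segs = {m.segment for m in members}
        if {"L", "M", "S"} <= segs:
            wg_counts[strain] = count_codons(members, pool=True)
            pooled_strains.add(strain)
        elif len(members) == 1 and members[0].segment == "WG":
            wg_counts[strain] = counts[members[0].id]
        if strain in wg_counts:
            wg_group[strain] = group_of[members[0].id]

    units = [(s.id, s.segment, group_of[s.id], counts[s.id]) for s in validated]
    units += [(f"{st}_WG", "WG", wg_group[st], wg_counts[st])
              for st in sorted(pooled_strains)]

    # ---- composition -------------------------------------------------------
    rows = []
    for uid, seg, grp, tab in units:
        try:
            c = comp.composition_summary(tab, include_stops=config.include_stops)
            p = comp.gravy_and_aro(tab)
        except Exception as err:
            raise _stage("composition", uid)(err)
        rows.append({"strain_id": uid, "segment": seg, "clade": grp,
                     **c.__dict__, "gravy": p.gravy, "aro": p.aro})
    emit("composition", pd.DataFrame(rows), "composition.tsv",
         params=f"include_stops={config.include_stops}")

    # ---- RSCU + classification --------------------------------------------
    groups = sorted(set(wg_group.values())) or sorted(set(group_of.values()))
    group_vectors: dict[str, rscu_mod.RSCUVector] = {}
    all_wg_tables = list(wg_counts.values())
    if all_wg_tables:
        group_vectors["overall"] = rscu_mod.mean_rscu(all_wg_tables)
        for g in groups:
            tabs = [t for st, t in wg_counts.items() if wg_group[st] == g]
            if tabs:
                group_vectors[g] = rscu_mod.mean_rscu(tabs)
    else:
        group_vectors["overall"] = rscu_mod.mean_rscu([t for _, _, _, t in units])
    emit("rscu", rscu_mod.rscu_table(group_vectors), "rscu.tsv")

    cls_rows = []
    for name, vec in group_vectors.items():
        cls = rscu_mod.classify_codons(vec, hi=config.rscu_hi, lo=config.rscu_lo)
        pref = cls.preferred_codons()
        for codon in sorted(vec.values):
            cls_rows.append({
                "group": name,
                "codon": rscu_mod.to_rna(codon),
                "rscu": vec[codon],
                "preferred": codon in pref,
                "over_represented": codon in cls.over_represented,
                "under_represented": codon in cls.under_represented,
                "ending": cls.ending_class[codon],
            })
    emit("rscu", pd.DataFrame(cls_rows), "rscu_classification.tsv",
         params=f"hi={config.rscu_hi},lo={config.rscu_lo}")

    # ---- ENC ---------------------------------------------------------------
    enc_rows = []
    enc_of: dict[str, float] = {}
    for uid, seg, grp, tab in units:
        try:
            rec = enc_mod.enc_record(tab)
        except ValueError as err:
            logger.warning("%s: %s", uid, err)
            continue
        enc_of[uid] = rec.enc
        enc_rows.append({"strain_id": uid, "segment": seg, "clade": grp,
                         "gc3s": rec.gc3s, "enc": rec.enc,
                         "enc_expected": rec.enc_expected,
                         "below_curve": rec.below_curve})
    emit("enc", pd.DataFrame(enc_rows), "enc.tsv")
    grid = np.round(np.arange(0.0, 1.0001, 0.01), 2)
    curve = pd.DataFrame({"s": grid,
                          "enc_expected": [enc_mod.expected_enc(s) for s in grid]})
    emit("enc_curve", curve, "enc_curve.tsv")

    # ---- PR2 + neutrality --------------------------------------------------
    pr2_rows = []
    for uid, seg, grp, tab in units:
        pt = sm.pr2_coordinates(tab)
        pr2_rows.append({"strain_id": uid, "segment": seg, "clade": grp,
                         "au_bias": pt.au_bias, "gc_bias": pt.gc_bias,
                         "n_codons": pt.n_codons})
    emit("pr2", pd.DataFrame(pr2_rows), "pr2.tsv")

    neut_rows = []
    comp_df = pd.DataFrame(rows)
    wg_comp = comp_df[comp_df["segment"] == "WG"]
    for gname, sub in [("overall", wg_comp)] + [
        (g, wg_comp[wg_comp["clade"] == g]) for g in groups
    ]:
        if len(sub) < 3 or sub["GC3s"].nunique() < 2:
            continue
        fit = sm.neutrality_fit(list(zip(sub["GC12s"] / 100, sub["GC3s"] / 100)))
        neut_rows.append({"group": gname, "slope": fit.slope,
                          "intercept": fit.intercept, "r": fit.r, "p": fit.p_value,
                          "mutation_pct": round(fit.mutation_pct, 2),
                          "selection_pct": round(fit.selection_pct, 2),
                          "n_points": fit.n_points})
    if neut_rows:
        emit("neutrality", pd.DataFrame(neut_rows), "neutrality.tsv")

    # ---- host adaptation ---------------------------------------------------
    if config.references:
        refs = {org: read_reference_usage(p, organism=org)
                for org, p in config.references.items()}
        ad_rows = []
        for org, ref in refs.items():
            w = ha.relative_adaptiveness(ref)
            for uid, seg, grp, tab in units:
                try:
                    cai = ha.compute_cai(tab, w)
                    rcdi = ha.compute_rcdi(tab, ref)
                except Exception as err:
                    raise _stage("adaptation", uid)(err)
                ad_rows.append({"strain_id": uid, "segment": seg, "clade": grp,
                                "reference_organism": org, "cai": cai, "rcdi": rcdi})
        ad_df = pd.DataFrame(ad_rows)
        emit("cai", ad_df, "adaptation.tsv")
        grp_rows = []
        for org, ref in refs.items():
            ref_vec = rscu_mod.rscu_from_reference(ref.frequencies)
            sub = ad_df[(ad_df["reference_organism"] == org) & (ad_df["segment"] == "WG")]
            if sub.empty:
                sub = ad_df[ad_df["reference_organism"] == org]
            for gname, vec in group_vectors.items():
                g_sub = sub if gname == "overall" else sub[sub["clade"] == gname]
                if g_sub.empty:
                    continue
                grp_rows.append({
                    "group": gname, "reference_organism": org,
                    "cai_mean": g_sub["cai"].mean(), "cai_sd": g_sub["cai"].std(ddof=1),
                    "rcdi_mean": g_sub["rcdi"].mean(), "rcdi_sd": g_sub["rcdi"].std(ddof=1),
                    "sid": ha.compute_sid(vec, ref_vec),
                    "n": len(g_sub),
                })
        emit("sid", pd.DataFrame(grp_rows), "adaptation_groups.tsv")

    # ---- correspondence analysis ------------------------------------------
    ca_units = [(uid, tab) for uid, seg, _, tab in units if seg == "WG"]
    if len(ca_units) < 2:
        ca_units = [(uid, tab) for uid, _, _, tab in units]
    ca_ok = len(ca_units) >= 2
    if ca_ok:
        mat = pd.DataFrame(
            {uid: np.nan_to_num(rscu_mod.compute_rscu(tab).as_list())
             for uid, tab in ca_units},
        ).T
        mat.columns = list(rscu_mod.SYNONYMOUS_CODONS)
        try:
            coa = mv.correspondence_analysis(mat, k=2)
        except ValueError as err:
            logger.warning("skipping CA: %s", err)
            ca_ok = False
        if ca_ok:
            emit("coa", coa.row_coords.rename_axis("strain_id").reset_index(),
                 "coa_rows.tsv")
            emit("coa", coa.col_coords.rename_axis("codon").reset_index(),
                 "coa_cols.tsv")
            emit("coa", pd.DataFrame({
                "axis": np.arange(1, len(coa.inertia_fractions) + 1),
                "inertia_fraction": coa.inertia_fractions,
            }), "coa_axes.tsv")

    # ---- correlations ------------------------------------------------------
    feat = comp_df[comp_df["segment"] == "WG"] if len(wg_comp) >= 3 else comp_df
    if len(feat) >= 3:
        table = feat.set_index("strain_id")[
            ["A3s", "U3s", "G3s", "C3s", "GC1s", "GC2s", "GC3s", "GC12s", "GC",
             "gravy", "aro"]
        ].copy()
        table["enc"] = [enc_of.get(i, np.nan) for i in table.index]
        if ca_ok:
            for ax in ("axis1", "axis2"):
                if ax in coa.row_coords.columns:
                    table[ax] = coa.row_coords.reindex(table.index)[ax]
        table = table.dropna(axis=1, how="all").dropna()
        if len(table) >= 3:
            corr = mv.spearman_matrix(table)
            emit("correlation", corr.to_long(), "correlation.tsv")

    # ---- group tests -------------------------------------------------------
    test_rows = []
    enc_df = pd.DataFrame(enc_rows)
    for seg in sorted(enc_df["segment"].unique()) if len(enc_df) else []:
        sub = enc_df[enc_df["segment"] == seg].dropna(subset=["enc"])
        labels = sub["clade"]
        ok_groups = [g for g, n in labels.value_counts().items() if n >= 2]
        sub = sub[sub["clade"].isin(ok_groups)]
        if sub["clade"].nunique() < 2:
            continue
        method = "mann-whitney" if sub["clade"].nunique() == 2 else "anova"
        res = group_compare(sub["enc"], sub["clade"], method=method)
        test_rows.append({"variable": "enc", "segment": seg, **res})
    if test_rows:
        emit("group_tests", pd.DataFrame(test_rows), "group_tests.tsv")

    (outdir / "manifest.txt").write_text(
        "# stage\tfile\trows\tformula\n" + "\n".join(manifest) + "\n"
    )
    bundle["manifest"] = outdir / "manifest.txt"
    return bundle
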