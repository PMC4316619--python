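"""Cross-gene and cross-lineage comparative statistics and report assembly.

TLR genes are compared as units (one value per gene) between the NA-sensing
class (receptors whose ligand is a nucleic acid) and the nonNA-sensing class,
with Welch's unequal-variance t-test and Pearson correlation tests.  Report
builders assemble per-gene TSV tables in the layout of the study's
polymorphism and neutrality-test tables, including a ``TLR average`` row and
significance stars at p < 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import UsageError

NA_CLASS = "NA"
NONNA_CLASS = "nonNA"
UNASSIGNED = "unassigned"

#: TLR family -> sensing class; paralogs (09A/09B, 22A/22B) inherit the
#: family's class.  TLR19 is too divergent to assign.
_FAMILY_CLASS = {
    "TLR03": NA_CLASS, "TLR07": NA_CLASS, "TLR08": NA_CLASS, "TLR09": NA_CLASS,
    "TLR13": NA_CLASS, "TLR21": NA_CLASS, "TLR22": NA_CLASS,
    "TLR01": NONNA_CLASS, "TLR02": NONNA_CLASS, "TLR05": NONNA_CLASS,
    "TLR05L": NONNA_CLASS, "TLR12": NONNA_CLASS, "TLR14": NONNA_CLASS,
    "TLR19": UNASSIGNED,
}


def classify_na_nonna(gene_id: str) -> str:
    """Sensing class (NA / nonNA / unassigned) for a TLR gene id."""
    gid = gene_id.upper().replace(" ", "")
    if gid in _FAMILY_CLASS:
        return _FAMILY_CLASS[gid]
    # strip a single paralog suffix letter (TLR09B -> TLR09), but not the L
    # of TLR05L which is its own gene
    if gid[-1].isalpha() and gid[:-1] in _FAMILY_CLASS and gid != "TLR05L":
        return _FAMILY_CLASS[gid[:-1]]
    raise UsageError(f"unrecognized TLR gene id {gene_id!r}")


@dataclass(frozen=True)
class ComparisonResult:
    name: str
    statistic: float
    df: float
    p_value: float
    group_means: tuple
    group_sizes: tuple


def welch_t_test(x, y, name="welch_t") -> ComparisonResult:
    """Welch's unequal-variance two-sample t-test (two-sided).

    The statistic is computed for (x - y); the Welch-Satterthwaite degrees of
    freedom may be fractional.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise UsageError("each sample needs >= 2 values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise UsageError("samples must be finite")
    vx = x.var(ddof=1) / len(x)
    vy = y.var(ddof=1) / len(y)
    if vx + vy == 0:
        raise UsageError("zero variance in both samples: t undefined")
    t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return ComparisonResult(
        name=name, statistic=float(t), df=float(df), p_value=float(p),
        group_means=(float(x.mean()), float(y.mean())),
        group_sizes=(len(x), len(y)),
    )


def pearson_correlation_test(x, y, name="pearson_r") -> ComparisonResult:
    """Pearson correlation with the t-based two-sided test on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise UsageError("need >= 3 paired values")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise UsageError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    n = len(x)
    if 1.0 - r * r <= 0:  # perfectly collinear
        t, p = math.copysign(math.inf, r), 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), n - 2)
    return ComparisonResult(
        name=name, statistic=r, df=float(n - 2), p_value=float(p),
        group_means=(float(x.mean()), float(y.mean())),
        group_sizes=(n, n),
    )


def split_by_class(values: dict, exclude=()):
    """Split a gene -> value mapping into (NA values, nonNA values), dropping
    excluded genes, unassigned genes and missing values."""
    na, nonna = [], []
    for gene, v in values.items():
        if gene in exclude or v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        cls = classify_na_nonna(gene)
        if cls == NA_CLASS:
            na.append(v)
        elif cls == NONNA_CLASS:
            nonna.append(v)
    return na, nonna


STAR_THRESHOLD = 0.01  # significance flag in report tables


def build_gene_report(
    summaries_by_lineage: dict,
    mk_by_lineage: dict = None,
    hka_p_by_lineage: dict = None,
    null_p: dict = None,
):
    """Assemble the per-gene report tables.

    Parameters
    ----------
    summaries_by_lineage : dict
        lineage label -> list of :class:`~tlrpopgen.popstats.LocusSummary`;
        the gene sets must agree across lineages.
    mk_by_lineage : dict, optional
        lineage -> {gene -> MKResult}.
    hka_p_by_lineage : dict, optional
        lineage -> {gene -> HKA p-value}.
    null_p : dict, optional
        (gene, lineage, statistic) -> simulation p-value, where statistic is
        e.g. ``"D_syn"`` or ``"H_nonsyn"``; used for the star flags.

    Returns
    -------
    dict with DataFrames ``polymorphism`` (per-lineage pi/S/alleles) and
    ``tests`` (MK, HKA, D and H per class), each ending in a ``TLR average``
    row of column means.
    """
    lineages = list(summaries_by_lineage)
    gene_sets = {
        lin: [s.locus_id for s in summaries_by_lineage[lin]] for lin in lineages
    }
    ref = gene_sets[lineages[0]]
    for lin in lineages[1:]:
        if set(gene_sets[lin]) != set(ref):
            offenders = sorted(set(gene_sets[lin]) ^ set(ref))
            raise UsageError(f"gene ids differ across lineages: {offenders}")
    by_gene = {
        lin: {s.locus_id: s for s in summaries_by_lineage[lin]} for lin in lineages
    }

    poly_rows, test_rows = [], []
    for gene in ref:
        prow = {"gene": gene}
        trow = {"gene": gene}
        for lin in lineages:
            s = by_gene[lin][gene]
            prow[f"nsites_{lin}"] = s.nsites
            prow[f"n_alleles_{lin}"] = s.n_alleles
            prow[f"S_{lin}"] = s.S
            prow[f"pi_{lin}"] = s.pi
            prow[f"pi_syn_{lin}"] = s.pi_syn
            prow[f"pi_nonsyn_{lin}"] = s.pi_nonsyn
            if mk_by_lineage:
                mk = mk_by_lineage[lin].get(gene)
                trow[f"mk_p_{lin}"] = mk.p_value if mk else float("nan")
            if hka_p_by_lineage:
                trow[f"hka_p_{lin}"] = hka_p_by_lineage[lin].get(gene, float("nan"))
            for stat in ("D_all", "D_syn", "D_nonsyn", "H_all", "H_syn", "H_nonsyn"):
                trow[f"{stat}_{lin}"] = getattr(s, stat)
        poly_rows.append(prow)
        test_rows.append(trow)

    def finish(rows):
        df = pd.DataFrame(rows)
        means = df.drop(columns="gene").mean(numeric_only=True)
        avg = {"gene": "TLR average", **means.to_dict()}
        return pd.concat([df, pd.DataFrame([avg])], ignore_index=True)

    out = {"polymorphism": finish(poly_rows), "tests": finish(test_rows)}
    if null_p:
        out["significance"] = pd.DataFrame(
            [
                {"gene": g, "lineage": lin, "statistic": stat, "p": p,
                 "starred": p < STAR_THRESHOLD}
                for (g, lin, stat), p in sorted(null_p.items())
            ]
        )
    return out


def write_report(tables: dict, out_dir):
    """Write report tables as TSV; missing values as NA."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(os.path.join(out_dir, f"{name}.tsv"), sep="\t",
                  index=False, na_rep="NA")
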