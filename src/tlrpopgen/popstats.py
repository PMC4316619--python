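"""Per-locus polymorphism statistics.

Segregating sites, haplotype counts, nucleotide diversity (overall and per
synonymous/nonsynonymous class), the unfolded site-frequency spectrum
polarized against the outgroup, Tajima's D and the unnormalized Fay & Wu H.

Statistics are computed on complete-deletion alignments (every column free of
gaps and ambiguity codes).  Undefined statistics (e.g. D with S = 0, H with no
polarizable site) propagate as NaN, never as zeros.

Class-specific statistics use only sites classified cleanly as synonymous or
nonsynonymous by :func:`tlrpopgen.codon.classify_segregating_site`; ``complex``
sites contribute to all-sites statistics only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import codon
from .alignment import HaplotypeAlignment
from .exceptions import UsageError

ALL = "all"
NAN = float("nan")


# ---------------------------------------------------------------------------
# SFS-level formulas (shared with the coalescent engine)

def harmonic(n, power=1):
    """a1 = sum 1/i (power=1) or a2 = sum 1/i^2 (power=2) for i < n."""
    return sum(1.0 / i**power for i in range(1, n))


def tajimas_d_from_counts(n, S, pi_count):
    """Tajima (1989) D from sample size, segregating sites and the mean
    pairwise difference count (not per site).  NaN when S == 0."""
    if S == 0:
        return NAN
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    if var <= 0:
        return NAN
    return (pi_count - S / a1) / math.sqrt(var)


def theta_pi_from_sfs(n, sfs):
    """Mean pairwise differences from an unfolded SFS (xi_1..xi_{n-1})."""
    i = np.arange(1, n)
    sfs = np.asarray(sfs, dtype=float)
    return float(np.sum(2.0 * i * (n - i) * sfs) / (n * (n - 1.0)))


def theta_h_from_sfs(n, sfs):
    i = np.arange(1, n)
    sfs = np.asarray(sfs, dtype=float)
    return float(np.sum(2.0 * i * i * sfs) / (n * (n - 1.0)))


def fay_wu_h_from_sfs(n, sfs):
    """Unnormalized Fay & Wu (2000) H = theta_pi - theta_H; NaN if the SFS is
    empty."""
    if np.sum(sfs) == 0:
        return NAN
    return theta_pi_from_sfs(n, sfs) - theta_h_from_sfs(n, sfs)


def tajimas_d_from_sfs(n, sfs):
    S = int(np.sum(sfs))
    return tajimas_d_from_counts(n, S, theta_pi_from_sfs(n, sfs))


# ---------------------------------------------------------------------------
# Alignment-level statistics

def _column_allele_counts(col):
    vals, counts = np.unique(col, return_counts=True)
    return dict(zip(vals.tolist(), counts.tolist()))


def segregating_columns(aln: HaplotypeAlignment):
    """Indices of columns with >= 2 distinct residues among the haplotypes."""
    h = aln.haplotypes
    seg = (h != h[0]).any(axis=0)
    return np.nonzero(seg)[0].tolist()


def haplotype_count(aln: HaplotypeAlignment) -> int:
    """Number of distinct haplotype strings."""
    return len(set(aln.haplotype_strings()))


def classify_columns(aln: HaplotypeAlignment, columns):
    """Map segregating column -> synonymous/nonsynonymous/complex label."""
    return {c: codon.classify_segregating_site(aln, c) for c in columns}


def segregating_sites_and_sfs(aln: HaplotypeAlignment, columns=None):
    """(S, unfolded SFS, unpolarizable column list).

    The derived state at a biallelic site is the allele differing from the
    outgroup residue.  Sites where the outgroup carries a third allele (or is
    missing) and sites with more than two ingroup alleles are unpolarizable:
    they count toward S (and pi, D) but are excluded from the SFS and H.
    """
    if columns is None:
        columns = segregating_columns(aln)
    n = aln.n_haplotypes
    sfs = np.zeros(n - 1, dtype=int)
    unpolarizable = []
    for c in columns:
        counts = _column_allele_counts(aln.haplotypes[:, c])
        alleles = [a for a in counts if a in codon.BASES]
        out = aln.outgroup[c]
        if len(alleles) != 2 or out not in alleles:
            unpolarizable.append(c)
            continue
        derived = alleles[0] if alleles[1] == out else alleles[1]
        k = counts[derived]
        if 1 <= k <= n - 1:
            sfs[k - 1] += 1
        else:  # derived allele fixed among haplotypes: not segregating here
            unpolarizable.append(c)
    return len(columns), sfs, unpolarizable


def _pairwise_diff_count(aln, columns):
    """Mean number of pairwise differences over the given columns."""
    n = aln.n_haplotypes
    npairs = n * (n - 1) / 2.0
    total = 0.0
    for c in columns:
        counts = _column_allele_counts(aln.haplotypes[:, c])
        same = sum(v * (v - 1) / 2.0 for v in counts.values())
        total += (npairs - same) / npairs
    return total


def _class_columns(aln, site_class, labels=None):
    cols = segregating_columns(aln)
    if site_class == ALL:
        return cols, labels
    if not aln.coding:
        raise UsageError("class-specific statistics require a coding locus")
    if labels is None:
        labels = classify_columns(aln, cols)
    return [c for c in cols if labels[c] == site_class], labels


def _class_site_denominator(aln, site_class):
    """Number of sites of the class, averaged over haplotypes (NG86)."""
    if site_class == ALL:
        return float(aln.length)
    start, stop = aln.codon_region
    totals = []
    for row in aln.haplotypes:
        counts = codon.count_syn_nonsyn_sites("".join(row[start:stop]))
        totals.append(
            counts.syn_sites if site_class == codon.SYNONYMOUS else counts.nonsyn_sites
        )
    return float(np.mean(totals))


def nucleotide_diversity(aln: HaplotypeAlignment, site_class=ALL, labels=None):
    """Per-site nucleotide diversity pi for a site class.

    Overall pi divides by alignment length; class-specific pi divides by the
    NG86 class site count averaged over haplotypes.  NaN for a single
    haplotype or a zero class denominator.
    """
    if aln.n_haplotypes < 2:
        return NAN
    cols, labels = _class_columns(aln, site_class, labels)
    denom = _class_site_denominator(aln, site_class)
    if denom <= 0:
        return NAN
    return _pairwise_diff_count(aln, cols) / denom


def tajimas_d(aln: HaplotypeAlignment, site_class=ALL, labels=None):
    """Tajima's D restricted to a site class; NaN when the class has S = 0."""
    cols, labels = _class_columns(aln, site_class, labels)
    return tajimas_d_from_counts(
        aln.n_haplotypes, len(cols), _pairwise_diff_count(aln, cols)
    )


def fay_wu_h(aln: HaplotypeAlignment, site_class=ALL, labels=None):
    """Unnormalized per-locus Fay & Wu H for a site class; NaN when the class
    has no polarizable segregating site."""
    cols, labels = _class_columns(aln, site_class, labels)
    _, sfs, _ = segregating_sites_and_sfs(aln, cols)
    return fay_wu_h_from_sfs(aln.n_haplotypes, sfs)


@dataclass
class LocusSummary:
    """Per-locus statistics record mirroring one row of the report tables."""

    locus_id: str
    n_copies: int
    nsites: int
    S: int
    n_alleles: int
    pi: float
    pi_syn: float = NAN
    pi_nonsyn: float = NAN
    D_all: float = NAN
    D_syn: float = NAN
    D_nonsyn: float = NAN
    H_all: float = NAN
    H_syn: float = NAN
    H_nonsyn: float = NAN
    sfs: np.ndarray = field(default=None, repr=False)
    n_unpolarizable: int = 0
    f_input: float = NAN  # externally supplied constraint estimate


def locus_summary(aln: HaplotypeAlignment, f_input=NAN) -> LocusSummary:
    """Compute the full per-locus statistics record.

    Class-specific statistics are filled only for coding loci.
    """
    cols = segregating_columns(aln)
    S, sfs, unpol = segregating_sites_and_sfs(aln, cols)
    summary = LocusSummary(
        locus_id=aln.locus_id,
        n_copies=aln.n_haplotypes,
        nsites=aln.length,
        S=S,
        n_alleles=haplotype_count(aln),
        pi=nucleotide_diversity(aln),
        D_all=tajimas_d(aln),
        H_all=fay_wu_h_from_sfs(aln.n_haplotypes, sfs),
        sfs=sfs,
        n_unpolarizable=len(unpol),
        f_input=f_input,
    )
    if aln.coding:
        labels = classify_columns(aln, cols)
        for cls, suffix in ((codon.SYNONYMOUS, "syn"), (codon.NONSYNONYMOUS, "nonsyn")):
            setattr(summary, f"pi_{suffix}", nucleotide_diversity(aln, cls, labels))
            setattr(summary, f"D_{suffix}", tajimas_d(aln, cls, labels))
            setattr(summary, f"H_{suffix}", fay_wu_h(aln, cls, labels))
    return summary


def summaries_to_table(summaries):
    """LocusSummary rows as a pandas DataFrame (missing values as NaN -> NA
    when written as TSV)."""
    import pandas as pd

    cols = [
        "locus_id", "n_copies", "nsites", "n_alleles", "S",
        "pi", "pi_nonsyn", "pi_syn",
        "D_all", "D_syn", "D_nonsyn", "H_all", "H_syn", "H_nonsyn",
        "f_input",
    ]
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in summaries])
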