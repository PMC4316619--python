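"""Genetic-code machinery: NG86 site counting, segregating-site
classification, pairwise dN/dS and mutation-rate calibration.

Synonymous/nonsynonymous site counts follow Nei & Gojobori (1986): the
synonymous fraction of a codon position is the proportion of the three
possible single-base changes that preserve the amino acid; changes creating a
stop codon count as nonsynonymous.  Pairwise divergence averages codon
differences over all minimal mutational pathways (pathways through stop codons
excluded) and applies the Jukes-Cantor correction
``d = -(3/4) ln(1 - (4/3) p)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from .exceptions import ConfigurationError, DataError, SaturationError, UsageError

from Bio.Data import CodonTable

BASES = "ACGT"

#: Standard nuclear genetic code, codon -> one-letter amino acid ('*' = stop).
_tbl = CodonTable.unambiguous_dna_by_id[1]
STANDARD_CODE = dict(_tbl.forward_table)
STANDARD_CODE.update({c: "*" for c in _tbl.stop_codons})
del _tbl

STOP_CODONS = frozenset(c for c, aa in STANDARD_CODE.items() if aa == "*")


def translate_codon(codon, code=STANDARD_CODE):
    return code[codon]


@dataclass(frozen=True)
class SiteClassCounts:
    """Fractional NG86 synonymous/nonsynonymous site counts."""

    syn_sites: float
    nonsyn_sites: float

    def __add__(self, other):
        return SiteClassCounts(
            self.syn_sites + other.syn_sites, self.nonsyn_sites + other.nonsyn_sites
        )


@dataclass(frozen=True)
class DivergenceEstimate:
    """Jukes-Cantor-corrected NG86 divergence between two coding sequences."""

    dN: float
    dS: float
    omega: float  # nan when dS == 0
    ncodons: int


@dataclass(frozen=True)
class ClassRates:
    """Per-class mutation rates and population-scaled locus rates."""

    mu_syn: float
    mu_nonsyn: float
    theta_syn: float
    theta_nonsyn: float
    rho: float


def _codon_site_counts(codon, code=STANDARD_CODE):
    """NG86 (syn, nonsyn) site count for one codon; None if unusable."""
    if any(b not in BASES for b in codon):
        return None
    if codon in STOP_CODONS:
        return None
    aa = code[codon]
    syn = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if code[mutant] == aa:  # stop codons never match a sense aa
                syn += 1.0
    return syn / 3.0, 3.0 - syn / 3.0


def iter_codons(seq, frame_offset=0):
    """Yield (codon_index, codon_string) over complete codons of ``seq``."""
    seq = "".join(seq) if not isinstance(seq, str) else seq
    ncod = (len(seq) - frame_offset) // 3
    for i in range(ncod):
        yield i, seq[frame_offset + 3 * i : frame_offset + 3 * i + 3]


def count_syn_nonsyn_sites(seq, frame_offset=0, code=STANDARD_CODE) -> SiteClassCounts:
    """NG86 fractional site counts over all complete codons of a sequence.

    Codons containing missing data are skipped.  A stop codon in the final
    codon position is excluded from counting; an internal stop raises
    :class:`DataError`.
    """
    seq = "".join(seq) if not isinstance(seq, str) else seq
    if len(seq) < frame_offset + 3:
        raise UsageError("sequence shorter than one codon past frame_offset")
    codons = list(iter_codons(seq, frame_offset))
    syn = nonsyn = 0.0
    for i, codon in codons:
        if any(b not in BASES for b in codon):
            continue
        if codon in STOP_CODONS:
            if i == len(codons) - 1:
                continue
            raise DataError(f"internal stop codon at codon index {i}")
        s, n = _codon_site_counts(codon, code)
        syn += s
        nonsyn += n
    return SiteClassCounts(syn, nonsyn)


SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
COMPLEX = "complex"


def _majority(column):
    """Most frequent valid base in a column (ties broken alphabetically)."""
    counts = {}
    for b in column:
        if b in BASES:
            counts[b] = counts.get(b, 0) + 1
    if not counts:
        return None
    return max(sorted(counts), key=lambda b: counts[b])


def _effect(codon_bg, pos_in_codon, a1, a2, code=STANDARD_CODE):
    """synonymous/nonsynonymous label for alleles a1/a2 at one codon position,
    holding the rest of the codon at ``codon_bg``."""
    c1 = codon_bg[:pos_in_codon] + a1 + codon_bg[pos_in_codon + 1 :]
    c2 = codon_bg[:pos_in_codon] + a2 + codon_bg[pos_in_codon + 1 :]
    if c1 in STOP_CODONS or c2 in STOP_CODONS:
        return NONSYNONYMOUS
    return SYNONYMOUS if code[c1] == code[c2] else NONSYNONYMOUS


def classify_segregating_site(aln, column, code=STANDARD_CODE):
    """Classify a segregating site of a coding locus.

    The amino-acid effect of the two observed alleles is evaluated holding the
    other two codon positions at their majority state.  Sites with more than
    two alleles, sites whose codon carries another segregating position that
    flips the classification depending on its background allele, and sites
    outside the complete-codon region are labelled ``complex`` (excluded from
    class-specific statistics).
    """
    if not aln.coding:
        raise UsageError("classify_segregating_site requires a coding locus")
    col = aln.haplotypes[:, column]
    alleles = sorted({b for b in col if b in BASES})
    if len(alleles) < 2:
        raise UsageError(f"column {column} is monomorphic")
    if len(alleles) > 2:
        return COMPLEX
    start, stop = aln.codon_region
    if not (start <= column < stop):
        return COMPLEX
    cod_idx = (column - start) // 3
    cod_cols = [start + 3 * cod_idx + k for k in range(3)]
    pos_in_codon = column - cod_cols[0]
    # majority background at the other two positions
    bg = []
    for c in cod_cols:
        m = _majority(aln.haplotypes[:, c])
        if m is None:
            return COMPLEX
        bg.append(m)
    codon_bg = "".join(bg)
    a1, a2 = alleles
    label = _effect(codon_bg, pos_in_codon, a1, a2, code)
    # other segregating positions in the same codon: classification must be
    # stable under both background alleles, otherwise the site is complex
    for c in cod_cols:
        if c == column:
            continue
        other = sorted({b for b in aln.haplotypes[:, c] if b in BASES})
        if len(other) > 2:
            return COMPLEX
        if len(other) == 2:
            p = c - cod_cols[0]
            labels = set()
            for ob in other:
                alt_bg = codon_bg[:p] + ob + codon_bg[p + 1 :]
                labels.add(_effect(alt_bg, pos_in_codon, a1, a2, code))
            if len(labels) > 1:
                return COMPLEX
            label = labels.pop()
    return label


def _pathway_counts(c1, c2, code=STANDARD_CODE):
    """(syn_diffs, nonsyn_diffs) between two codons, averaged over all minimal
    mutational pathways that avoid stop codons."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != c2:
                ok = False
                break
            if cur in STOP_CODONS or nxt in STOP_CODONS:
                nonsyn += 1
            elif code[cur] == code[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            results.append((syn, nonsyn))
    if not results:  # all pathways blocked; fall back to counting every path
        results = [(0, len(diff_pos))]
    syn = sum(r[0] for r in results) / len(results)
    nonsyn = sum(r[1] for r in results) / len(results)
    return syn, nonsyn


def jukes_cantor(p):
    """JC69 distance from a proportion of differing sites."""
    if p < 0:
        raise UsageError("proportion must be >= 0")
    if p >= 0.75:
        raise SaturationError(f"p = {p:.4f} >= 3/4: Jukes-Cantor saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def pairwise_dn_ds(seq1, seq2, frame_offset=0, code=STANDARD_CODE) -> DivergenceEstimate:
    """NG86 pairwise dN/dS with Jukes-Cantor correction.

    Codons with missing data or a stop in either sequence are skipped; site
    denominators are averaged between the two sequences.  ``omega`` is NaN
    when ``dS == 0``.
    """
    seq1 = "".join(seq1) if not isinstance(seq1, str) else seq1
    seq2 = "".join(seq2) if not isinstance(seq2, str) else seq2
    if len(seq1) != len(seq2):
        raise UsageError("sequences must have equal length")
    syn_sites = nonsyn_sites = 0.0
    syn_diff = nonsyn_diff = 0.0
    ncod = 0
    for (_, c1), (_, c2) in zip(iter_codons(seq1, frame_offset), iter_codons(seq2, frame_offset)):
        if any(b not in BASES for b in c1 + c2):
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        s1 = _codon_site_counts(c1, code)
        s2 = _codon_site_counts(c2, code)
        syn_sites += (s1[0] + s2[0]) / 2.0
        nonsyn_sites += (s1[1] + s2[1]) / 2.0
        sd, nd = _pathway_counts(c1, c2, code)
        syn_diff += sd
        nonsyn_diff += nd
        ncod += 1
    pS = syn_diff / syn_sites if syn_sites > 0 else 0.0
    pN = nonsyn_diff / nonsyn_sites if nonsyn_sites > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    omega = dN / dS if dS > 0 else float("nan")
    return DivergenceEstimate(dN=dN, dS=dS, omega=omega, ncodons=ncod)


def calibrate_class_rates(
    dS_out,
    dN_out,
    divergence_time,
    generation_time,
    Ne,
    syn_sites,
    nonsyn_sites,
    rho_per_site=0.0,
) -> ClassRates:
    """Per-generation class mutation rates from divergence to the outgroup.

    ``mu_class = d_class / (2 T / g)`` where ``T`` is the outgroup divergence
    time in years and ``g`` the generation time: divergence accumulates along
    both branches.  Population-scaled locus rates are ``theta = 4 Ne mu L``
    per class and ``rho = 4 Ne rho_per_site L_total``.
    """
    if generation_time <= 0:
        raise ConfigurationError("generation_time must be > 0")
    if divergence_time <= 0:
        raise ConfigurationError("divergence_time must be > 0")
    if dS_out < 0 or dN_out < 0:
        raise UsageError("divergences must be >= 0")
    gens = 2.0 * divergence_time / generation_time
    mu_syn = dS_out / gens
    mu_nonsyn = dN_out / gens
    L_total = syn_sites + nonsyn_sites
    return ClassRates(
        mu_syn=mu_syn,
        mu_nonsyn=mu_nonsyn,
        theta_syn=4.0 * Ne * mu_syn * syn_sites,
        theta_nonsyn=4.0 * Ne * mu_nonsyn * nonsyn_sites,
        rho=4.0 * Ne * rho_per_site * L_total,
    )
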