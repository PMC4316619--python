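"""McDonald-Kreitman and Hudson-Kreitman-Aguade machinery.

The MK test contrasts synonymous/nonsynonymous counts of sites that are
polymorphic within the ingroup against sites fixed between the ingroup and the
outgroup; its 2x2 table is tested with Fisher's exact test and summarized by
the neutrality index ``NI = (Pn/Ps)/(Dn/Ds)``.

The multilocus HKA test fits the one-population-plus-divergence neutral
system of Hudson, Kreitman & Aguade (1987): one scaled mutation parameter
``theta_i`` per locus and a common divergence time ``T`` (in 2N generations),
with

* ``E[S_i] = theta_i a(n_i)``,   ``Var[S_i] = a1 theta + a2 theta^2``
* ``E[D_i] = theta_i (T + 1)``,  ``Var[D_i] = E[D_i] + theta_i^2``

where ``D_i`` is the mean pairwise ingroup-outgroup difference count.  The
goodness-of-fit statistic ``X2`` sums squared deviations scaled by these
variances; significance comes from coalescent simulation under the fitted
neutral parameters.  Per-locus leave-one-out contributions to ``X2`` serve as
the locus-flagging diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from . import codon
from .alignment import HaplotypeAlignment
from .coalescent import (
    DemographicModel,
    drop_mutations,
    simulate_genealogy,
    two_population_split_model,
)
from .exceptions import ConfigurationError, NumericalError, UsageError
from .popstats import harmonic, segregating_columns

NAN = float("nan")


@dataclass(frozen=True)
class MKCounts:
    """2x2 polymorphism/divergence x synonymous/nonsynonymous table.

    ``n_complex`` counts sites excluded because their class could not be
    determined unambiguously.
    """

    Pn: int
    Ps: int
    Dn: int
    Ds: int
    n_complex: int = 0

    def __post_init__(self):
        if min(self.Pn, self.Ps, self.Dn, self.Ds) < 0:
            raise UsageError("MK counts must be non-negative")


def _fixed_site_class(aln, column):
    """synonymous/nonsynonymous/complex label for a fixed ingroup-outgroup
    difference, holding the rest of the codon at the ingroup consensus and
    requiring stability against other varying positions in the codon."""
    start, stop = aln.codon_region
    if not (start <= column < stop):
        return codon.COMPLEX
    cod_idx = (column - start) // 3
    cod_cols = [start + 3 * cod_idx + k for k in range(3)]
    pos = column - cod_cols[0]
    bg = []
    for c in cod_cols:
        counts = {}
        for b in aln.haplotypes[:, c]:
            if b in codon.BASES:
                counts[b] = counts.get(b, 0) + 1
        if not counts:
            return codon.COMPLEX
        bg.append(max(sorted(counts), key=lambda b: counts[b]))
    codon_bg = "".join(bg)
    a_in, a_out = codon_bg[pos], aln.outgroup[column]
    if a_out not in codon.BASES:
        return codon.COMPLEX
    label = codon._effect(codon_bg, pos, a_in, a_out)
    for c in cod_cols:
        if c == column:
            continue
        p = c - cod_cols[0]
        alts = {b for b in aln.haplotypes[:, c] if b in codon.BASES}
        if aln.outgroup[c] in codon.BASES:
            alts.add(aln.outgroup[c])
        if len(alts) > 2:
            return codon.COMPLEX
        labels = set()
        for ob in alts:
            alt_bg = codon_bg[:p] + ob + codon_bg[p + 1 :]
            labels.add(codon._effect(alt_bg, pos, a_in, a_out))
        if len(labels) > 1:
            return codon.COMPLEX
        label = labels.pop()
    return label


def build_mk_table(aln: HaplotypeAlignment) -> MKCounts:
    """Count polymorphic and fixed synonymous/nonsynonymous sites.

    A site is polymorphic if >= 2 alleles segregate among the ingroup
    haplotypes (regardless of the outgroup state) and fixed if the ingroup is
    monomorphic and differs from the outgroup residue.  Complex sites are
    excluded from the table and reported in ``n_complex``.
    """
    if not aln.coding:
        raise UsageError("MK table requires a coding locus")
    if aln.outgroup is None:
        raise ConfigurationError("MK table requires an outgroup")
    Pn = Ps = Dn = Ds = ncx = 0
    seg = set(segregating_columns(aln))
    for c in range(aln.length):
        if c in seg:
            label = codon.classify_segregating_site(aln, c)
            if label == codon.SYNONYMOUS:
                Ps += 1
            elif label == codon.NONSYNONYMOUS:
                Pn += 1
            else:
                ncx += 1
        else:
            a_in = aln.haplotypes[0, c]
            a_out = aln.outgroup[c]
            if a_in in codon.BASES and a_out in codon.BASES and a_in != a_out:
                label = _fixed_site_class(aln, c)
                if label == codon.SYNONYMOUS:
                    Ds += 1
                elif label == codon.NONSYNONYMOUS:
                    Dn += 1
                else:
                    ncx += 1
    return MKCounts(Pn=Pn, Ps=Ps, Dn=Dn, Ds=Ds, n_complex=ncx)


def fisher_exact_2x2(table: MKCounts):
    """Two-sided Fisher exact p-value for the MK table.

    Uses the standard convention (sum of hypergeometric point probabilities
    <= the observed one).  If any margin is zero the table is untestable and
    p = 1 is returned with ``testable=False``.
    """
    t = [[table.Pn, table.Dn], [table.Ps, table.Ds]]
    margins = (
        table.Pn + table.Dn, table.Ps + table.Ds,
        table.Pn + table.Ps, table.Dn + table.Ds,
    )
    if 0 in margins:
        return 1.0, False
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p), True


def neutrality_index(table: MKCounts):
    """NI = (Pn/Ps)/(Dn/Ds); NaN when Ps, Dn or Ds is zero."""
    if table.Ps == 0 or table.Dn == 0 or table.Ds == 0:
        return NAN
    return (table.Pn / table.Ps) / (table.Dn / table.Ds)


@dataclass
class MKResult:
    counts: MKCounts
    p_value: float
    testable: bool
    ni: float


def mk_test(aln: HaplotypeAlignment) -> MKResult:
    counts = build_mk_table(aln)
    p, testable = fisher_exact_2x2(counts)
    return MKResult(counts=counts, p_value=p, testable=testable, ni=neutrality_index(counts))


# ---------------------------------------------------------------------------
# HKA

@dataclass(frozen=True)
class HKALocus:
    """Per-locus HKA input: segregating sites, mean pairwise divergence to the
    outgroup (count, not per site), alignment length and sample size."""

    locus_id: str
    S: float
    D: float
    L: float
    n: int

    def __post_init__(self):
        if self.S < 0 or self.D < 0 or self.L <= 0 or self.n < 2:
            raise UsageError(f"invalid HKA record for {self.locus_id}")


@dataclass
class HKAResult:
    X2: float
    T: float
    thetas: dict          # locus_id -> fitted per-locus theta
    contributions: dict   # locus_id -> leave-one-out drop in X2
    locus_X2: dict        # locus_id -> this locus's own terms of X2


def _fit(loci):
    """Solve the HKA moment equations for (T, theta_i)."""
    a = {l.locus_id: harmonic(l.n) for l in loci}
    sumD = sum(l.D for l in loci)

    def g(T):
        return sumD - (T + 1.0) * sum(
            (l.S + l.D) / (a[l.locus_id] + T + 1.0) for l in loci
        )

    lo = 1e-9
    if g(lo) <= 0:
        T = lo  # degenerate: essentially no divergence beyond polymorphism
    else:
        hi = 10.0
        while g(hi) > 0 and hi < 1e9:
            hi *= 10.0
        if g(hi) > 0:
            raise NumericalError("HKA moment equation has no root")
        T = optimize.brentq(g, lo, hi, xtol=1e-12, rtol=1e-12)
    thetas = {
        l.locus_id: (l.S + l.D) / (a[l.locus_id] + T + 1.0) for l in loci
    }
    return T, thetas


def _x2_terms(loci, T, thetas):
    terms = {}
    for l in loci:
        th = thetas[l.locus_id]
        a1 = harmonic(l.n)
        a2 = harmonic(l.n, 2)
        ES = th * a1
        varS = a1 * th + a2 * th * th
        ED = th * (T + 1.0)
        varD = ED + th * th
        t = 0.0
        if varS > 0:
            t += (l.S - ES) ** 2 / varS
        if varD > 0:
            t += (l.D - ED) ** 2 / varD
        terms[l.locus_id] = t
    return terms


def hka_statistic(loci) -> HKAResult:
    """Fit the multilocus HKA system and return the goodness-of-fit X2.

    With a single locus the fit is saturated (X2 = 0).  ``contributions``
    holds the drop in X2 when each locus is removed and the remaining system
    refitted — the locus-flagging surrogate for a per-locus selection test.
    """
    loci = list(loci)
    if not loci:
        raise UsageError("need at least 1 locus")
    T, thetas = _fit(loci)
    terms = _x2_terms(loci, T, thetas)
    X2 = sum(terms.values())
    contributions = {}
    if len(loci) > 2:
        for l in loci:
            rest = [x for x in loci if x.locus_id != l.locus_id]
            Tr, thr = _fit(rest)
            contributions[l.locus_id] = X2 - sum(_x2_terms(rest, Tr, thr).values())
    return HKAResult(X2=X2, T=T, thetas=thetas, contributions=contributions,
                     locus_X2=terms)


def _simulate_locus_SD(n, theta, T, rng):
    """Simulate (S, D) for one locus: S among the ingroup sample, D the mean
    pairwise ingroup-outgroup difference count."""
    demography = two_population_split_model(T, sizes=(1.0, 1.0), ancestral_size=1.0)
    arg = simulate_genealogy((n, 1), demography, 0.0, rng)
    muts = drop_mutations(arg, theta, 0.0, rng)
    if len(muts) == 0:
        return 0.0, 0.0
    cin = muts.counts[:, 0]
    cout = muts.counts[:, 1]
    S = int(np.sum((cin >= 1) & (cin <= n - 1)))
    D = float(np.sum(np.where(cout == 1, n - cin, cin)) / n)
    return S, D


def hka_simulation_pvalue(loci, fit: HKAResult, nreps=10_000, seed=None, rng=None):
    """Empirical p-value for the HKA X2 by neutral coalescent simulation.

    Each replicate simulates every locus under the fitted (theta_i, T),
    refits the system and recomputes X2; p = (1 + #{X2_sim >= X2_obs}) /
    (nreps + 1).  ``nreps`` < 100 triggers a warning flag in the output.
    """
    loci = list(loci)
    if rng is None:
        rng = np.random.default_rng(seed)
    warned = nreps < 100
    count = 0
    for _ in range(nreps):
        sim = []
        for l in loci:
            S, D = _simulate_locus_SD(l.n, fit.thetas[l.locus_id], fit.T, rng)
            sim.append(HKALocus(l.locus_id, S, D, l.L, l.n))
        Ts, ths = _fit(sim)
        x2 = sum(_x2_terms(sim, Ts, ths).values())
        if x2 >= fit.X2:
            count += 1
    p = (1 + count) / (nreps + 1)
    return (p, warned) if warned else (p, False)


def hka_input_from_alignments(alignments, lineage=None):
    """Build HKA per-locus records from complete-deletion alignments.

    ``lineage`` restricts the ingroup to one lineage label.  D is the mean
    pairwise difference count between ingroup haplotypes and the outgroup."""
    records = []
    for aln in alignments:
        if lineage is not None:
            ids = [s for s, l in zip(aln.samples, aln.lineages) if l == lineage]
            aln = aln.subset(ids)
        n = aln.n_haplotypes
        S = len(segregating_columns(aln))
        diffs = (aln.haplotypes != aln.outgroup[None, :])
        valid = np.isin(aln.outgroup, list(codon.BASES))
        D = float(diffs[:, valid].sum(axis=1).mean())
        records.append(HKALocus(aln.locus_id, S, D, aln.length, n))
    return records
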