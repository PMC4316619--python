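"""Neutral coalescent simulator with recombination and piecewise demography.

A Hudson-style backwards-in-time simulator over a continuous locus ``[0, 1)``.
Lineages carry ancestral-material segments; recombination splits a lineage at
a uniform breakpoint within its ancestral extent, coalescence merges two
lineages and records parent-child edges over the overlapping material.  A
genomic region is retired as soon as its local most recent common ancestor is
reached.  Mutations are dropped on edges under the infinite-sites model in two
classes (synonymous / nonsynonymous) with class probability proportional to
the class rates.

Units and rates
---------------
Time is measured in units of ``2 N0`` generations throughout (so the expected
pairwise coalescence time in a population of relative size 1 is 1.0).  With
``theta = 4 N0 mu L`` and ``rho = 4 N0 r L`` per locus:

* pairwise coalescence rate in a population of relative size ``x``: ``1/x``;
* recombination rate of a lineage with ancestral extent ``g``: ``rho g / 2``;
* migration rate per lineage: ``M / 2`` with ``M = 4 N0 m``;
* mutation rate per unit branch length: ``theta / 2``.

Randomness comes from a single :class:`numpy.random.Generator` (PCG64);
given identical seeds and configurations output is bit-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ModelError, UsageError
from .popstats import fay_wu_h_from_sfs, tajimas_d_from_sfs

#: hard horizon (in 2N0-generation units) after which a model that still has
#: uncoalesced lineages and no pending events is declared malformed
TIME_HORIZON = 32768.0


@dataclass(frozen=True)
class DemographicEvent:
    """One backwards-in-time event.

    kind is one of ``size_change`` (params: pop, size), ``join`` (params:
    source, dest — all lineages of ``source`` move to ``dest``),
    ``migration_change`` (params: rate, the scaled symmetric rate 4*N0*m) or
    ``sweep_merge`` (params: pop, fraction — each lineage of ``pop`` is,
    independently with the given probability, caught by a sweep and all
    caught lineages coalesce instantaneously; the star-like approximation of
    an incomplete selective sweep that reached frequency ``fraction``).
    """

    time: float
    kind: str
    params: dict

    def __post_init__(self):
        if self.kind not in ("size_change", "join", "migration_change", "sweep_merge"):
            raise ModelError(f"unknown event kind {self.kind!r}")
        if self.time < 0:
            raise ModelError("event time must be >= 0")


@dataclass(frozen=True)
class DemographicModel:
    """Piecewise-constant multi-population history.

    ``populations`` holds present-day sizes relative to the reference size
    ``reference_N0`` (diploid).  Event times are in units of 2*N0 generations,
    strictly increasing.
    """

    populations: tuple
    events: tuple = ()
    reference_N0: float = 1.0e5
    migration: float = 0.0  # scaled symmetric rate 4*N0*m at time 0

    def __post_init__(self):
        if any(s <= 0 for s in self.populations):
            raise ModelError("population sizes must be > 0")
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ModelError("event times must be strictly increasing")
        for e in self.events:
            if e.kind in ("size_change",) and e.params["size"] <= 0:
                raise ModelError("size_change size must be > 0")

    @property
    def n_populations(self):
        return len(self.populations)

    def to_json(self):
        return json.dumps(
            {
                "populations": list(self.populations),
                "reference_N0": self.reference_N0,
                "migration": self.migration,
                "events": [
                    {"time": e.time, "kind": e.kind, "params": e.params}
                    for e in self.events
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text):
        doc = json.loads(text)
        return cls(
            populations=tuple(doc["populations"]),
            events=tuple(
                DemographicEvent(e["time"], e["kind"], e["params"])
                for e in doc["events"]
            ),
            reference_N0=doc.get("reference_N0", 1.0e5),
            migration=doc.get("migration", 0.0),
        )


def constant_model(size=1.0, N0=1.0e5) -> DemographicModel:
    return DemographicModel(populations=(size,), reference_N0=N0)


def two_population_split_model(
    split_time,
    sizes=(1.0, 1.0),
    ancestral_size=1.0,
    migration=0.0,
    N0=1.0e5,
) -> DemographicModel:
    """Two populations splitting from a common ancestor at ``split_time``
    (backwards: population 1 joins population 0, which then takes the
    ancestral size)."""
    events = (
        DemographicEvent(split_time, "join", {"source": 1, "dest": 0}),
        DemographicEvent(
            math.nextafter(split_time, math.inf),
            "size_change",
            {"pop": 0, "size": ancestral_size},
        ),
    )
    return DemographicModel(
        populations=tuple(sizes), events=events, reference_N0=N0, migration=migration
    )


def study_model(
    split_time,
    outgroup_time,
    sizes=(1.0, 1.0, 1.0),
    ancestral_size=1.0,
    migration=0.0,
    N0=1.0e5,
) -> DemographicModel:
    """Two ingroup lineages plus an outgroup population: the ingroup pair
    merges at ``split_time``, the outgroup at the (deeper) ``outgroup_time``."""
    if outgroup_time <= split_time:
        raise ModelError("outgroup_time must exceed split_time")
    events = (
        DemographicEvent(split_time, "join", {"source": 1, "dest": 0}),
        DemographicEvent(outgroup_time, "join", {"source": 2, "dest": 0}),
        DemographicEvent(
            math.nextafter(outgroup_time, math.inf),
            "size_change",
            {"pop": 0, "size": ancestral_size},
        ),
    )
    return DemographicModel(
        populations=tuple(sizes), events=events, reference_N0=N0, migration=migration
    )


def with_sweep(model: DemographicModel, pop, fraction, time) -> DemographicModel:
    """Insert an incomplete-sweep emulation on one population of a model.

    At ``time`` units ago, each lineage of ``pop`` is caught by the sweep
    independently with probability ``fraction`` (the frequency the swept
    haplotype reached) and all caught lineages coalesce instantaneously.
    ``fraction = 0`` leaves the model unchanged.  This genealogical
    star-collapse is the standard demographic emulation of a recent
    incomplete sweep and produces an excess of high-frequency derived alleles
    (negative Fay & Wu H) plus negative-skewed Tajima's D.
    """
    if not 0 <= fraction <= 1:
        raise ModelError("sweep fraction must be in [0, 1]")
    if fraction == 0:
        return model
    events = sorted(
        list(model.events)
        + [DemographicEvent(time, "sweep_merge", {"pop": pop, "fraction": fraction})],
        key=lambda e: e.time,
    )
    fixed = []
    for e in events:
        t = e.time
        if fixed and t <= fixed[-1].time:
            t = math.nextafter(fixed[-1].time, math.inf)
            e = DemographicEvent(t, e.kind, e.params)
        fixed.append(e)
    return DemographicModel(
        populations=model.populations,
        events=tuple(fixed),
        reference_N0=model.reference_N0,
        migration=model.migration,
    )


def crash_recovery_model(
    crash_depth,
    crash_start=0.01,
    crash_duration=0.05,
    size=1.0,
    N0=1.0e5,
) -> DemographicModel:
    """Single population that went through a recent crash of relative depth
    ``crash_depth`` (1.0 = no crash) between ``crash_start`` and
    ``crash_start + crash_duration`` time units ago.  Used to emulate the
    genealogical distortion of a recent sweep."""
    if not 0 < crash_depth <= 1:
        raise ModelError("crash_depth must be in (0, 1]")
    if crash_depth == 1.0:
        return constant_model(size, N0)
    events = (
        DemographicEvent(crash_start, "size_change", {"pop": 0, "size": size * crash_depth}),
        DemographicEvent(
            crash_start + crash_duration, "size_change", {"pop": 0, "size": size}
        ),
    )
    return DemographicModel(populations=(size,), events=events, reference_N0=N0)


@dataclass(frozen=True)
class SimulationConfig:
    """Per-locus simulation settings.

    ``n_samples`` gives the number of sampled gene copies per population
    (parallel to the model's populations).  ``theta_syn``/``theta_nonsyn`` and
    ``rho`` are per-locus scaled rates; non-coding loci put everything in
    ``theta_syn``.  ``L`` is the locus length in sites (used when threading
    mutations onto sequences).
    """

    n_samples: tuple
    theta_syn: float = 0.0
    theta_nonsyn: float = 0.0
    rho: float = 0.0
    L: int = 1000
    nreps: int = 100_000
    seed: int = None

    def __post_init__(self):
        if sum(self.n_samples) < 2:
            raise UsageError("need at least 2 sampled gene copies")
        if min(self.theta_syn, self.theta_nonsyn, self.rho) < 0:
            raise UsageError("rates must be >= 0")
        if self.nreps < 1:
            raise UsageError("nreps must be >= 1")

    @property
    def theta_total(self):
        return self.theta_syn + self.theta_nonsyn


class AncestralGraph:
    """Genealogical output of one replicate: node times plus edges.

    Each edge spans a genomic interval ``[left, right)`` (fractions of the
    locus) and records the per-sample-group count of samples subtended by its
    child over that interval, which makes derived-allele counts of mutations
    available without tree traversal.
    """

    __slots__ = (
        "n_samples", "node_times",
        "edge_left", "edge_right", "edge_parent", "edge_child",
        "edge_counts", "sample_groups",
    )

    def __init__(self, n_samples, node_times, edges, edge_counts, sample_groups):
        self.n_samples = tuple(n_samples)
        self.node_times = np.asarray(node_times, dtype=float)
        edges = np.asarray(edges, dtype=float).reshape(-1, 4)
        self.edge_left = edges[:, 0]
        self.edge_right = edges[:, 1]
        self.edge_parent = edges[:, 2].astype(int)
        self.edge_child = edges[:, 3].astype(int)
        self.edge_counts = np.asarray(edge_counts, dtype=int).reshape(
            -1, len(n_samples)
        )
        self.sample_groups = np.asarray(sample_groups, dtype=int)

    @property
    def n_total(self):
        return int(sum(self.n_samples))

    @property
    def n_edges(self):
        return len(self.edge_parent)

    def branch_lengths(self):
        return self.node_times[self.edge_parent] - self.node_times[self.edge_child]

    def total_branch_length(self):
        """Genome-averaged total branch length (equals the tree length when
        rho = 0)."""
        return float(
            np.sum(self.branch_lengths() * (self.edge_right - self.edge_left))
        )

    def tmrca(self):
        return float(self.node_times.max()) if len(self.node_times) else 0.0

    def samples_below(self, node, x):
        """Sample ids subtended by ``node`` in the marginal tree at position
        ``x``."""
        n = self.n_total
        out, stack = [], [int(node)]
        while stack:
            u = stack.pop()
            if u < n:
                out.append(u)
                continue
            mask = (
                (self.edge_parent == u) & (self.edge_left <= x) & (x < self.edge_right)
            )
            stack.extend(self.edge_child[mask].tolist())
        return sorted(out)


def simulate_genealogy(n_samples, demography: DemographicModel, rho=0.0, rng=None):
    """Simulate one ancestral recombination graph under the model.

    ``n_samples`` is the per-population sample configuration; sample nodes are
    numbered population by population.  Raises :class:`ModelError` if the
    lineages cannot fully coalesce (no migration and no join events merging
    the occupied populations, or the time horizon is exceeded).
    """
    if rng is None:
        rng = np.random.default_rng()
    npop = demography.n_populations
    if len(n_samples) != npop:
        raise ModelError("n_samples length must match the number of populations")
    n_total = int(sum(n_samples))
    if n_total < 2:
        raise UsageError("need at least 2 samples")

    sizes = list(demography.populations)
    migration = demography.migration
    pending = list(demography.events)

    node_times = [0.0] * n_total
    edges = []       # (left, right, parent, child)
    edge_counts = [] # per-group subtended sample counts of the child interval

    # lineages: list of [pop, segments]; segment = (left, right, node, counts)
    lineages = []
    sample_groups = []
    nid = 0
    for pop, ns in enumerate(n_samples):
        for _ in range(ns):
            counts = tuple(1 if g == pop else 0 for g in range(npop))
            lineages.append([pop, [(0.0, 1.0, nid, counts)]])
            sample_groups.append(pop)
            nid += 1

    t = 0.0

    def extent(segs):
        return segs[-1][1] - segs[0][0]

    while lineages:
        kpop = [0] * npop
        for lin in lineages:
            kpop[lin[0]] += 1
        coal_rates = [k * (k - 1) / 2.0 / sizes[p] for p, k in enumerate(kpop)]
        coal_total = sum(coal_rates)
        extents = [extent(lin[1]) for lin in lineages]
        rec_total = 0.5 * rho * sum(extents)
        mig_total = 0.5 * migration * len(lineages) if npop > 1 else 0.0
        total = coal_total + rec_total + mig_total

        if total <= 0:
            if pending:
                t = pending[0].time
            else:
                raise ModelError(
                    f"lineages cannot coalesce at t={t:.3g}: no events pending "
                    "and total event rate is zero"
                )
        else:
            wait = rng.exponential(1.0 / total)
            if pending and t + wait >= pending[0].time:
                t = pending[0].time
            else:
                t += wait
                if t > TIME_HORIZON:
                    raise ModelError(
                        f"coalescent did not complete by the time horizon "
                        f"{TIME_HORIZON}"
                    )
                u = rng.uniform(0.0, total)
                if u < coal_total:
                    # choose population, then an unordered pair within it
                    for p, r in enumerate(coal_rates):
                        if u < r:
                            break
                        u -= r
                    members = [i for i, lin in enumerate(lineages) if lin[0] == p]
                    ia, ib = rng.choice(len(members), size=2, replace=False)
                    a, b = members[ia], members[ib]
                    la, lb = lineages[a][1], lineages[b][1]
                    merged, new_node = _merge_segments(
                        la, lb, t, nid, n_total, node_times, edges, edge_counts
                    )
                    if new_node:
                        nid += 1
                    for idx in sorted((a, b), reverse=True):
                        del lineages[idx]
                    if merged:
                        lineages.append([p, merged])
                elif u < coal_total + rec_total:
                    u2 = rng.uniform(0.0, sum(extents))
                    for i, g in enumerate(extents):
                        if u2 < g:
                            break
                        u2 -= g
                    segs = lineages[i][1]
                    bp = segs[0][0] + u2
                    left_segs, right_segs = _split_segments(segs, bp)
                    if left_segs and right_segs:
                        pop = lineages[i][0]
                        lineages[i][1] = left_segs
                        lineages.append([pop, right_segs])
                    # a breakpoint outside actual material changes nothing
                else:
                    i = rng.integers(len(lineages))
                    others = [p for p in range(npop) if p != lineages[i][0]]
                    lineages[i][0] = others[rng.integers(len(others))]
                continue

        # apply the pending event at time t
        while pending and pending[0].time <= t:
            ev = pending.pop(0)
            if ev.kind == "size_change":
                sizes[ev.params["pop"]] = ev.params["size"]
            elif ev.kind == "migration_change":
                migration = ev.params["rate"]
            elif ev.kind == "join":
                src, dst = ev.params["source"], ev.params["dest"]
                for lin in lineages:
                    if lin[0] == src:
                        lin[0] = dst
            elif ev.kind == "sweep_merge":
                pop = ev.params["pop"]
                frac = ev.params["fraction"]
                swept = [
                    i for i, lin in enumerate(lineages)
                    if lin[0] == pop and rng.random() < frac
                ]
                if len(swept) >= 2:
                    acc = lineages[swept[0]][1]
                    for i in swept[1:]:
                        acc, made = _merge_segments(
                            acc, lineages[i][1], ev.time, nid, n_total,
                            node_times, edges, edge_counts,
                        )
                        if made:
                            nid += 1
                    for i in sorted(swept, reverse=True):
                        del lineages[i]
                    if acc:
                        lineages.append([pop, acc])

    return AncestralGraph(n_samples, node_times, edges, edge_counts, sample_groups)


def _split_segments(segs, bp):
    left, right = [], []
    for seg in segs:
        l, r, node, counts = seg
        if r <= bp:
            left.append(seg)
        elif l >= bp:
            right.append(seg)
        else:
            left.append((l, bp, node, counts))
            right.append((bp, r, node, counts))
    return left, right


def _merge_segments(la, lb, t, next_id, n_total, node_times, edges, edge_counts):
    """Coalesce two segment lists at time ``t``.

    Returns (surviving segment list, whether a new node was created).  Where
    the two lists overlap, a parent node is created (once per coalescence) and
    edges are recorded; overlap regions whose combined count reaches the full
    sample size have found their local MRCA and are retired.
    """
    bps = sorted({s[0] for s in la} | {s[1] for s in la} | {s[0] for s in lb} | {s[1] for s in lb})
    out = []
    new_node = None

    def cover(segs, l, r):
        for s in segs:
            if s[0] <= l and r <= s[1]:
                return s
        return None

    for l, r in zip(bps, bps[1:]):
        sa = cover(la, l, r)
        sb = cover(lb, l, r)
        if sa is None and sb is None:
            continue
        if sb is None:
            out.append((l, r, sa[2], sa[3]))
        elif sa is None:
            out.append((l, r, sb[2], sb[3]))
        else:
            if new_node is None:
                new_node = next_id
                node_times.append(t)
            combined = tuple(x + y for x, y in zip(sa[3], sb[3]))
            edges.append((l, r, new_node, sa[2]))
            edge_counts.append(sa[3])
            edges.append((l, r, new_node, sb[2]))
            edge_counts.append(sb[3])
            if sum(combined) < n_total:
                out.append((l, r, new_node, combined))
    # compact adjacent segments with identical node and counts
    compact = []
    for seg in out:
        if compact and compact[-1][1] == seg[0] and compact[-1][2] == seg[2] \
                and compact[-1][3] == seg[3]:
            compact[-1] = (compact[-1][0], seg[1], seg[2], seg[3])
        else:
            compact.append(seg)
    return compact, new_node is not None


@dataclass
class MutationTable:
    """Simulated polymorphisms: positions in [0, 1), per-group derived counts,
    class labels and the edge each mutation fell on."""

    positions: np.ndarray
    counts: np.ndarray       # (n_mutations, n_groups)
    is_synonymous: np.ndarray
    edge_index: np.ndarray

    def __len__(self):
        return len(self.positions)

    def derived_counts(self, groups=None):
        """Total derived count, optionally restricted to the given sample
        groups."""
        if groups is None:
            return self.counts.sum(axis=1)
        return self.counts[:, list(groups)].sum(axis=1)


def drop_mutations(arg: AncestralGraph, theta_syn, theta_nonsyn, rng=None) -> MutationTable:
    """Drop infinite-sites mutations on the graph.

    Poisson counts per edge at total rate ``(theta_syn + theta_nonsyn)/2`` per
    unit branch length (times the genomic span of the edge); each mutation is
    synonymous with probability ``theta_syn / theta_total`` and placed
    uniformly within its edge's interval.
    """
    if rng is None:
        rng = np.random.default_rng()
    if theta_syn < 0 or theta_nonsyn < 0:
        raise UsageError("rates must be >= 0")
    theta = theta_syn + theta_nonsyn
    empty = MutationTable(
        positions=np.empty(0),
        counts=np.empty((0, len(arg.n_samples)), dtype=int),
        is_synonymous=np.empty(0, dtype=bool),
        edge_index=np.empty(0, dtype=int),
    )
    if theta == 0 or arg.n_edges == 0:
        return empty
    span = arg.edge_right - arg.edge_left
    lam = 0.5 * theta * arg.branch_lengths() * span
    n_mut = rng.poisson(lam)
    total = int(n_mut.sum())
    if total == 0:
        return empty
    edge_idx = np.repeat(np.arange(arg.n_edges), n_mut)
    positions = arg.edge_left[edge_idx] + rng.random(total) * span[edge_idx]
    is_syn = rng.random(total) < (theta_syn / theta)
    order = np.argsort(positions)
    return MutationTable(
        positions=positions[order],
        counts=arg.edge_counts[edge_idx[order]],
        is_synonymous=is_syn[order],
        edge_index=edge_idx[order],
    )


# ---------------------------------------------------------------------------
# Null distributions and empirical p-values

TWO_SIDED = "two_sided"
ONE_SIDED_LOW = "one_sided_low"


@dataclass
class NullDistribution:
    statistic: str
    values: np.ndarray
    n_undefined: int = 0
    observed: float = None
    p_value: float = None
    sidedness: str = None


def _sfs_from_mutations(muts: MutationTable, n, site_class, focal_groups=None):
    counts = muts.derived_counts(focal_groups)
    if site_class == "synonymous":
        counts = counts[muts.is_synonymous]
    elif site_class == "nonsynonymous":
        counts = counts[~muts.is_synonymous]
    counts = counts[(counts >= 1) & (counts <= n - 1)]
    return np.bincount(counts, minlength=n)[1:n]


def simulate_null_distribution(
    statistic,
    config: SimulationConfig,
    demography: DemographicModel,
    site_class="all",
    focal_population=0,
    rng=None,
) -> NullDistribution:
    """Simulate the null distribution of Tajima's D or Fay & Wu's H.

    Per replicate the statistic is computed from the simulated unfolded SFS of
    the focal population's samples (ancestral states are exact by
    construction).  Replicates where the statistic is undefined (no
    segregating site of the class) are counted in ``n_undefined``.
    """
    if statistic not in ("D", "H"):
        raise UsageError("statistic must be 'D' or 'H'")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_samples[focal_population]
    if n < 2:
        raise UsageError("focal population must have >= 2 samples")
    values = []
    n_undefined = 0
    for _ in range(config.nreps):
        arg = simulate_genealogy(config.n_samples, demography, config.rho, rng)
        muts = drop_mutations(arg, config.theta_syn, config.theta_nonsyn, rng)
        sfs = _sfs_from_mutations(muts, n, site_class, (focal_population,))
        v = tajimas_d_from_sfs(n, sfs) if statistic == "D" else fay_wu_h_from_sfs(n, sfs)
        if math.isnan(v):
            n_undefined += 1
        else:
            values.append(v)
    if not values:
        raise ModelError("all replicates produced an undefined statistic")
    return NullDistribution(
        statistic=statistic, values=np.asarray(values), n_undefined=n_undefined
    )


def empirical_pvalue(observed, null: NullDistribution, sidedness=TWO_SIDED):
    """Pseudocount empirical p-value of an observed statistic against a
    simulated null.

    ``one_sided_low``: p = (1 + #{sim <= obs}) / (1 + m);
    ``two_sided``: twice the smaller tail, capped at 1.
    """
    m = len(null.values)
    if m < 100:
        raise UsageError(f"need >= 100 defined simulated values, have {m}")
    lo = (1 + int(np.sum(null.values <= observed))) / (1 + m)
    hi = (1 + int(np.sum(null.values >= observed))) / (1 + m)
    if sidedness == ONE_SIDED_LOW:
        p = lo
    elif sidedness == TWO_SIDED:
        p = min(1.0, 2.0 * min(lo, hi))
    else:
        raise UsageError(f"unknown sidedness {sidedness!r}")
    return p


def null_test(observed, null: NullDistribution, sidedness) -> NullDistribution:
    """Return a copy of ``null`` with the observed value and p-value filled."""
    p = empirical_pvalue(observed, null, sidedness)
    return NullDistribution(
        statistic=null.statistic,
        values=null.values,
        n_undefined=null.n_undefined,
        observed=observed,
        p_value=p,
        sidedness=sidedness,
    )


def write_ms(path, tables, n_total, command="tlrpopgen"):
    """Write replicates in the ms text dialect (positions only; genotypes are
    not emitted because derived carriers are summarized as counts)."""
    with open(path, "w") as fh:
        fh.write(f"{command} {n_total} {len(tables)}\n\n")
        for muts in tables:
            fh.write("//\n")
            fh.write(f"segsites: {len(muts)}\n")
            if len(muts):
                pos = " ".join(f"{p:.5f}" for p in muts.positions)
                fh.write(f"positions: {pos}\n")
            fh.write("\n")
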