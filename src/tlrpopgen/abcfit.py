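"""Rejection-ABC demographic fitting from a multilocus neutral panel.

Plain rejection ABC: draw parameters from the prior, simulate the multilocus
panel, summarize, standardize each summary by its median absolute deviation
across the simulated table, rank simulations by Euclidean distance to the
observed summary vector and accept the stated quantile.  No regression
adjustment is applied.  Model choice accepts across pooled per-model tables
and reports the acceptance fraction per model.

The default model family is two ingroup populations splitting from a common
ancestor (piecewise-constant sizes, optional symmetric migration); see
:func:`tlrpopgen.coalescent.two_population_split_model`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coalescent import MutationTable
from .exceptions import ConfigurationError, UsageError
from .popstats import tajimas_d_from_counts

NAN = float("nan")


@dataclass(frozen=True)
class PriorSpec:
    """Independent per-parameter priors.

    ``params`` maps name -> (dist, low, high) with dist in {"uniform",
    "loguniform"}; ``low == high`` gives a fixed-value prior.
    """

    params: dict

    def __post_init__(self):
        for name, (dist, lo, hi) in self.params.items():
            if dist not in ("uniform", "loguniform"):
                raise ConfigurationError(f"{name}: unknown distribution {dist!r}")
            if not (math.isfinite(lo) and math.isfinite(hi)) or lo > hi:
                raise ConfigurationError(f"{name}: bounds must be finite and ordered")
            if dist == "loguniform" and lo <= 0:
                raise ConfigurationError(f"{name}: loguniform bounds must be > 0")

    @property
    def names(self):
        return list(self.params)


def draw_prior(spec: PriorSpec, rng) -> dict:
    """One independent draw per parameter."""
    out = {}
    for name, (dist, lo, hi) in spec.params.items():
        if lo == hi:
            out[name] = lo
        elif dist == "uniform":
            out[name] = rng.uniform(lo, hi)
        else:
            out[name] = math.exp(rng.uniform(math.log(lo), math.log(hi)))
    return out


# ---------------------------------------------------------------------------
# Panel summaries

#: fixed ordering of the multilocus summary vector
SUMMARY_NAMES = (
    "mean_pi_a", "var_pi_a", "mean_pi_b", "var_pi_b",
    "mean_D_a", "var_D_a", "mean_D_b", "var_D_b",
    "mean_dxy", "var_dxy", "mean_shared", "mean_fixed",
)


@dataclass(frozen=True)
class TwoLineageLocusSummary:
    """Per-locus input to the ABC summary vector (per-site pi and dxy)."""

    pi_a: float
    pi_b: float
    D_a: float
    D_b: float
    dxy: float
    n_shared: int
    n_fixed: int


def locus_summary_from_mutations(muts: MutationTable, n_a, n_b, L,
                                 group_a=0, group_b=1) -> TwoLineageLocusSummary:
    """Two-lineage summary of a simulated locus from per-group derived counts."""
    ca = muts.counts[:, group_a].astype(float)
    cb = muts.counts[:, group_b].astype(float)
    pa, pb = ca / n_a, cb / n_b

    def _pi(c, n):
        seg = (c >= 1) & (c <= n - 1)
        return float(np.sum(2.0 * c[seg] * (n - c[seg]) / (n * (n - 1.0)))) / L

    def _d(c, n):
        seg = (c >= 1) & (c <= n - 1)
        S = int(seg.sum())
        pi_count = float(np.sum(2.0 * c[seg] * (n - c[seg]) / (n * (n - 1.0))))
        return tajimas_d_from_counts(n, S, pi_count)

    dxy = float(np.sum(pa * (1 - pb) + (1 - pa) * pb)) / L
    shared = int(np.sum((ca >= 1) & (ca <= n_a - 1) & (cb >= 1) & (cb <= n_b - 1)))
    fixed = int(np.sum(((ca == n_a) & (cb == 0)) | ((ca == 0) & (cb == n_b))))
    return TwoLineageLocusSummary(
        pi_a=_pi(ca, n_a), pi_b=_pi(cb, n_b),
        D_a=_d(ca, n_a), D_b=_d(cb, n_b),
        dxy=dxy, n_shared=shared, n_fixed=fixed,
    )


def locus_summary_from_alignment(aln, lineage_a, lineage_b) -> TwoLineageLocusSummary:
    """Two-lineage summary of an observed locus alignment."""
    from . import popstats

    sub_a = aln.subset([s for s, l in zip(aln.samples, aln.lineages) if l == lineage_a])
    sub_b = aln.subset([s for s, l in zip(aln.samples, aln.lineages) if l == lineage_b])
    ha, hb = sub_a.haplotypes, sub_b.haplotypes
    L = aln.length
    dxy = 0.0
    shared = fixed = 0
    for c in range(L):
        va, ca = np.unique(ha[:, c], return_counts=True)
        vb, cb = np.unique(hb[:, c], return_counts=True)
        fa = dict(zip(va.tolist(), (ca / ca.sum()).tolist()))
        fb = dict(zip(vb.tolist(), (cb / cb.sum()).tolist()))
        dxy += 1.0 - sum(fa.get(b, 0.0) * fb.get(b, 0.0) for b in set(fa) | set(fb))
        if len(va) > 1 and len(vb) > 1:
            shared += 1
        elif len(va) == 1 and len(vb) == 1 and va[0] != vb[0]:
            fixed += 1
    return TwoLineageLocusSummary(
        pi_a=popstats.nucleotide_diversity(sub_a),
        pi_b=popstats.nucleotide_diversity(sub_b),
        D_a=popstats.tajimas_d(sub_a),
        D_b=popstats.tajimas_d(sub_b),
        dxy=dxy / L,
        n_shared=shared,
        n_fixed=fixed,
    )


def multilocus_summaries(locus_summaries) -> np.ndarray:
    """Aggregate per-locus two-lineage summaries into the fixed-order vector.

    Undefined Tajima's D values (monomorphic loci) are imputed as 0 — the
    neutral expectation — before averaging.  Raises if a statistic is
    undefined on every locus.
    """
    rows = list(locus_summaries)
    if len(rows) < 2:
        raise UsageError("need >= 2 loci for multilocus summaries")

    def col(attr, impute_zero=False):
        v = np.array([getattr(r, attr) for r in rows], dtype=float)
        if np.all(np.isnan(v)):
            raise ConfigurationError(f"statistic {attr} undefined on all loci")
        if impute_zero:
            v = np.nan_to_num(v, nan=0.0)
        return v

    pa, pb = col("pi_a"), col("pi_b")
    da, db = col("D_a", True), col("D_b", True)
    dxy = col("dxy")
    out = [
        pa.mean(), pa.var(ddof=1), pb.mean(), pb.var(ddof=1),
        da.mean(), da.var(ddof=1), db.mean(), db.var(ddof=1),
        dxy.mean(), dxy.var(ddof=1),
        float(np.mean([r.n_shared for r in rows])),
        float(np.mean([r.n_fixed for r in rows])),
    ]
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Rejection

@dataclass
class ABCResult:
    accepted: dict                 # parameter name -> accepted draws (array)
    accepted_summaries: np.ndarray
    tolerance: float
    point: dict                    # name -> (median, lo95, hi95)
    n_accepted: int = 0
    warning: str = None
    model_probabilities: dict = field(default=None)


def _standardize(observed, table):
    med = np.median(table, axis=0)
    mad = np.median(np.abs(table - med), axis=0)
    scale = np.where(mad > 0, mad, 1.0)  # constant summaries carry no signal
    return (observed - med) / scale, (table - med) / scale


def abc_reject(observed, params, summaries, tolerance) -> ABCResult:
    """Rejection step: accept the ``tolerance`` quantile of simulations
    closest (Euclidean, MAD-standardized) to the observed summary vector.

    ``params`` maps parameter name -> array of drawn values, ``summaries`` is
    the (n_sims, n_summaries) matrix.  Ties in distance are broken by
    simulation order (stable sort), so results are deterministic given the
    table.
    """
    summaries = np.asarray(summaries, dtype=float)
    observed = np.asarray(observed, dtype=float)
    nsims = summaries.shape[0]
    if not 0 < tolerance <= 1:
        raise UsageError("tolerance must be in (0, 1]")
    obs_z, tab_z = _standardize(observed, summaries)
    dist = np.sqrt(np.sum((tab_z - obs_z) ** 2, axis=1))
    n_accept = max(1, int(round(tolerance * nsims)))
    idx = np.argsort(dist, kind="stable")[:n_accept]
    accepted = {k: np.asarray(v)[idx] for k, v in params.items()}
    point = {
        k: (float(np.median(v)),
            float(np.quantile(v, 0.025)),
            float(np.quantile(v, 0.975)))
        for k, v in accepted.items()
    }
    warning = None
    if n_accept < 20:
        warning = f"only {n_accept} draws accepted; posterior summaries unstable"
    return ABCResult(
        accepted=accepted,
        accepted_summaries=summaries[idx],
        tolerance=tolerance,
        point=point,
        n_accepted=n_accept,
        warning=warning,
    )


def abc_model_choice(observed, model_tables, tolerance):
    """Posterior model probabilities by rejection across pooled tables.

    ``model_tables`` maps model name -> (params, summaries); every model must
    contribute the same number of simulations.  The probability of a model is
    the fraction of overall-accepted draws belonging to it.
    """
    names = list(model_tables)
    if len(names) < 2:
        raise UsageError("need >= 2 models")
    counts = {m: np.asarray(model_tables[m][1]).shape[0] for m in names}
    if len(set(counts.values())) != 1:
        raise UsageError("models must have equal simulation counts")
    pooled = np.vstack([np.asarray(model_tables[m][1], dtype=float) for m in names])
    labels = np.concatenate([
        np.full(counts[m], i) for i, m in enumerate(names)
    ])
    observed = np.asarray(observed, dtype=float)
    obs_z, tab_z = _standardize(observed, pooled)
    dist = np.sqrt(np.sum((tab_z - obs_z) ** 2, axis=1))
    n_accept = max(1, int(round(tolerance * pooled.shape[0])))
    idx = np.argsort(dist, kind="stable")[:n_accept]
    if len(idx) == 0:
        raise UsageError("no draws accepted")
    probs = {}
    for i, m in enumerate(names):
        probs[m] = float(np.mean(labels[idx] == i))
    return probs


def simulate_reference_table(spec: PriorSpec, simulate_fn, n_sims, rng):
    """Draw ``n_sims`` parameter vectors and simulate their summaries.

    ``simulate_fn(params, rng) -> summary vector``.  Returns (params dict of
    arrays, summary matrix)."""
    draws = [draw_prior(spec, rng) for _ in range(n_sims)]
    summaries = np.array([simulate_fn(d, rng) for d in draws], dtype=float)
    params = {k: np.array([d[k] for d in draws]) for k in spec.names}
    return params, summaries
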