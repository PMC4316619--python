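"""Study-shaped synthetic datasets with known ground truth.

Generates concrete FASTA haplotype alignments by threading coalescent
mutations onto an ancestral sequence, for a sampling design shaped like the
newt study: two ingroup lineages (38 and 34 gene copies by default) plus one
outgroup copy, a panel of short neutral non-coding loci and a set of long
coding loci with controllable selective constraint or a sweep-like signature.

Coding loci use a placement scheme that makes downstream synonymous /
nonsynonymous classification exact:

* ancestral codons have a pyrimidine (T/C) third position, so no codon in any
  generated haplotype is a stop codon;
* synonymous mutations are T<->C swaps at third positions — synonymous in
  every codon family regardless of what segregates at the other positions;
* nonsynonymous mutations are placed at first/second codon positions, where
  every single-base change is nonsynonymous whenever the third position is a
  pyrimidine.

Selective constraint ``c`` scales the nonsynonymous mutation rate
(``theta_nonsyn_effective = c * theta_nonsyn``).  Incomplete sweeps are
emulated genealogically, not with a true selection model: at a recent time a
given fraction of the focal population's lineages (the frequency the swept
haplotype reached) coalesces instantaneously, producing the excess of
high-frequency derived alleles (negative Fay & Wu H) and negative-skewed
Tajima's D characteristic of a recent incomplete sweep.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .alignment import HaplotypeAlignment
from .coalescent import (
    DemographicEvent,
    DemographicModel,
    drop_mutations,
    simulate_genealogy,
    study_model,
    with_sweep,
)
from .exceptions import ConfigurationError, UsageError

PYRIMIDINES = ("T", "C")
BASES = "ACGT"


@dataclass(frozen=True)
class TruthRecord:
    """Generating parameters of one synthetic locus."""

    locus_id: str
    theta_syn: float
    theta_nonsyn: float
    rho: float
    demography_id: str
    selection: str          # none | constraint | sweep_like
    constraint_c: float
    seed: int

    def __post_init__(self):
        if not 0 <= self.constraint_c <= 1:
            raise UsageError("constraint must be in [0, 1]")
        if self.selection not in ("none", "constraint", "sweep_like"):
            raise UsageError(f"unknown selection label {self.selection!r}")


@dataclass(frozen=True)
class StudySpec:
    """Shape and generating conditions of a synthetic study.

    Defaults emulate the study design: 38 + 34 ingroup gene copies and one
    outgroup copy; 62 neutral 0.5-kb non-coding loci; 11 coding loci of
    500-800 codons with a mixture of constraint levels and two sweep-like
    loci in lineage B.  Rates assume a per-site scaled mutation rate
    ``theta_site = 4 N0 mu`` of 0.005 (matching per-lineage non-coding
    diversity of ~0.005) and an equal per-site recombination rate.  Times are
    in units of 2 N0 generations: the ingroup split at 4.67 (~7 Ma at 6-year
    generations and N0 = 125,000) and the outgroup split at 12.27 (~18.4 Ma).
    """

    n_lineage_a: int = 38
    n_lineage_b: int = 34
    lineage_names: tuple = ("Lm", "Lvg")
    n_neutral: int = 62
    neutral_length: int = 500
    coding_loci: tuple = (
        ("tlr01", 550, "constraint", 0.25),
        ("tlr02", 550, "constraint", 0.25),
        ("tlr03", 600, "constraint", 0.25),
        ("tlr04", 500, "constraint", 0.10),
        ("tlr05", 650, "constraint", 0.25),
        ("tlr06", 700, "constraint", 0.40),
        ("tlr07", 750, "constraint", 0.25),
        ("tlr08", 800, "constraint", 0.25),
        ("tlr09", 600, "constraint", 0.0),
        ("tlr10", 650, "sweep_like", 0.25),
        ("tlr11", 700, "sweep_like", 0.25),
    )
    theta_site: float = 0.005
    rho_site: float = 0.005
    split_time: float = 4.67
    outgroup_time: float = 12.27
    N0: float = 1.25e5
    migration: float = 0.0
    sweep_fraction: float = 0.9
    sweep_time: float = 0.01
    sweep_population: int = 1
    generation_time: float = 6.0
    divergence_time_outgroup: float = 18.4e6


def base_demography(spec: StudySpec) -> DemographicModel:
    return study_model(
        split_time=spec.split_time,
        outgroup_time=spec.outgroup_time,
        sizes=(1.0, 1.0, 1.0),
        migration=spec.migration,
        N0=spec.N0,
    )


def _sample_labels(spec: StudySpec):
    a, b = spec.lineage_names
    samples = [f"{a}_h{i:02d}" for i in range(spec.n_lineage_a)]
    samples += [f"{b}_h{i:02d}" for i in range(spec.n_lineage_b)]
    lineages = [a] * spec.n_lineage_a + [b] * spec.n_lineage_b
    return tuple(samples), tuple(lineages)


def _carriers(arg, muts, i):
    child = int(arg.edge_child[muts.edge_index[i]])
    return arg.samples_below(child, float(muts.positions[i]))


def _build_alignment(spec, locus_id, matrix, outgroup_row, coding):
    samples, lineages = _sample_labels(spec)
    return HaplotypeAlignment(
        locus_id=locus_id,
        samples=samples,
        lineages=lineages,
        haplotypes=matrix,
        outgroup=outgroup_row,
        coding=coding,
        frame_offset=0,
    )


def _thread_mutations(arg, muts, ancestral, columns, derived_fn, n_ingroup, rng):
    """Write mutations into a haplotype matrix.

    ``columns`` are the candidate columns for these mutations (each used at
    most once: infinite sites); ``derived_fn(col, ancestral_base)`` returns
    the derived base.
    """
    n_total = arg.n_total
    matrix = np.tile(np.array(list(ancestral)), (n_total, 1))
    order = {}
    n_mut = len(muts)
    if n_mut > len(columns):
        raise ConfigurationError(
            f"{n_mut} mutations exceed {len(columns)} available columns; "
            "increase locus length or lower theta"
        )
    chosen = rng.choice(len(columns), size=n_mut, replace=False)
    for i in range(n_mut):
        col = columns[chosen[i]]
        derived = derived_fn(col, ancestral[col])
        for s in _carriers(arg, muts, i):
            matrix[s, col] = derived
        order[i] = col
    return matrix, order


def generate_neutral_locus(locus_id, spec: StudySpec, demography, seed):
    """One non-coding locus: random ancestral sequence, mutations anywhere."""
    rng = np.random.default_rng(seed)
    L = spec.neutral_length
    theta = spec.theta_site * L
    rho = spec.rho_site * L
    n = (spec.n_lineage_a, spec.n_lineage_b, 1)
    arg = simulate_genealogy(n, demography, rho, rng)
    muts = drop_mutations(arg, theta, 0.0, rng)
    ancestral = "".join(rng.choice(list(BASES), size=L))

    def derived(col, anc):
        alts = [b for b in BASES if b != anc]
        return alts[rng.integers(3)]

    matrix, _ = _thread_mutations(
        arg, muts, ancestral, list(range(L)), derived,
        spec.n_lineage_a + spec.n_lineage_b, rng,
    )
    n_in = spec.n_lineage_a + spec.n_lineage_b
    aln = _build_alignment(spec, locus_id, matrix[:n_in], matrix[n_in], coding=False)
    truth = TruthRecord(
        locus_id=locus_id, theta_syn=theta, theta_nonsyn=0.0, rho=rho,
        demography_id="base", selection="none", constraint_c=1.0, seed=int(seed),
    )
    return aln, truth


def generate_coding_locus(
    locus_id,
    length_codons,
    spec: StudySpec,
    demography,
    seed,
    constraint_c=1.0,
    selection_label=None,
    demography_id="base",
):
    """One coding locus with exact synonymous/nonsynonymous placement.

    The nonsynonymous rate is ``constraint_c`` times the synonymous per-site
    rate scaled by the number of placement positions of each class (one
    third-position per codon for synonymous, two first/second positions for
    nonsynonymous).
    """
    rng = np.random.default_rng(seed)
    L = 3 * length_codons
    theta_syn = spec.theta_site * length_codons           # one syn column/codon
    theta_nonsyn = constraint_c * spec.theta_site * 2 * length_codons
    rho = spec.rho_site * L
    n = (spec.n_lineage_a, spec.n_lineage_b, 1)
    arg = simulate_genealogy(n, demography, rho, rng)
    muts = drop_mutations(arg, theta_syn, theta_nonsyn, rng)

    # ancestral: any first/second bases, pyrimidine third position
    anc = []
    for _ in range(length_codons):
        anc.append(BASES[rng.integers(4)])
        anc.append(BASES[rng.integers(4)])
        anc.append(PYRIMIDINES[rng.integers(2)])
    ancestral = "".join(anc)

    syn_cols = [3 * k + 2 for k in range(length_codons)]
    nonsyn_cols = [c for k in range(length_codons) for c in (3 * k, 3 * k + 1)]

    n_total = arg.n_total
    matrix = np.tile(np.array(list(ancestral)), (n_total, 1))

    def place(indices, columns, derived_fn):
        if len(indices) == 0:
            return
        if len(indices) > len(columns):
            raise ConfigurationError(
                f"{locus_id}: mutation count exceeds available columns"
            )
        chosen = rng.choice(len(columns), size=len(indices), replace=False)
        for i, ci in zip(indices, chosen):
            col = columns[ci]
            derived = derived_fn(col, ancestral[col])
            for s in _carriers(arg, muts, i):
                matrix[s, col] = derived

    syn_idx = np.nonzero(muts.is_synonymous)[0]
    nonsyn_idx = np.nonzero(~muts.is_synonymous)[0]
    place(syn_idx, syn_cols, lambda col, anc_b: "C" if anc_b == "T" else "T")
    place(
        nonsyn_idx, nonsyn_cols,
        lambda col, anc_b: [b for b in BASES if b != anc_b][rng.integers(3)],
    )

    n_in = spec.n_lineage_a + spec.n_lineage_b
    aln = _build_alignment(spec, locus_id, matrix[:n_in], matrix[n_in], coding=True)
    if selection_label is None:
        selection_label = "constraint" if constraint_c < 1.0 else "none"
    truth = TruthRecord(
        locus_id=locus_id, theta_syn=theta_syn, theta_nonsyn=theta_nonsyn,
        rho=rho, demography_id=demography_id, selection=selection_label,
        constraint_c=constraint_c, seed=int(seed),
    )
    return aln, truth


def inject_sweep_signature(
    locus_id,
    length_codons,
    spec: StudySpec,
    seed,
    constraint_c=0.25,
):
    """Coding locus under the sweep emulation: at ``spec.sweep_time`` units
    ago a fraction ``spec.sweep_fraction`` of the focal population's lineages
    coalesces instantaneously, distorting genealogies toward an excess of
    high-frequency derived alleles (negative H, negative-skewed D)."""
    demography = with_sweep(
        base_demography(spec),
        spec.sweep_population,
        spec.sweep_fraction,
        spec.sweep_time,
    )
    return generate_coding_locus(
        locus_id, length_codons, spec, demography, seed,
        constraint_c=constraint_c, selection_label="sweep_like",
        demography_id="sweep",
    )


def generate_neutral_locus_set(n_loci, spec: StudySpec, demography, seed):
    """The neutral non-coding panel: ``n_loci`` alignments plus truth."""
    ss = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(ss.spawn(n_loci)):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        out.append(
            generate_neutral_locus(f"utr{i + 1:02d}", spec, demography, child_seed)
        )
    return out


def generate_study_dataset(out_dir, spec: StudySpec = None, seed=0):
    """Generate the full synthetic study on disk.

    Writes one FASTA per locus, a study configuration JSON and a truth TSV.
    Deterministic: the same seed yields byte-identical files.  Returns the
    list of (alignment, truth) pairs.
    """
    from .alignment import write_fasta_alignment

    if spec is None:
        spec = StudySpec()
    ids = [f"utr{i + 1:02d}" for i in range(spec.n_neutral)]
    ids += [c[0] for c in spec.coding_loci]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("locus id collision in study spec")

    demography = base_demography(spec)
    pairs = generate_neutral_locus_set(spec.n_neutral, spec, demography, seed)
    ss = np.random.SeedSequence((seed, 1))
    for (locus_id, ncod, sel, c), child in zip(spec.coding_loci, ss.spawn(len(spec.coding_loci))):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        if sel == "sweep_like":
            pairs.append(
                inject_sweep_signature(locus_id, ncod, spec, child_seed, constraint_c=c)
            )
        else:
            pairs.append(
                generate_coding_locus(
                    locus_id, ncod, spec, demography, child_seed, constraint_c=c,
                    selection_label=sel,
                )
            )

    os.makedirs(out_dir, exist_ok=True)
    loci_cfg = []
    for aln, truth in pairs:
        fname = f"{aln.locus_id}.fasta"
        write_fasta_alignment(aln, os.path.join(out_dir, fname))
        loci_cfg.append(
            {
                "locus_id": aln.locus_id,
                "path": fname,
                "coding": aln.coding,
                "frame_offset": aln.frame_offset,
                "gene_class": "coding" if aln.coding else "neutral",
            }
        )
    samples, lineages = _sample_labels(spec)
    lin_map = {}
    for s, l in zip(samples, lineages):
        lin_map.setdefault(l, []).append(s)
    config = {
        "loci": loci_cfg,
        "lineages": lin_map,
        "outgroup_sample": "outgroup",
        "divergence_time_outgroup": spec.divergence_time_outgroup,
        "generation_time": spec.generation_time,
    }
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True)
    with open(os.path.join(out_dir, "truth.tsv"), "w") as fh:
        cols = list(asdict(pairs[0][1]))
        fh.write("\t".join(cols) + "\n")
        for _, truth in pairs:
            d = asdict(truth)
            fh.write("\t".join(str(d[c]) for c in cols) + "\n")
    return pairs
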