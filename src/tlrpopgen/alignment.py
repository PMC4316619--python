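"""Reading, validating and filtering per-locus haplotype alignments.

A locus is represented by a :class:`HaplotypeAlignment`: an in-frame set of
phased haplotypes (gene copies) from one or more evolutionary lineages plus a
single outgroup sequence.  Residues are uppercase ``A/C/G/T``; gaps (``-``) and
IUPAC ambiguity codes are both treated as missing data and stored as ``N``.

Coordinates are 0-based and half-open throughout.  For coding loci
``frame_offset`` gives the 0-based column of the first complete codon; the
codon index of column ``c`` is ``(c - frame_offset) // 3``.

Missing data are handled by *complete deletion* (:func:`apply_complete_deletion`):
every column in which any haplotype or the outgroup carries ``-``/``N`` is
removed before statistics are computed; for coding loci whole codons are
removed so the reading frame is preserved.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import (
    AlignmentFormatError,
    ConfigurationError,
    DegenerateAlignmentError,
)

VALID_BASES = frozenset("ACGT")
MISSING = frozenset("-N")

#: Default generation time (years) used when a study configuration omits it.
#: Small-bodied European newts mature at 2-4 years and breed over several
#: seasons; 6 years is a conventional mid-range figure for Lissotriton.
DEFAULT_GENERATION_TIME = 6.0


def _sanitize(seq: str) -> str:
    """Uppercase a sequence and map non-ACGT, non-gap symbols to N."""
    out = []
    for ch in seq.upper():
        if ch in VALID_BASES:
            out.append(ch)
        elif ch == "-":
            out.append("-")
        else:
            out.append("N")
    return "".join(out)


@dataclass(frozen=True)
class HaplotypeAlignment:
    """Phased in-frame haplotypes for one locus plus one outgroup sequence.

    Attributes
    ----------
    locus_id : str
    samples : tuple of str
        Haplotype (gene-copy) identifiers, order preserved.
    lineages : tuple of str
        Lineage label per haplotype, parallel to ``samples``.
    haplotypes : np.ndarray
        ``(n_haplotypes, length)`` array of single characters.
    outgroup : np.ndarray
        ``(length,)`` array of single characters.
    coding : bool
    frame_offset : int
        0-based offset of the first complete codon (coding loci only).
    column_map : tuple of int, optional
        Original column index of each current column (set by
        :func:`apply_complete_deletion`; identity if never filtered).
    """

    locus_id: str
    samples: tuple
    lineages: tuple
    haplotypes: np.ndarray
    outgroup: np.ndarray
    coding: bool = False
    frame_offset: int = 0
    column_map: tuple = field(default=None)

    def __post_init__(self):
        if self.haplotypes.ndim != 2:
            raise AlignmentFormatError("haplotypes must be a 2-D character array")
        n, length = self.haplotypes.shape
        if n < 2:
            raise AlignmentFormatError(
                f"{self.locus_id}: at least 2 haplotypes required, got {n}"
            )
        if self.outgroup.shape != (length,):
            raise AlignmentFormatError(
                f"{self.locus_id}: outgroup length {self.outgroup.shape[0]} "
                f"!= alignment length {length}"
            )
        if len(self.samples) != n or len(self.lineages) != n:
            raise AlignmentFormatError(
                f"{self.locus_id}: sample/lineage labels do not match haplotype count"
            )
        if self.frame_offset < 0:
            raise AlignmentFormatError("frame_offset must be >= 0")
        if self.column_map is None:
            object.__setattr__(self, "column_map", tuple(range(length)))

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def length(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def codon_region(self):
        """(start, stop) of the in-frame codon region, truncated to codons."""
        ncod = (self.length - self.frame_offset) // 3
        return self.frame_offset, self.frame_offset + 3 * ncod

    def haplotype_strings(self):
        return ["".join(row) for row in self.haplotypes]

    def outgroup_string(self) -> str:
        return "".join(self.outgroup)

    def subset(self, sample_ids) -> "HaplotypeAlignment":
        """Restrict to the given haplotype ids (outgroup retained)."""
        wanted = set(sample_ids)
        idx = [i for i, s in enumerate(self.samples) if s in wanted]
        if len(idx) < 2:
            raise AlignmentFormatError(
                f"{self.locus_id}: subset retains fewer than 2 haplotypes"
            )
        return replace(
            self,
            samples=tuple(self.samples[i] for i in idx),
            lineages=tuple(self.lineages[i] for i in idx),
            haplotypes=self.haplotypes[idx],
        )


def read_fasta_alignment(
    path,
    locus_id=None,
    outgroup_id="outgroup",
    lineage_of=None,
    coding=False,
    frame_offset=0,
) -> HaplotypeAlignment:
    """Read one locus alignment from FASTA.

    The record whose id equals ``outgroup_id`` becomes the outgroup sequence;
    all other records are ingroup haplotypes.  ``lineage_of`` maps sample id to
    lineage label (default: single lineage ``"ingroup"``).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"{path}: empty or not FASTA")
    if len(records) < 2:
        raise AlignmentFormatError(f"{path}: fewer than 2 records")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise AlignmentFormatError(
            f"{path}: records have unequal lengths {sorted(lengths)}"
        )
    outgroup = None
    samples, lineages, rows = [], [], []
    for rec in records:
        seq = _sanitize(str(rec.seq))
        if rec.id == outgroup_id:
            if outgroup is not None:
                raise AlignmentFormatError(f"{path}: duplicate outgroup record")
            outgroup = np.array(list(seq))
            continue
        samples.append(rec.id)
        if lineage_of is None:
            lineages.append("ingroup")
        else:
            try:
                lineages.append(lineage_of[rec.id])
            except KeyError:
                raise ConfigurationError(
                    f"{path}: sample {rec.id!r} has no lineage assignment"
                ) from None
        rows.append(list(seq))
    if outgroup is None:
        raise ConfigurationError(f"{path}: missing outgroup record {outgroup_id!r}")
    return HaplotypeAlignment(
        locus_id=locus_id or os.path.splitext(os.path.basename(str(path)))[0],
        samples=tuple(samples),
        lineages=tuple(lineages),
        haplotypes=np.array(rows),
        outgroup=outgroup,
        coding=coding,
        frame_offset=frame_offset,
    )


def write_fasta_alignment(aln: HaplotypeAlignment, path, outgroup_id="outgroup"):
    """Write an alignment back to FASTA (outgroup record last)."""
    records = [
        SeqRecord(Seq(s), id=sid, description="")
        for sid, s in zip(aln.samples, aln.haplotype_strings())
    ]
    records.append(SeqRecord(Seq(aln.outgroup_string()), id=outgroup_id, description=""))
    SeqIO.write(records, str(path), "fasta")


def apply_complete_deletion(aln: HaplotypeAlignment) -> HaplotypeAlignment:
    """Remove every column with missing data in any haplotype or the outgroup.

    For coding loci the whole codon containing an excluded column is removed so
    that the reading frame is preserved; columns before ``frame_offset`` and
    after the last complete codon are treated site-wise.  The returned
    alignment's ``column_map`` records the original index of each retained
    column.  Idempotent.
    """
    stacked = np.vstack([aln.haplotypes, aln.outgroup[None, :]])
    bad = np.isin(stacked, ("-", "N")).any(axis=0)
    if aln.coding:
        start, stop = aln.codon_region
        for cod in range(start, stop, 3):
            if bad[cod : cod + 3].any():
                bad[cod : cod + 3] = True
    keep = ~bad
    if not keep.any():
        raise DegenerateAlignmentError(
            f"{aln.locus_id}: complete deletion removed all columns"
        )
    if keep.all():
        return aln
    new_map = tuple(np.asarray(aln.column_map)[keep].tolist())
    # recompute frame offset: count retained columns before the old codon start
    if aln.coding:
        start, _ = aln.codon_region
        new_offset = int(keep[:start].sum())
    else:
        new_offset = aln.frame_offset
    return replace(
        aln,
        haplotypes=aln.haplotypes[:, keep],
        outgroup=aln.outgroup[keep],
        column_map=new_map,
        frame_offset=new_offset,
    )


@dataclass(frozen=True)
class LocusDescriptor:
    locus_id: str
    path: str
    coding: bool = False
    frame_offset: int = 0
    gene_class: str = "unassigned"
    outgroup_id: str = "outgroup"


@dataclass(frozen=True)
class StudyConfig:
    """Cross-validated description of a multi-locus study.

    ``lineages`` maps lineage label to a tuple of sample (gene-copy) ids; every
    sample referenced by a locus belongs to exactly one lineage.
    """

    loci: tuple
    lineages: dict
    outgroup_sample: str = "outgroup"
    divergence_time_outgroup: float = 18.4e6
    generation_time: float = DEFAULT_GENERATION_TIME
    base_dir: str = "."

    def __post_init__(self):
        if self.divergence_time_outgroup <= 0:
            raise ConfigurationError("divergence_time_outgroup must be > 0")
        if self.generation_time <= 0:
            raise ConfigurationError("generation_time must be > 0")
        seen = {}
        for lin, ids in self.lineages.items():
            for sid in ids:
                if sid in seen:
                    raise ConfigurationError(
                        f"sample {sid!r} assigned to lineages "
                        f"{seen[sid]!r} and {lin!r}"
                    )
                seen[sid] = lin

    @property
    def lineage_of(self) -> dict:
        return {sid: lin for lin, ids in self.lineages.items() for sid in ids}

    def load_alignment(self, desc: LocusDescriptor) -> HaplotypeAlignment:
        path = os.path.join(self.base_dir, desc.path)
        if not os.path.exists(path):
            raise IOError(f"{desc.locus_id}: alignment file {path!r} not found")
        return read_fasta_alignment(
            path,
            locus_id=desc.locus_id,
            outgroup_id=desc.outgroup_id,
            lineage_of=self.lineage_of,
            coding=desc.coding,
            frame_offset=desc.frame_offset,
        )


def load_study_config(path) -> StudyConfig:
    """Load a study configuration from a JSON document.

    Expected keys: ``loci`` (list of descriptor objects), ``lineages``
    (label -> list of sample ids), optional ``outgroup_sample``,
    ``divergence_time_outgroup`` (years), ``generation_time`` (years).
    Referenced alignment files must exist relative to the config location.
    """
    path = str(path)
    with open(path) as fh:
        doc = json.load(fh)
    base = os.path.dirname(os.path.abspath(path))
    loci = tuple(
        LocusDescriptor(
            locus_id=d["locus_id"],
            path=d["path"],
            coding=bool(d.get("coding", False)),
            frame_offset=int(d.get("frame_offset", 0)),
            gene_class=d.get("gene_class", "unassigned"),
            outgroup_id=d.get("outgroup_id", doc.get("outgroup_sample", "outgroup")),
        )
        for d in doc["loci"]
    )
    cfg = StudyConfig(
        loci=loci,
        lineages={k: tuple(v) for k, v in doc["lineages"].items()},
        outgroup_sample=doc.get("outgroup_sample", "outgroup"),
        divergence_time_outgroup=float(doc.get("divergence_time_outgroup", 18.4e6)),
        generation_time=float(doc.get("generation_time", DEFAULT_GENERATION_TIME)),
        base_dir=base,
    )
    for desc in cfg.loci:
        full = os.path.join(base, desc.path)
        if not os.path.exists(full):
            raise IOError(f"locus {desc.locus_id}: file {full!r} not found")
    return cfg
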