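"""Quantification of editing at previously catalogued A-to-I sites.

The caller follows the printed criteria literally: only base calls with
Phred quality >= 25 count; a catalogued site is edited when the A-to-G
(or T-to-C on the reverse strand) fraction is >= 1% of the quality-passing
depth and all other mismatches together stay <= 1%; sites editing above 3%
in the ADAR-null strain are blacklisted as non-editing artifacts.

Threshold comparisons are exact: fractions of integer counts are compared
as rationals against the decimal thresholds, never through binary floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import infer_editing_strand
from .formats import NT_CODE, NUCLEOTIDES, PileupColumn, SampleMeta, SiteRecord


@dataclass(frozen=True)
class EditingConfig:
    """Thresholds of the known-site analysis (defaults = printed values)."""

    q_min: int = 25  # minimum Phred quality per base call
    theta_site: float = 0.01  # target change minimum fraction (inclusive)
    theta_other: float = 0.01  # aggregate other-change maximum (inclusive)
    theta_mut: float = 0.03  # ADAR-null blacklist bound (exclusive)
    aggregate_other: bool = True  # sum all non-target mismatches (else per-change)
    min_expressed_depth: int = 1  # editing-matrix expressed flag

    def __post_init__(self):
        if self.q_min < 0:
            raise ValueError("q_min must be >= 0")
        for name in ("theta_site", "theta_other", "theta_mut"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")


@lru_cache(maxsize=None)
def _frac(threshold: float) -> Fraction:
    # str() round-trips the decimal literal the user wrote (0.05 -> "0.05"),
    # so 2/40 >= 0.05 holds exactly.
    return Fraction(str(threshold))


# A-to-I signature: edited strand '+' shows as A>G, '-' as T>C.
TARGET_ALT = {"A": "G", "T": "C"}


class NucCounts:
    """Quality-passing base counts at one position, by nucleotide and strand."""

    __slots__ = ("chrom", "pos", "ref", "mat")

    def __init__(self, chrom="", pos=0, ref="N", mat=None):
        self.chrom = chrom
        self.pos = int(pos)
        self.ref = ref
        self.mat = np.zeros((4, 2), dtype=np.int64) if mat is None else mat

    def add_column(self, col: PileupColumn, q_min: int) -> "NucCounts":
        if self.ref == "N":
            self.chrom, self.pos, self.ref = col.chrom, col.pos, col.ref
        elif (self.chrom, self.pos) == (col.chrom, col.pos) and self.ref != col.ref:
            raise ValueError(
                f"reference disagreement at {col.chrom}:{col.pos}: "
                f"{self.ref} vs {col.ref}"
            )
        keep = col.quals >= q_min
        codes = col.codes[keep]
        fwd = col.fwd[keep]
        np.add.at(self.mat, (codes[fwd], 0), 1)
        np.add.at(self.mat, (codes[~fwd], 1), 1)
        return self

    @property
    def depth(self) -> int:
        return int(self.mat.sum())

    def count(self, nt: str) -> int:
        return int(self.mat[NT_CODE[nt]].sum())

    def as_dict(self) -> dict[tuple[str, str], int]:
        return {
            (nt, strand): int(self.mat[NT_CODE[nt], j])
            for nt in NUCLEOTIDES
            for j, strand in enumerate("+-")
            if self.mat[NT_CODE[nt], j]
        }

    def drop_alt(self, alt: str) -> "NucCounts":
        mat = self.mat.copy()
        mat[NT_CODE[alt]] = 0
        return NucCounts(self.chrom, self.pos, self.ref, mat)

    def merge(self, other: "NucCounts") -> "NucCounts":
        if self.ref != "N" and other.ref != "N" and self.ref != other.ref:
            raise ValueError("reference disagreement in merge")
        return NucCounts(
            self.chrom or other.chrom,
            self.pos or other.pos,
            other.ref if self.ref == "N" else self.ref,
            self.mat + other.mat,
        )


def quality_filter_column(col: PileupColumn, q_min: int = 25) -> NucCounts:
    """Drop calls below the Phred threshold; count the rest by (nt, strand)."""
    return NucCounts().add_column(col, q_min)


def merge_replicates(columns: Sequence[PileupColumn]) -> PileupColumn:
    """Pool decoded columns of one position across replicas.

    Pooled calls are the concatenation of the per-replica calls, so pooled
    depth is additive and the pooled target fraction is the depth-weighted
    mean of per-replica fractions.
    """
    if not columns:
        raise ValueError("no columns to merge")
    first = columns[0]
    for col in columns[1:]:
        if (col.chrom, col.pos) != (first.chrom, first.pos):
            raise ValueError("cannot merge columns of different positions")
        if col.ref != first.ref:
            raise ValueError(
                f"reference disagreement at {first.chrom}:{first.pos}"
            )
    return PileupColumn(
        first.chrom,
        first.pos,
        first.ref,
        np.concatenate([c.codes for c in columns]),
        np.concatenate([c.fwd for c in columns]),
        np.concatenate([c.quals for c in columns]),
        sample=None,
    )


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

EDITED = "edited"
NOT_EDITED = "not_edited"
NOT_EXPRESSED = "not_expressed"


@dataclass(frozen=True)
class KnownCall:
    status: str  # edited | not_edited | not_expressed
    record: SiteRecord | None = None


def call_known_site(
    counts: NucCounts, ref_base: str, config: EditingConfig = EditingConfig()
) -> KnownCall:
    """Apply the known-site criteria to quality-filtered counts.

    Edited iff target fraction >= theta_site and the other-mismatch
    fraction (aggregate by default) <= theta_other.  Zero depth is
    "not expressed", which is distinct from "not edited".
    """
    ref_base = ref_base.upper()
    if ref_base not in TARGET_ALT:
        raise ValueError(f"not an A-to-I-assessable reference base: {ref_base!r}")
    depth = counts.depth
    if depth == 0:
        return KnownCall(NOT_EXPRESSED)
    alt = TARGET_ALT[ref_base]
    n_target = counts.count(alt)
    others = {
        nt: counts.count(nt) for nt in NUCLEOTIDES if nt not in (ref_base, alt)
    }
    n_other = sum(others.values())
    if Fraction(n_target, depth) < _frac(config.theta_site):
        return KnownCall(NOT_EDITED)
    if config.aggregate_other:
        if Fraction(n_other, depth) > _frac(config.theta_other):
            return KnownCall(NOT_EDITED)
    else:
        if any(
            Fraction(c, depth) > _frac(config.theta_other) for c in others.values()
        ):
            return KnownCall(NOT_EDITED)
    change = f"{ref_base}>{alt}"
    return KnownCall(
        EDITED,
        SiteRecord(
            chrom=counts.chrom,
            pos=counts.pos,
            strand=infer_editing_strand(ref_base, change),
            ref=ref_base,
            change=change,
            level=n_target / depth,
            n_target=n_target,
            n_other=n_other,
            n_total=depth,
            status="known",
        ),
    )


def build_adar_blacklist(
    adar_counts: Mapping[tuple[str, int], NucCounts],
    sites: Iterable[tuple[str, int, str]],
    theta_mut: float = 0.03,
) -> tuple[set[tuple[str, int]], set[tuple[str, int]]]:
    """Sites whose target change exceeds theta_mut in the pooled ADAR-null data.

    Returns (blacklisted, unassessable); a site with zero ADAR-null coverage
    cannot be assessed and is retained with a flag.  The bound is exclusive:
    exactly theta_mut is retained.
    """
    blacklisted: set[tuple[str, int]] = set()
    unassessable: set[tuple[str, int]] = set()
    for chrom, pos, ref in sites:
        ref = ref.upper()
        nc = adar_counts.get((chrom, pos))
        if nc is None or nc.depth == 0:
            unassessable.add((chrom, pos))
            continue
        alt = TARGET_ALT.get(ref)
        if alt is None:
            continue
        if Fraction(nc.count(alt), nc.depth) > _frac(theta_mut):
            blacklisted.add((chrom, pos))
    return blacklisted, unassessable


# ---------------------------------------------------------------------------
# gene-level pooling and the editing matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneEditingSummary:
    gene_id: str
    n_target: int
    n_total: int

    @property
    def level(self) -> float | None:
        return None if self.n_total == 0 else self.n_target / self.n_total


def gene_level_editing(
    gene_id: str, site_counts: Sequence[tuple[NucCounts, str]]
) -> GeneEditingSummary:
    """Pool target and total counts over a gene's catalogued sites.

    ``site_counts`` pairs quality-filtered counts with the site's reference
    base; the gene-level fraction is (sum n_target) / (sum n_total) exactly.
    """
    n_target = n_total = 0
    for nc, ref in site_counts:
        n_total += nc.depth
        alt = TARGET_ALT[ref.upper()]
        n_target += nc.count(alt)
    return GeneEditingSummary(gene_id, n_target, n_total)


@dataclass
class EditingMatrix:
    """Unthresholded site x sample editing levels with expression flags.

    ``levels`` holds the raw target-change fraction (no calling thresholds);
    a cell whose quality-passing depth is below ``min_expressed_depth`` is
    flagged unexpressed and its level is undefined (NaN), not zero.
    """

    levels: pd.DataFrame
    expressed: pd.DataFrame


def editing_matrix(
    per_sample_counts: Mapping[str, Mapping[tuple[str, int], NucCounts]],
    sites: Sequence[tuple[str, int, str]],
    min_expressed_depth: int = 1,
) -> EditingMatrix:
    index = [f"{c}:{p}" for c, p, _ in sites]
    samples = list(per_sample_counts)
    levels = pd.DataFrame(np.nan, index=index, columns=samples)
    expressed = pd.DataFrame(False, index=index, columns=samples)
    for sample, counts in per_sample_counts.items():
        for (chrom, pos, ref), label in zip(sites, index):
            nc = counts.get((chrom, pos))
            depth = 0 if nc is None else nc.depth
            if depth >= min_expressed_depth and depth > 0:
                expressed.loc[label, sample] = True
                levels.loc[label, sample] = nc.count(TARGET_ALT[ref.upper()]) / depth
    return EditingMatrix(levels=levels, expressed=expressed)


# ---------------------------------------------------------------------------
# catalogue I/O and the pooled pipeline
# ---------------------------------------------------------------------------


def read_catalogue(path) -> list[tuple[str, int, str]]:
    """Known-site catalogue: TSV of (chrom, pos, ref)."""
    sites = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.split()
            sites.append((f[0], int(f[1]), f[2].upper()))
    return sites


def write_catalogue(sites: Iterable[tuple[str, int, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\n")
        for chrom, pos, ref in sites:
            fh.write(f"{chrom}\t{pos}\t{ref}\n")


def collect_site_counts(
    pileup_paths: Sequence, positions: set[tuple[str, int]], q_min: int
) -> dict[tuple[str, int], NucCounts]:
    """Stream pileup files, accumulating quality-passing counts at positions."""
    from .formats import read_pileup

    acc: dict[tuple[str, int], NucCounts] = {}
    for path in pileup_paths:
        for col in read_pileup(path):
            key = (col.chrom, col.pos)
            if key in positions:
                acc.setdefault(key, NucCounts()).add_column(col, q_min)
    return acc


@dataclass
class KnownSiteResult:
    records_by_group: dict[tuple[str, str], list[SiteRecord]]
    blacklisted: set[tuple[str, int]]
    unassessable: set[tuple[str, int]]
    not_expressed: list[tuple[str, int]]
    # pooled quality-passing counts at catalogue positions, per strain+stage
    pooled_counts: dict[tuple[str, str], dict[tuple[str, int], NucCounts]] = field(
        default_factory=dict
    )
    gene_summaries: list[GeneEditingSummary] = field(default_factory=list)

    @property
    def records(self) -> list[SiteRecord]:
        return [r for recs in self.records_by_group.values() for r in recs]


def run_known_site_analysis(
    pileups_by_sample: Mapping[SampleMeta, object],
    catalogue: Sequence[tuple[str, int, str]],
    config: EditingConfig = EditingConfig(),
    stage: str | None = None,
) -> KnownSiteResult:
    """Known-site editing on strain+stage pooled pileups.

    Replicas of one strain and stage are pooled (additive counts), the
    ADAR-null pool of the same stage supplies the 3% blacklist, and the
    criteria are applied per catalogued site on the wild-type and adbp-1
    pools.
    """
    positions = {(c, p) for c, p, _ in catalogue}
    by_group: dict[tuple[str, str], list] = {}
    for meta, path in pileups_by_sample.items():
        if stage is not None and meta.stage != stage:
            continue
        by_group.setdefault((meta.strain, meta.stage), []).append(path)

    pooled: dict[tuple[str, str], dict[tuple[str, int], NucCounts]] = {
        grp: collect_site_counts(paths, positions, config.q_min)
        for grp, paths in by_group.items()
    }

    records_by_group: dict[tuple[str, str], list[SiteRecord]] = {}
    blacklisted_all: set = set()
    unassessable_all: set = set()
    not_expressed: list = []
    for (strain, stg), counts in sorted(pooled.items()):
        if strain == "adar_null":
            continue
        adar = pooled.get(("adar_null", stg), {})
        blacklist, unassessable = build_adar_blacklist(
            adar, catalogue, config.theta_mut
        )
        blacklisted_all |= blacklist
        unassessable_all |= unassessable
        records = records_by_group.setdefault((strain, stg), [])
        for chrom, pos, ref in catalogue:
            if (chrom, pos) in blacklist:
                continue
            nc = counts.get((chrom, pos), NucCounts(chrom, pos, ref))
            call = call_known_site(nc, ref, config)
            if call.status == EDITED:
                records.append(call.record)
            elif call.status == NOT_EXPRESSED:
                not_expressed.append((chrom, pos))
    return KnownSiteResult(
        records_by_group=records_by_group,
        blacklisted=blacklisted_all,
        unassessable=unassessable_all,
        not_expressed=not_expressed,
        pooled_counts=pooled,
    )


def gene_summaries_for_group(
    result: KnownSiteResult,
    group: tuple[str, str],
    catalogue: Sequence[tuple[str, int, str]],
    gene_of_site: Mapping[tuple[str, int], str],
) -> list[GeneEditingSummary]:
    """Gene-level pooling of one strain+stage's catalogued-site counts."""
    counts = result.pooled_counts.get(group, {})
    by_gene: dict[str, list] = {}
    for chrom, pos, ref in catalogue:
        gene = gene_of_site.get((chrom, pos))
        if gene is None or (chrom, pos) in result.blacklisted:
            continue
        nc = counts.get((chrom, pos))
        if nc is not None:
            by_gene.setdefault(gene, []).append((nc, ref))
    return [
        gene_level_editing(gene, sites) for gene, sites in sorted(by_gene.items())
    ]
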