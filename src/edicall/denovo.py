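"""De-novo editing-site discovery from per-sample pileups.

A candidate position must pass, after removal of DNA-derived variants and
of every nucleotide change seen in the ADAR-null strain, all of:

* base calls filtered at Phred >= 25;
* the most abundant remaining mismatch supported by >= 2 reads;
* that mismatch >= 5% of the quality-passing depth;
* every other mismatch <= 1% of the depth;
* the same (position, change) a candidate in >= 2 biological replicas
  of the strain and stage.

Candidates of any substitution class survive to this point; only A>G /
T>C (the A-to-I signature on either strand) enter the editing report,
the rest go to a diagnostics channel.  A site found in the adbp-1 mutant
is *de novo* when it is edited in neither wild-type analysis (known-site
or de-novo) at the same coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .formats import NT_CODE, NUCLEOTIDES, SampleMeta, SiteRecord, read_pileup
from .known_sites import NucCounts, _frac

logger = logging.getLogger(__name__)

A_TO_I_CHANGES = {"A>G", "T>C"}


@dataclass(frozen=True)
class DenovoConfig:
    """De-novo caller thresholds (defaults = printed values)."""

    q_min: int = 25
    k_min: int = 2  # minimum reads supporting the top change
    theta_dn: float = 0.05  # top-change minimum fraction (inclusive)
    theta_other: float = 0.01  # per-other-change maximum fraction (inclusive)
    r_min: int = 2  # minimum supporting replicas
    pool_adar_replicas: bool = True  # pooled ADAR-null subtraction (else union)

    def __post_init__(self):
        if self.k_min < 1:
            raise ValueError("k_min must be >= 1")
        if self.r_min < 1:
            raise ValueError("r_min must be >= 1")
        for name in ("theta_dn", "theta_other"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0,1]")


@dataclass(frozen=True)
class Candidate:
    chrom: str
    pos: int
    ref: str
    change: str  # "X>Y"
    n_target: int
    n_other: int
    n_total: int

    @property
    def level(self) -> float:
        return self.n_target / self.n_total

    @property
    def key(self):
        return (self.chrom, self.pos, self.change)


def subtract_genomic_variants(counts: NucCounts, mask) -> NucCounts:
    """Remove DNA-derived mismatch calls at masked positions.

    A position masked without an alt loses all its mismatches; a masked
    (position, alt) pair loses only that alt.  Reference-matching calls
    are always kept.
    """
    alts = mask.masked_alts(counts.chrom, counts.pos)
    if alts is None:  # whole position masked
        out = counts
        for nt in NUCLEOTIDES:
            if nt != counts.ref:
                out = out.drop_alt(nt)
        return out
    out = counts
    for alt in alts:
        if alt != counts.ref:
            out = out.drop_alt(alt)
    return out


def subtract_mutant_changes(
    counts: NucCounts, adar_counts: NucCounts | None
) -> NucCounts:
    """Remove every mismatch the ADAR-null strain shows at this position.

    One quality-passing ADAR-null read of an alt suffices to erase that
    alt from the test column (the literal reading of the subtraction
    rule).  Idempotent by construction.
    """
    if adar_counts is None or adar_counts.depth == 0:
        return counts
    out = counts
    for nt in NUCLEOTIDES:
        if nt != counts.ref and adar_counts.count(nt) > 0:
            out = out.drop_alt(nt)
    return out


def call_candidate_site(
    counts: NucCounts, config: DenovoConfig = DenovoConfig()
) -> Candidate | None:
    """Apply the per-sample candidate criteria to subtracted, filtered counts.

    The most abundant mismatch is the candidate change (ties broken in
    fixed A<C<G<T order, with a warning); it must reach ``k_min`` reads and
    ``theta_dn`` of the depth while every other mismatch stays at or below
    ``theta_other``.
    """
    depth = counts.depth
    if depth == 0 or counts.ref not in NT_CODE:
        return None
    per_nt = counts.mat.sum(axis=1)
    ref_code = NT_CODE[counts.ref]
    mism = per_nt.copy()
    mism[ref_code] = 0
    top = int(mism.max())
    if top < config.k_min:
        return None
    top_code = int(mism.argmax())  # argmax takes the first max: A<C<G<T order
    if int((mism == top).sum()) > 1:
        logger.warning(
            "tie for most abundant change at %s:%d; fixed A<C<G<T order applied",
            counts.chrom,
            counts.pos,
        )
    if Fraction(top, depth) < _frac(config.theta_dn):
        return None
    n_other = 0
    for code in range(4):
        if code in (ref_code, top_code):
            continue
        c = int(per_nt[code])
        n_other += c
        if c and Fraction(c, depth) > _frac(config.theta_other):
            return None
    return Candidate(
        chrom=counts.chrom,
        pos=counts.pos,
        ref=counts.ref,
        change=f"{counts.ref}>{NUCLEOTIDES[top_code]}",
        n_target=top,
        n_other=n_other,
        n_total=depth,
    )


# ---------------------------------------------------------------------------
# replica consolidation and novelty
# ---------------------------------------------------------------------------


@dataclass
class ConsolidatedSite:
    chrom: str
    pos: int
    ref: str
    change: str
    n_replicas: int
    n_target: int  # pooled over supporting replicas
    n_other: int
    n_total: int

    @property
    def level(self) -> float:
        return self.n_target / self.n_total

    @property
    def key(self):
        return (self.chrom, self.pos, self.change)


def consolidate_replicas(
    candidates_by_sample: Mapping[SampleMeta, Sequence[Candidate]],
    r_min: int = 2,
) -> dict[tuple[str, str], list[ConsolidatedSite]]:
    """Keep (position, change) pairs called in >= r_min replicas per group.

    Output is canonically ordered by (chrom, pos, change) within each
    (strain, stage) group; counts are pooled over supporting replicas.
    """
    grouped: dict[tuple[str, str], dict[tuple, list[Candidate]]] = {}
    for meta, cands in candidates_by_sample.items():
        bucket = grouped.setdefault((meta.strain, meta.stage), {})
        for cand in cands:
            bucket.setdefault(cand.key, []).append(cand)
    out: dict[tuple[str, str], list[ConsolidatedSite]] = {}
    for group, by_key in grouped.items():
        kept = []
        for key in sorted(by_key):
            support = by_key[key]
            if len(support) < r_min:
                continue
            kept.append(
                ConsolidatedSite(
                    chrom=support[0].chrom,
                    pos=support[0].pos,
                    ref=support[0].ref,
                    change=support[0].change,
                    n_replicas=len(support),
                    n_target=sum(c.n_target for c in support),
                    n_other=sum(c.n_other for c in support),
                    n_total=sum(c.n_total for c in support),
                )
            )
        out[group] = kept
    return out


def classify_novelty(
    site: ConsolidatedSite,
    wt_edited_positions: set[tuple[str, int]],
) -> str:
    """'de_novo' when the position is edited in no wild-type analysis."""
    return "known" if (site.chrom, site.pos) in wt_edited_positions else "de_novo"


def to_site_record(site: ConsolidatedSite, status: str) -> SiteRecord:
    from .annotate import infer_editing_strand

    return SiteRecord(
        chrom=site.chrom,
        pos=site.pos,
        strand=infer_editing_strand(site.ref, site.change),
        ref=site.ref,
        change=site.change,
        level=site.level,
        n_target=site.n_target,
        n_other=site.n_other,
        n_total=site.n_total,
        status=status,
    )


# ---------------------------------------------------------------------------
# streaming pipeline
# ---------------------------------------------------------------------------


def _adar_presence(
    adar_paths: Sequence, q_min: int
) -> dict[tuple[str, int], int]:
    """Bitmask of quality-passing nucleotides seen in pooled ADAR-null data."""
    presence: dict[tuple[str, int], int] = {}
    for path in adar_paths:
        for col in read_pileup(path):
            if col.depth == 0:
                continue
            keep = col.quals >= q_min
            codes = col.codes[keep]
            if len(codes) == 0:
                continue
            bits = 0
            for code in np.unique(codes):
                bits |= 1 << int(code)
            key = (col.chrom, col.pos)
            presence[key] = presence.get(key, 0) | bits
    return presence


def scan_sample(
    path,
    sample: SampleMeta,
    dna_mask,
    snp_mask,
    adar_presence: Mapping[tuple[str, int], int],
    config: DenovoConfig = DenovoConfig(),
) -> list[Candidate]:
    """Call per-sample candidates over one pileup file (streaming)."""
    cands: list[Candidate] = []
    kmin = config.k_min
    for col in read_pileup(path, sample):
        if col.ref not in NT_CODE or col.depth == 0:
            continue
        keep = col.quals >= config.q_min
        per_nt = np.bincount(col.codes[keep], minlength=4).astype(np.int64)
        ref_code = NT_CODE[col.ref]
        key = (col.chrom, col.pos)
        # genomic-variant subtraction
        for mask in (dna_mask, snp_mask):
            if mask is None:
                continue
            alts = mask.masked_alts(col.chrom, col.pos)
            if alts is None:
                for code in range(4):
                    if code != ref_code:
                        per_nt[code] = 0
            else:
                for alt in alts:
                    if NT_CODE[alt] != ref_code:
                        per_nt[NT_CODE[alt]] = 0
        # mutant-change subtraction
        bits = adar_presence.get(key, 0)
        if bits:
            for code in range(4):
                if code != ref_code and bits & (1 << code):
                    per_nt[code] = 0
        mism = per_nt.copy()
        mism[ref_code] = 0
        if int(mism.max()) < kmin:
            continue
        mat = np.zeros((4, 2), dtype=np.int64)
        mat[:, 0] = per_nt
        cand = call_candidate_site(
            NucCounts(col.chrom, col.pos, col.ref, mat), config
        )
        if cand is not None:
            cands.append(cand)
    return cands


@dataclass
class DenovoResult:
    records_by_group: dict[tuple[str, str], list[SiteRecord]]
    diagnostics_by_group: dict[tuple[str, str], list[ConsolidatedSite]]
    candidates_by_sample: dict[SampleMeta, list[Candidate]] = field(
        default_factory=dict
    )

    @property
    def records(self) -> list[SiteRecord]:
        return [r for recs in self.records_by_group.values() for r in recs]


def run_denovo_analysis(
    pileups_by_sample: Mapping[SampleMeta, object],
    dna_mask=None,
    snp_mask=None,
    config: DenovoConfig = DenovoConfig(),
    wt_known_positions: set[tuple[str, int]] | None = None,
    stage: str | None = None,
) -> DenovoResult:
    """Full de-novo search over a sample set.

    ADAR-null replicas are pooled per stage for the mutant subtraction;
    wild-type and adbp-1 samples are scanned individually, consolidated at
    >= r_min replicas per strain+stage, and classified against the
    wild-type edited positions (known-site analysis positions passed in
    via ``wt_known_positions`` plus the wild-type de-novo positions found
    here).
    """
    samples = {
        meta: path
        for meta, path in pileups_by_sample.items()
        if stage is None or meta.stage == stage
    }
    stages = sorted({m.stage for m in samples})
    adar_presence_by_stage = {}
    for stg in stages:
        adar_paths = [
            p for m, p in samples.items() if m.strain == "adar_null" and m.stage == stg
        ]
        adar_presence_by_stage[stg] = _adar_presence(adar_paths, config.q_min)

    candidates: dict[SampleMeta, list[Candidate]] = {}
    for meta, path in sorted(samples.items(), key=lambda kv: kv[0].sample_id):
        if meta.strain == "adar_null":
            continue
        candidates[meta] = scan_sample(
            path,
            meta,
            dna_mask,
            snp_mask,
            adar_presence_by_stage[meta.stage],
            config,
        )

    consolidated = consolidate_replicas(candidates, config.r_min)

    wt_positions: set[tuple[str, int]] = set(wt_known_positions or ())
    for (strain, _), sites in consolidated.items():
        if strain == "wild_type":
            wt_positions |= {(s.chrom, s.pos) for s in sites if s.change in A_TO_I_CHANGES}

    records_by_group: dict[tuple[str, str], list[SiteRecord]] = {}
    diagnostics: dict[tuple[str, str], list[ConsolidatedSite]] = {}
    for group, sites in consolidated.items():
        recs, diag = [], []
        for site in sites:
            if site.change not in A_TO_I_CHANGES:
                diag.append(site)
                continue
            if group[0] == "wild_type":
                status = "known"
            else:
                status = classify_novelty(site, wt_positions)
            recs.append(to_site_record(site, status))
        records_by_group[group] = recs
        diagnostics[group] = diag
    return DenovoResult(
        records_by_group=records_by_group,
        diagnostics_by_group=diagnostics,
        candidates_by_sample=candidates,
    )
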