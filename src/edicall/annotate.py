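"""Strand-aware assignment of gene regions to genomic positions.

Each position receives exactly one region label.  When isoforms disagree, a
fixed precedence applies: coding exon > UTR > noncoding exon > intron; a
position outside every gene is intergenic.  When genes on both strands
overlap a position, the gene whose strand matches the inferred editing
strand wins before precedence is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .formats import GeneModel, SiteRecord

REGION_LABELS = ("cds_exon", "utr5", "utr3", "noncoding_exon", "intron", "intergenic")

# lower rank = higher precedence
_RANK = {"cds_exon": 0, "utr5": 1, "utr3": 1, "noncoding_exon": 2, "intron": 3}


@dataclass(frozen=True)
class _Hit:
    region: str
    gene_id: str
    strand: str
    biotype: str

    @property
    def rank(self) -> int:
        return _RANK[self.region]


class PositionIndex:
    """Interval-tree point index over gene-model features."""

    def __init__(self, models: Iterable[GeneModel]):
        self._trees: dict[str, IntervalTree] = {}
        for gm in models:
            gm.validate()
            tree = self._trees.setdefault(gm.chrom, IntervalTree())
            for t in gm.transcripts:
                coding = bool(t.cds)
                for region, ivs in (
                    ("cds_exon", t.cds),
                    ("utr5", t.utr5),
                    ("utr3", t.utr3),
                    ("noncoding_exon", t.noncoding_exons if not coding else []),
                    ("intron", t.introns),
                ):
                    for s, e in ivs:
                        # interval tree is half-open; inputs are 1-based closed
                        tree[s : e + 1] = _Hit(region, gm.gene_id, gm.strand, gm.biotype)

    def query(self, chrom: str, pos: int) -> list[_Hit]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree[pos]]


def build_interval_index(models: Iterable[GeneModel]) -> PositionIndex:
    return PositionIndex(models)


def infer_editing_strand(ref_base: str, change: str) -> str:
    """Editing strand from the observed change: A>G is '+', T>C is '-'.

    Inosine pairs like guanosine, so editing of a minus-strand adenosine
    shows up as a T-to-C change on the plus strand.
    """
    change = change.replace("->", ">").replace("→", ">")
    if change == "A>G" and ref_base.upper() == "A":
        return "+"
    if change == "T>C" and ref_base.upper() == "T":
        return "-"
    raise ValueError(f"not an A-to-I signature: ref={ref_base!r} change={change!r}")


def annotate_position(
    chrom: str,
    pos: int,
    index: PositionIndex,
    strand: str | None = None,
) -> tuple[str, str | None]:
    """Label one position; returns (region, gene_id-or-None).

    ``strand``, when given (the inferred editing strand), restricts hits to
    matching-strand genes first; if no gene matches, all hits compete under
    the precedence rule.
    """
    hits = index.query(chrom, pos)
    if not hits:
        return "intergenic", None
    if strand is not None and strand in "+-":
        matching = [h for h in hits if h.strand == strand]
        if matching:
            hits = matching
    best = min(hits, key=lambda h: (h.rank, h.gene_id))
    return best.region, best.gene_id


def annotate_sites(
    sites: Sequence[SiteRecord], index: PositionIndex
) -> list[SiteRecord]:
    """Return copies of the records with region and gene assigned."""
    from dataclasses import replace

    out = []
    for s in sites:
        region, gene = annotate_position(s.chrom, s.pos, index, strand=s.strand)
        out.append(replace(s, region=region, gene_id=gene))
    return out


def region_fractions(
    sites: Sequence[SiteRecord], merge_utr: bool = True
) -> dict[str, float]:
    """Fraction of sites per region label; UTR5/UTR3 merged by default.

    Fractions sum to 1 over any non-empty site set.
    """
    if not sites:
        return {}
    counts: dict[str, int] = {}
    for s in sites:
        label = s.region
        if merge_utr and label in ("utr5", "utr3"):
            label = "utr"
        counts[label] = counts.get(label, 0) + 1
    n = len(sites)
    return {k: v / n for k, v in sorted(counts.items())}
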