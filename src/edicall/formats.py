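"""Readers and writers for the formats the editing pipeline touches.

Covers the samtools text-pileup dialect (the per-position base/quality
summaries every caller in this package consumes), FASTA genomes, GFF3-like
gene annotation, and the tab-separated site / variant / count tables.

Coordinates are 1-based closed intervals everywhere, matching pileup.
All tables are UTF-8, tab-separated, with a single '#'-prefixed header line.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

NUCLEOTIDES = "ACGT"
NT_CODE = {c: i for i, c in enumerate(NUCLEOTIDES)}

# Phred offset for quality characters; +33 is the modern standard and the
# only offset the pipeline emits.  read_pileup takes an explicit override.
PHRED_OFFSET = 33


class PileupParseError(ValueError):
    """Malformed pileup input; message carries the 1-based line number."""


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one RNA-seq sample: strain, developmental stage, replica."""

    strain: str  # wild_type | adbp1_mutant | adar_null
    stage: str  # embryo | L4
    replica: int
    sample_id: str = ""

    STRAINS = ("wild_type", "adbp1_mutant", "adar_null")
    STAGES = ("embryo", "L4")

    def __post_init__(self):
        if self.strain not in self.STRAINS:
            raise ValueError(f"unknown strain {self.strain!r}")
        if self.stage not in self.STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.replica < 1:
            raise ValueError("replica index must be >= 1")
        if not self.sample_id:
            object.__setattr__(
                self, "sample_id", f"{self.strain}_{self.stage}_rep{self.replica}"
            )


@dataclass(frozen=True)
class BaseCall:
    """A single decoded read base at one reference position."""

    nucleotide: str  # A/C/G/T, reference-match symbols already resolved
    strand: str  # '+' or '-'
    quality: int  # Phred score

    def __post_init__(self):
        if self.nucleotide not in NT_CODE:
            raise ValueError(f"invalid nucleotide {self.nucleotide!r}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if not 0 <= self.quality <= 93:
            raise ValueError(f"Phred quality out of range: {self.quality}")


class PileupColumn:
    """One reference position's decoded base calls for one sample.

    Calls are stored as parallel numpy arrays (nucleotide code, strand,
    quality) so that downstream counting and filtering stay vectorised;
    the ``calls`` property materialises :class:`BaseCall` objects on demand.
    Indel segments, read start/end marks, deletion placeholders and
    reference skips are consumed by the decoder but never become calls.
    """

    __slots__ = ("chrom", "pos", "ref", "sample", "codes", "fwd", "quals")

    def __init__(self, chrom, pos, ref, codes, fwd, quals, sample=None):
        self.chrom = chrom
        self.pos = int(pos)
        self.ref = ref
        self.sample = sample
        self.codes = np.asarray(codes, dtype=np.uint8)
        self.fwd = np.asarray(fwd, dtype=bool)
        self.quals = np.asarray(quals, dtype=np.uint8)
        if not (len(self.codes) == len(self.fwd) == len(self.quals)):
            raise ValueError("codes/strands/qualities must be parallel")

    @classmethod
    def from_calls(cls, chrom, pos, ref, calls: Sequence[BaseCall], sample=None):
        codes = [NT_CODE[c.nucleotide] for c in calls]
        fwd = [c.strand == "+" for c in calls]
        quals = [c.quality for c in calls]
        return cls(chrom, pos, ref, codes, fwd, quals, sample)

    @property
    def depth(self) -> int:
        return len(self.codes)

    @property
    def calls(self) -> tuple[BaseCall, ...]:
        return tuple(
            BaseCall(NUCLEOTIDES[c], "+" if f else "-", int(q))
            for c, f, q in zip(self.codes, self.fwd, self.quals)
        )

    def __len__(self):
        return len(self.codes)

    def __eq__(self, other):
        if not isinstance(other, PileupColumn):
            return NotImplemented
        return (
            (self.chrom, self.pos, self.ref) == (other.chrom, other.pos, other.ref)
            and np.array_equal(self.codes, other.codes)
            and np.array_equal(self.fwd, other.fwd)
            and np.array_equal(self.quals, other.quals)
        )

    def __repr__(self):
        return f"PileupColumn({self.chrom}:{self.pos} {self.ref} depth={self.depth})"


@dataclass(frozen=True)
class SiteRecord:
    """A called editing site."""

    chrom: str
    pos: int  # 1-based
    strand: str  # '+' or '-' (strand carrying the edited adenosine)
    ref: str
    change: str  # "A>G" or "T>C" for A-to-I; others appear in diagnostics
    level: float
    n_target: int
    n_other: int
    n_total: int
    region: str = "unknown"
    gene_id: str | None = None
    status: str = "known"  # known | de_novo

    def __post_init__(self):
        if self.n_total > 0 and not (0 <= self.n_target + self.n_other <= self.n_total):
            raise ValueError("count fields inconsistent")

    @property
    def key(self):
        return (self.chrom, self.pos, self.strand, self.change)


# ---------------------------------------------------------------------------
# pileup decoding
# ---------------------------------------------------------------------------

# Fast path lookup tables: map a base-string byte to a nucleotide code
# (255 = consumes a quality slot but emits no call, e.g. N/*/</>) and to a
# strand.  46='.', 44=','.
_SIMPLE = np.full(256, 254, dtype=np.uint8)  # 254 = not a simple symbol
_FWD = np.zeros(256, dtype=bool)
for _c in "ACGT":
    _SIMPLE[ord(_c)] = NT_CODE[_c]
    _SIMPLE[ord(_c.lower())] = NT_CODE[_c]
    _FWD[ord(_c)] = True
_SIMPLE[ord(".")] = 100  # resolve to ref, forward
_SIMPLE[ord(",")] = 101  # resolve to ref, reverse
_FWD[ord(".")] = True
for _c in "Nn*<>":
    _SIMPLE[ord(_c)] = 255
_FWD[ord("N")] = _FWD[ord("*")] = True
_SIMPLE_OK = frozenset(b".,ACGTacgtNn*<>")


def _decode_bases(bases: str, quals: str, ref: str, offset: int, lineno: int):
    """Decode a pileup base string into (codes, fwd, quals) arrays.

    Every read symbol ('.', ',', letters, '*', '<', '>') consumes exactly one
    quality character; '^X' (X = mapping quality, never a base), '$' and
    '+n.../-n...' indel segments consume base-string characters only.
    """
    raw = bases.encode("ascii")
    if all(b in _SIMPLE_OK for b in raw):
        codes = _SIMPLE[np.frombuffer(raw, dtype=np.uint8)]
        fwd = _FWD[np.frombuffer(raw, dtype=np.uint8)]
        q = np.frombuffer(quals.encode("ascii"), dtype=np.uint8)
        if len(codes) != len(q):
            raise PileupParseError(
                f"line {lineno}: {len(codes)} read symbols but {len(q)} qualities"
            )
        ref_code = NT_CODE.get(ref, 255)
        codes = codes.copy()
        codes[codes == 100] = ref_code
        codes[codes == 101] = ref_code
        keep = codes < 4
        return codes[keep], fwd[keep], (q - offset)[keep], len(raw)

    # slow path: full dialect
    codes, fwd, out_q = [], [], []
    i = 0  # index into base string
    j = 0  # index into quality string
    n_reads = 0
    ref_code = NT_CODE.get(ref, None)
    while i < len(bases):
        ch = bases[i]
        if ch == "^":
            if i + 1 >= len(bases):
                raise PileupParseError(f"line {lineno}: dangling '^'")
            i += 2  # mapping-quality char is always discarded
            continue
        if ch == "$":
            i += 1
            continue
        if ch in "+-":
            i += 1
            num = ""
            while i < len(bases) and bases[i].isdigit():
                num += bases[i]
                i += 1
            if not num:
                raise PileupParseError(f"line {lineno}: indel without length")
            i += int(num)  # inserted/deleted sequence, not a column call
            continue
        if j >= len(quals):
            raise PileupParseError(f"line {lineno}: quality string exhausted")
        qv = ord(quals[j]) - offset
        j += 1
        n_reads += 1
        if ch in ".,":
            if ref_code is None:
                i += 1
                continue  # ref N: match symbol carries no base identity
            codes.append(ref_code)
            fwd.append(ch == ".")
        elif ch in "ACGTacgt":
            codes.append(NT_CODE[ch.upper()])
            fwd.append(ch.isupper())
        elif ch in "Nn*<>":
            pass  # consumes depth/quality but emits no base call
        else:
            raise PileupParseError(f"line {lineno}: unknown base symbol {ch!r}")
        i += 1
        if ch in "Nn*<>":
            continue
        out_q.append(qv)
    if j != len(quals):
        raise PileupParseError(
            f"line {lineno}: {len(quals) - j} unconsumed quality characters"
        )
    return (
        np.array(codes, dtype=np.uint8),
        np.array(fwd, dtype=bool),
        np.array(out_q, dtype=np.uint8),
        n_reads,
    )


def read_pileup(
    path, sample: SampleMeta | None = None, phred_offset: int = PHRED_OFFSET
) -> Iterator[PileupColumn]:
    """Stream a samtools-dialect text pileup as decoded columns.

    Each line is ``chrom pos ref depth bases qualities`` (tab-separated).
    '.'/',' resolve to the reference base on the forward/reverse strand;
    upper/lower-case letters are forward/reverse mismatches; ``^X``, ``$``,
    indel segments, ``*``, ``<`` and ``>`` are consumed without emitting
    calls.  Qualities pair positionally with read symbols only.
    """
    handle = open(path) if not isinstance(path, io.TextIOBase) else path
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise PileupParseError(
                    f"line {lineno}: expected 6 tab-separated fields, got {len(fields)}"
                )
            chrom, pos, ref, depth, bases, quals = fields
            ref = ref.upper()
            depth = int(depth)
            if depth == 0:
                # samtools writes placeholder '* *' at zero depth
                yield PileupColumn(chrom, int(pos), ref, [], [], [], sample)
                continue
            codes, fwd, q, n_reads = _decode_bases(
                bases, quals, ref, phred_offset, lineno
            )
            if n_reads != depth:
                raise PileupParseError(
                    f"line {lineno}: depth field {depth} but decoded {n_reads} reads"
                )
            yield PileupColumn(chrom, int(pos), ref, codes, fwd, q, sample)
    finally:
        if handle is not path:
            handle.close()


_QUAL_CHARS = np.array([chr(q + PHRED_OFFSET) for q in range(94)])


def write_pileup(columns: Iterable[PileupColumn], path) -> None:
    """Write columns in the samtools 6-column text dialect (Phred+33)."""
    with open(path, "w") as fh:
        for col in columns:
            if col.depth == 0:
                fh.write(f"{col.chrom}\t{col.pos}\t{col.ref}\t0\t*\t*\n")
                continue
            bases = []
            for code, f in zip(col.codes, col.fwd):
                nt = NUCLEOTIDES[code]
                if nt == col.ref:
                    bases.append("." if f else ",")
                else:
                    bases.append(nt if f else nt.lower())
            quals = "".join(chr(int(q) + PHRED_OFFSET) for q in col.quals)
            fh.write(
                f"{col.chrom}\t{col.pos}\t{col.ref}\t{col.depth}\t"
                f"{''.join(bases)}\t{quals}\n"
            )


# ---------------------------------------------------------------------------
# site tables
# ---------------------------------------------------------------------------

_SITE_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "ref",
    "change",
    "level",
    "n_target",
    "n_other",
    "n_total",
    "region",
    "gene_id",
    "status",
]


def write_site_table(records: Iterable[SiteRecord], path) -> None:
    """Serialise site records as a '#'-headed TSV (levels to 6 sig. digits)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_SITE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(r.pos),
                        r.strand,
                        r.ref,
                        r.change,
                        repr(float(r.level)),
                        str(r.n_target),
                        str(r.n_other),
                        str(r.n_total),
                        r.region,
                        r.gene_id if r.gene_id is not None else ".",
                        r.status,
                    ]
                )
                + "\n"
            )


def read_site_table(path, allow_duplicates: bool = False) -> list[SiteRecord]:
    records: list[SiteRecord] = []
    seen: set = set()
    with open(path) as fh:
        header = fh.readline().lstrip("#").split()
        if header != _SITE_COLUMNS:
            raise ValueError(f"{path}: unexpected site-table header {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rec = SiteRecord(
                chrom=f[0],
                pos=int(f[1]),
                strand=f[2],
                ref=f[3],
                change=f[4],
                level=float(f[5]),
                n_target=int(f[6]),
                n_other=int(f[7]),
                n_total=int(f[8]),
                region=f[9],
                gene_id=None if f[10] == "." else f[10],
                status=f[11],
            )
            if rec.key in seen and not allow_duplicates:
                raise ValueError(f"{path}: duplicate site row {rec.key}")
            seen.add(rec.key)
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# gene models (GFF3-like)
# ---------------------------------------------------------------------------


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, 1-based closed."""
        ex = sorted(self.exons)
        return [
            (ex[i][1] + 1, ex[i + 1][0] - 1)
            for i in range(len(ex) - 1)
            if ex[i + 1][0] > ex[i][1] + 1
        ]

    @property
    def noncoding_exons(self) -> list[tuple[int, int]]:
        """Exon stretches not covered by CDS or UTR features."""
        covered = sorted(self.cds + self.utr5 + self.utr3)
        if not covered:
            return list(self.exons)
        out = []
        for s, e in sorted(self.exons):
            cursor = s
            for cs, ce in covered:
                if ce < cursor or cs > e:
                    continue
                if cs > cursor:
                    out.append((cursor, cs - 1))
                cursor = max(cursor, ce + 1)
            if cursor <= e:
                out.append((cursor, e))
        return out


@dataclass
class GeneModel:
    """Strand-aware exon/intron/UTR structure of one gene."""

    gene_id: str
    chrom: str
    strand: str
    biotype: str = "coding"  # coding | lncRNA | other
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        starts, ends = zip(*(t.span for t in self.transcripts))
        return min(starts), max(ends)

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: unknown strand {self.strand!r}")
        for t in self.transcripts:
            span = t.span
            for kind in ("cds", "utr5", "utr3"):
                for s, e in getattr(t, kind):
                    if s < span[0] or e > span[1]:
                        raise ValueError(
                            f"{self.gene_id}/{t.transcript_id}: {kind} feature "
                            f"({s},{e}) outside transcript span {span}"
                        )
            ivs = sorted(t.cds + t.utr5 + t.utr3)
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"{self.gene_id}/{t.transcript_id}: overlapping features"
                    )


_UTR5_TYPES = {"five_prime_UTR", "five_prime_utr", "5UTR"}
_UTR3_TYPES = {"three_prime_UTR", "three_prime_utr", "3UTR"}
_TRANSCRIPT_TYPES = {"mRNA", "transcript", "lnc_RNA", "ncRNA"}


def read_gene_models(path) -> list[GeneModel]:
    """Parse a GFF3-like annotation into validated gene models.

    Introns are derived as gaps between consecutive exons of a transcript;
    coordinates are 1-based closed throughout.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for gene in db.features_of_type("gene"):
        biotype = gene.attributes.get("biotype", ["coding"])[0]
        gm = GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=gene.strand, biotype=biotype
        )
        for tr in db.children(gene, level=1):
            if tr.featuretype not in _TRANSCRIPT_TYPES:
                continue
            t = Transcript(transcript_id=tr.id)
            for feat in db.children(tr, level=1):
                iv = (feat.start, feat.end)
                if feat.featuretype == "exon":
                    t.exons.append(iv)
                elif feat.featuretype == "CDS":
                    t.cds.append(iv)
                elif feat.featuretype in _UTR5_TYPES:
                    t.utr5.append(iv)
                elif feat.featuretype in _UTR3_TYPES:
                    t.utr3.append(iv)
            if not t.exons:
                continue
            for s, e in t.exons:
                if s < tr.start or e > tr.end:
                    raise ValueError(
                        f"{gene.id}/{tr.id}: exon ({s},{e}) outside transcript "
                        f"span ({tr.start},{tr.end})"
                    )
            t.exons.sort()
            gm.transcripts.append(t)
        if gm.transcripts:
            gm.validate()
            models.append(gm)
    return models


# ---------------------------------------------------------------------------
# masks, FASTA, counts
# ---------------------------------------------------------------------------


class VariantMask:
    """Genomic positions (optionally alt-specific) to exclude as DNA-derived.

    Built from DNA-seq variant calls and SNP catalogues; lookup is O(1) by
    (chrom, pos) and by (chrom, pos, alt).
    """

    def __init__(self, entries: Iterable[tuple] = ()):
        self._any: set[tuple[str, int]] = set()
        self._alt: dict[tuple[str, int], set[str]] = {}
        for entry in entries:
            self.add(*entry)

    def add(self, chrom: str, pos: int, alt: str | None = None):
        if alt is None or alt == ".":
            self._any.add((chrom, int(pos)))
        else:
            self._alt.setdefault((chrom, int(pos)), set()).add(alt.upper())

    def contains(self, chrom: str, pos: int, alt: str | None = None) -> bool:
        key = (chrom, int(pos))
        if key in self._any:
            return True
        if alt is not None:
            return alt.upper() in self._alt.get(key, ())
        return key in self._alt

    def masked_alts(self, chrom: str, pos: int) -> set[str] | None:
        """None when all alts are masked at the position; else the alt set."""
        key = (chrom, int(pos))
        if key in self._any:
            return None
        return self._alt.get(key, set())

    def __len__(self):
        return len(self._any) + sum(len(v) for v in self._alt.values())


def read_variant_mask(path) -> VariantMask:
    """Read a (chrom, pos[, alt]) TSV into a VariantMask."""
    mask = VariantMask()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.split()
            mask.add(f[0], int(f[1]), f[2] if len(f) > 2 else None)
    return mask


def write_variant_mask(entries: Iterable[tuple], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\talt\n")
        for entry in entries:
            chrom, pos = entry[0], entry[1]
            alt = entry[2] if len(entry) > 2 and entry[2] else "."
            fh.write(f"{chrom}\t{pos}\t{alt}\n")


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file as {name: uppercase sequence}; names must be unique."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate FASTA record {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_counts(path) -> pd.DataFrame:
    """Gene x sample integer count table (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", comment=None)
    df.columns = [df.columns[0].lstrip("#")] + list(df.columns[1:])
    df = df.set_index(df.columns[0])
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene row {dup!r}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        try:
            as_float = arr.astype(float)
        except ValueError as exc:
            raise ValueError(f"{path}: non-integer count ({exc})") from exc
        if np.isnan(as_float).any() or not (as_float == np.floor(as_float)).all():
            raise ValueError(f"{path}: non-integer count")
        df = df.astype(np.int64)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative count")
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\t" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False)
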