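"""Secondary-structure stability of the sequence surrounding editing sites.

For each site the 50 nucleotides on either side are extracted (window of
101 nt), from the genome for the unspliced form and from the spliced
transcript for the spliced form; minus-strand (T-to-C) sites use the
reverse complement so the window's center is always the edited adenosine.
The minimum free energy (MFE, kcal/mol) of each window is predicted with a
nearest-neighbor thermodynamics backend (ViennaRNA), outliers with
|dG| > 100 are removed, and group means are compared with the Welch
two-sample t-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .context import reverse_complement
from .formats import GeneModel, SiteRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StructureConfig:
    flank: int = 50  # window length = 2*flank + 1 = 101
    outlier_bound: float = 100.0  # kcal/mol, |dG| above this removed
    temperature: float = 37.0  # folding temperature, Celsius
    literal_outlier_rule: bool = False  # remove only dG > bound, as printed

    def __post_init__(self):
        if self.flank < 1:
            raise ValueError("flank must be >= 1")


@dataclass(frozen=True)
class WindowFold:
    site: SiteRecord
    form: str  # spliced | unspliced
    sequence: str
    dG: float | None = None


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------


def extract_window(
    site: SiteRecord, source: Mapping[str, str], flank: int = 50
) -> str | None:
    """Genomic (unspliced) window around a site, on the edited strand.

    Returns None (logged) when the site sits within ``flank`` of either
    sequence end.  The returned window has length 2*flank+1 and its center
    is A for a valid A-to-I site.
    """
    seq = source.get(site.chrom)
    if seq is None:
        raise KeyError(f"unknown sequence {site.chrom!r}")
    i = site.pos - 1
    if i - flank < 0 or i + flank >= len(seq):
        logger.info("site %s:%d too close to a sequence end; excluded", site.chrom, site.pos)
        return None
    window = seq[i - flank : i + flank + 1]
    if site.strand == "-":
        window = reverse_complement(window)
    return window


class Transcriptome:
    """Spliced transcript sequences with a genome -> transcript coordinate map.

    One transcript per gene (the longest spliced form) supplies the
    spliced sequence, oriented 5'->3' on the gene strand.
    """

    def __init__(self, genome: Mapping[str, str], models: Sequence[GeneModel]):
        self._seqs: dict[str, str] = {}
        # (chrom, genomic pos) -> (transcript_id, 0-based spliced index)
        self._map: dict[tuple[str, int], tuple[str, int]] = {}
        for gm in models:
            tr = max(
                gm.transcripts,
                key=lambda t: sum(e - s + 1 for s, e in t.exons),
            )
            chrom_seq = genome[gm.chrom]
            pieces = []
            offsets = []  # (start, end, offset of start within spliced seq)
            total = 0
            for s, e in sorted(tr.exons):
                pieces.append(chrom_seq[s - 1 : e])
                offsets.append((s, e, total))
                total += e - s + 1
            spliced = "".join(pieces)
            if gm.strand == "-":
                spliced = reverse_complement(spliced)
            self._seqs[tr.transcript_id] = spliced
            for s, e, off in offsets:
                for pos in range(s, e + 1):
                    idx = off + (pos - s)
                    if gm.strand == "-":
                        idx = total - 1 - idx
                    self._map[(gm.chrom, pos)] = (tr.transcript_id, idx)

    @property
    def sequences(self) -> dict[str, str]:
        return dict(self._seqs)

    def locate(self, chrom: str, pos: int) -> tuple[str, int] | None:
        return self._map.get((chrom, pos))

    def window(self, chrom: str, pos: int, flank: int) -> str | None:
        """Spliced window centered on a genomic position; None if absent
        from the transcriptome (e.g. intronic site) or end-proximal."""
        loc = self.locate(chrom, pos)
        if loc is None:
            return None
        tid, idx = loc
        seq = self._seqs[tid]
        if idx - flank < 0 or idx + flank >= len(seq):
            return None
        return seq[idx - flank : idx + flank + 1]


def extract_windows(
    sites: Sequence[SiteRecord],
    genome: Mapping[str, str],
    transcriptome: Transcriptome | None = None,
    flank: int = 50,
) -> list[WindowFold]:
    """Unspliced (and, when a transcriptome is given, spliced) windows."""
    out = []
    for site in sites:
        w = extract_window(site, genome, flank)
        if w is not None:
            out.append(WindowFold(site, "unspliced", w))
        if transcriptome is not None:
            ws = transcriptome.window(site.chrom, site.pos, flank)
            if ws is None:
                logger.info(
                    "site %s:%d absent from spliced transcriptome; excluded",
                    site.chrom,
                    site.pos,
                )
                continue
            # spliced sequences are stored on the gene strand already; a
            # minus-strand site is therefore centered without further RC
            out.append(WindowFold(site, "spliced", ws))
    return out


# ---------------------------------------------------------------------------
# folding
# ---------------------------------------------------------------------------


def fold_mfe(sequence: str, config: StructureConfig = StructureConfig()) -> float:
    """Minimum free energy (kcal/mol) of one RNA sequence.

    T is transcribed to U before folding; ambiguous bases raise.  The
    backend is nearest-neighbor thermodynamics (ViennaRNA); results are
    deterministic for a given sequence and backend version.
    """
    rna = sequence.upper().replace("T", "U")
    if any(ch not in "ACGU" for ch in rna):
        bad = sorted({ch for ch in rna if ch not in "ACGU"})
        raise ValueError(f"ambiguous bases in sequence: {bad}")
    import RNA

    if config.temperature != 37.0:
        md = RNA.md()
        md.temperature = config.temperature
        fc = RNA.fold_compound(rna, md)
    else:
        fc = RNA.fold_compound(rna)
    _, dg = fc.mfe()
    return float(dg)


def fold_windows(
    windows: Sequence[WindowFold], config: StructureConfig = StructureConfig()
) -> list[WindowFold]:
    from dataclasses import replace

    return [replace(w, dG=fold_mfe(w.sequence, config)) for w in windows]


# ---------------------------------------------------------------------------
# Welch comparison
# ---------------------------------------------------------------------------


def welch_test(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Welch two-sample t-test (two-sided), Welch-Satterthwaite df.

    Degenerate variance: both groups constant and equal in mean gives
    t=0, p=1 by convention; constant but unequal raises.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if ma == mb:
            return WelchResult(0.0, float(len(a) + len(b) - 2), 1.0, ma, mb, len(a), len(b))
        raise ValueError("degenerate variance: both groups constant, means differ")
    sa, sb = va / len(a), vb / len(b)
    t = (ma - mb) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (
        sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p), float(ma), float(mb), len(a), len(b))


def remove_outliers(
    values: Sequence[float], config: StructureConfig = StructureConfig()
) -> list[float]:
    """Drop MFE outliers: |dG| > bound (or literally dG > bound by flag)."""
    if config.literal_outlier_rule:
        return [v for v in values if not v > config.outlier_bound]
    return [v for v in values if not abs(v) > config.outlier_bound]


def compare_mfe_groups(
    group_a: Sequence[float],
    group_b: Sequence[float],
    config: StructureConfig = StructureConfig(),
) -> WelchResult:
    """Outlier-filter both groups, then Welch-compare their mean MFE."""
    a = remove_outliers(group_a, config)
    b = remove_outliers(group_b, config)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("a group has fewer than 2 values after outlier removal")
    return welch_test(a, b)
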