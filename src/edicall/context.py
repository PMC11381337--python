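"""Nucleotide context around edited adenosines.

Counts the nucleotides at positions -w..+w relative to each edited
adenosine on its own strand (minus-strand sites contribute the reverse
complement of their plus-strand window, so position -1 is always the 5'
neighbor) and converts counts to a probability matrix with a Laplace-style
pseudocount:

    P_ic = (n_ic + lambda) / (sum_c' n_ic' + C * lambda)

with C = 4 characters.  Profiles are stratified by gene region (exon /
intron / UTR) and paired with random-adenosine controls drawn from the
same regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import NT_CODE, NUCLEOTIDES, GeneModel, SiteRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifConfig:
    half_width: int = 3  # positions each side of the edited base
    pseudocount: float = 1.0  # lambda
    n_characters: int = 4  # C

    def __post_init__(self):
        if self.half_width < 1:
            raise ValueError("half_width must be >= 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


@dataclass
class ContextProfile:
    """Position x nucleotide counts and probabilities around edited bases."""

    counts: pd.DataFrame  # index -w..w, columns A C G T, integers
    probabilities: pd.DataFrame
    n_sites: int
    stratum: str = "all"


def context_counts(
    sites: Sequence[SiteRecord], genome: Mapping[str, str], w: int = 3
) -> tuple[pd.DataFrame, int]:
    """Count nucleotides at offsets -w..w on each site's edited strand.

    Sites within w of a sequence end, or with an ambiguous base in the
    window, are excluded (logged).  Returns (counts, n_sites_used).
    """
    mat = np.zeros((2 * w + 1, 4), dtype=np.int64)
    used = 0
    for s in sites:
        seq = genome.get(s.chrom)
        if seq is None:
            raise KeyError(f"unknown sequence {s.chrom!r}")
        i = s.pos - 1
        if i - w < 0 or i + w >= len(seq):
            logger.info("site %s:%d within %d of sequence end; excluded", s.chrom, s.pos, w)
            continue
        window = seq[i - w : i + w + 1]
        if s.strand == "-":
            window = reverse_complement(window)
        if any(ch not in NT_CODE for ch in window):
            logger.info("site %s:%d has ambiguous base in window; excluded", s.chrom, s.pos)
            continue
        for j, ch in enumerate(window):
            mat[j, NT_CODE[ch]] += 1
        used += 1
    counts = pd.DataFrame(
        mat, index=range(-w, w + 1), columns=list(NUCLEOTIDES)
    )
    return counts, used


def probability_matrix(
    counts: pd.DataFrame, pseudocount: float = 1.0, n_characters: int = 4
) -> pd.DataFrame:
    """P_ic = (n_ic + lambda) / (sum_c' n_ic' + C*lambda); rows sum to 1."""
    n = counts.to_numpy(dtype=float)
    lam = float(pseudocount)
    denom = n.sum(axis=1, keepdims=True) + n_characters * lam
    if lam == 0 and (denom == 0).any():
        raise ValueError("all-zero counts with lambda=0: probabilities undefined")
    return pd.DataFrame(
        (n + lam) / denom, index=counts.index, columns=counts.columns
    )


def build_profile(
    sites: Sequence[SiteRecord],
    genome: Mapping[str, str],
    config: MotifConfig = MotifConfig(),
    stratum: str = "all",
) -> ContextProfile:
    counts, used = context_counts(sites, genome, config.half_width)
    probs = probability_matrix(counts, config.pseudocount, config.n_characters)
    return ContextProfile(counts=counts, probabilities=probs, n_sites=used, stratum=stratum)


# ---------------------------------------------------------------------------
# random-adenosine controls
# ---------------------------------------------------------------------------

_STRATUM_REGIONS = {
    "cds_exon": ("cds_exon",),
    "intron": ("intron",),
    "utr": ("utr5", "utr3"),
    "noncoding_exon": ("noncoding_exon",),
}


def _adenosine_positions_by_region(
    genome: Mapping[str, str], models: Sequence[GeneModel]
) -> dict[str, list[tuple[str, int, str]]]:
    """All (chrom, pos, strand) with an A on the gene strand, per region."""
    out: dict[str, list[tuple[str, int, str]]] = {}
    want = "A"
    for gm in models:
        seq = genome[gm.chrom]
        target = want if gm.strand == "+" else "T"
        for t in gm.transcripts:
            coding = bool(t.cds)
            for region, ivs in (
                ("cds_exon", t.cds),
                ("utr5", t.utr5),
                ("utr3", t.utr3),
                ("noncoding_exon", t.noncoding_exons if not coding else []),
                ("intron", t.introns),
            ):
                bucket = out.setdefault(region, [])
                for s, e in ivs:
                    for pos in range(s, e + 1):
                        if seq[pos - 1] == target:
                            bucket.append((gm.chrom, pos, gm.strand))
    for region in out:
        out[region] = sorted(set(out[region]))
    return out


def sample_random_adenosines(
    genome: Mapping[str, str],
    models: Sequence[GeneModel],
    strata: Mapping[str, int],
    seed: int,
) -> list[SiteRecord]:
    """Draw random gene-strand adenosines, stratified by region.

    Returns synthetic control records (level 0) with the requested count
    per stratum; deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    pool = _adenosine_positions_by_region(genome, models)
    out: list[SiteRecord] = []
    for stratum, n in sorted(strata.items()):
        regions = _STRATUM_REGIONS.get(stratum, (stratum,))
        candidates = sorted(
            {c for r in regions for c in pool.get(r, [])}
        )
        if len(candidates) < n:
            raise ValueError(
                f"stratum {stratum!r}: requested {n} adenosines, "
                f"only {len(candidates)} available"
            )
        idx = rng.choice(len(candidates), size=n, replace=False)
        for i in sorted(idx):
            chrom, pos, strand = candidates[i]
            out.append(
                SiteRecord(
                    chrom=chrom,
                    pos=pos,
                    strand=strand,
                    ref="A" if strand == "+" else "T",
                    change="A>G" if strand == "+" else "T>C",
                    level=0.0,
                    n_target=0,
                    n_other=0,
                    n_total=0,
                    region=stratum,
                    status="known",
                )
            )
    return out


def stratified_profiles(
    sites: Sequence[SiteRecord],
    genome: Mapping[str, str],
    models: Sequence[GeneModel],
    config: MotifConfig = MotifConfig(),
    seed: int = 0,
) -> dict[str, dict[str, ContextProfile]]:
    """Observed and random-control profiles for all / exon / intron / UTR.

    UTR5 and UTR3 are merged into one stratum; empty strata are omitted
    with a warning.  Controls are drawn with region-matched counts.
    """
    strata: dict[str, list[SiteRecord]] = {"all": list(sites)}
    for s in sites:
        label = "utr" if s.region in ("utr5", "utr3") else s.region
        if label in _STRATUM_REGIONS:
            strata.setdefault(label, []).append(s)
    out: dict[str, dict[str, ContextProfile]] = {}
    control_request = {
        k: len(v) for k, v in strata.items() if k != "all" and v
    }
    controls = sample_random_adenosines(genome, models, control_request, seed)
    controls_by_stratum: dict[str, list[SiteRecord]] = {}
    for c in controls:
        controls_by_stratum.setdefault(c.region, []).append(c)
    all_controls = [c for v in controls_by_stratum.values() for c in v]
    for name, members in strata.items():
        if not members:
            logger.warning("stratum %r has no sites; profile omitted", name)
            continue
        ctrl = all_controls if name == "all" else controls_by_stratum.get(name, [])
        out[name] = {
            "observed": build_profile(members, genome, config, stratum=name),
            "control": build_profile(ctrl, genome, config, stratum=f"{name}_control"),
        }
    return out


def write_profile(profile: ContextProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#stratum={profile.stratum}\tn_sites={profile.n_sites}\n")
        fh.write("#position\t" + "\t".join(NUCLEOTIDES) + "\n")
        for i, row in profile.probabilities.iterrows():
            fh.write(f"{i}\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def plot_profile(profile: ContextProfile, path) -> None:
    """Stacked-bar probability logo (optional; requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    fig, ax = plt.subplots(figsize=(1 + len(profile.probabilities) * 0.6, 3))
    bottom = np.zeros(len(profile.probabilities))
    x = profile.probabilities.index.to_numpy()
    for nt in NUCLEOTIDES:
        vals = profile.probabilities[nt].to_numpy()
        ax.bar(x, vals, bottom=bottom, label=nt, color=colors[nt])
        bottom += vals
    ax.set_xlabel("position relative to edited adenosine")
    ax.set_ylabel("probability")
    ax.set_title(f"{profile.stratum} (n={profile.n_sites})")
    ax.legend(ncol=4, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
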