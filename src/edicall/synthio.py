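"""Synthetic data emulating the three-strain, two-stage, three-replica design.

The generator produces a random genome with multi-exon gene models, plants
strain-specific editing truth with the study's region biases (wild-type
editing mostly intronic, adbp-1-mutant editing mostly exonic, none in the
ADAR-null strain), and emits per-sample text pileups with
coverage-dependent binomial edited-read counts, sequencing errors, a
two-point Phred quality model, homozygous SNPs, and ADAR-null artifact
changes — everything the callers downstream consume, plus the ground
truth needed for recovery testing.

Pileups are emitted directly (the analysis pipeline starts at pileup
level); read-level simulation is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import (
    NUCLEOTIDES,
    GeneModel,
    SampleMeta,
    Transcript,
    write_counts,
    write_fasta,
    write_variant_mask,
)
from .known_sites import write_catalogue

STRAINS = ("wild_type", "adbp1_mutant", "adar_null")


@dataclass(frozen=True)
class SimProfile:
    """Study-design parameters of the synthetic fixture.

    Defaults encode the emulated design: three strains at two stages with
    three biological replicas, ~60x coverage, 0.1% sequencing error,
    wild-type sites 80% intronic, adbp-1 sites 65.5% exonic, and an
    ADAR-null strain carrying artifact changes but no true editing.
    """

    n_genes: int = 180
    n_sites: Mapping[str, int] = field(
        default_factory=lambda: {"wild_type": 200, "adbp1_mutant": 200, "adar_null": 0}
    )
    region_mix: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "wild_type": {"intron": 0.80, "cds_exon": 0.13, "utr": 0.07},
            "adbp1_mutant": {"cds_exon": 0.655, "intron": 0.20, "utr": 0.145},
        }
    )
    level_range: tuple[float, float] = (0.05, 0.5)
    coverage_mean: float = 60.0
    coverage_dispersion: float = 10.0  # negative-binomial size parameter
    error_rate: float = 0.001
    q_high: int = 37
    q_low: int = 15
    p_low_quality: float = 0.05
    n_replicas: int = 3
    stages: tuple[str, ...] = ("embryo", "L4")
    stage_level_multiplier: Mapping[str, float] = field(
        default_factory=lambda: {"embryo": 1.0, "L4": 1.0}
    )
    n_snps: int = 100
    n_artifacts: int = 20  # ADAR-null artifact-change sites
    artifact_shared_fraction: float = 0.5  # also present in the other strains
    artifact_level_range: tuple[float, float] = (0.05, 0.10)
    lnc_fraction: float = 0.15
    gc_content: float = 0.36

    def __post_init__(self):
        for strain, mix in self.region_mix.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"region mix for {strain} must sum to 1")
        for r in (self.error_rate, self.p_low_quality, self.artifact_shared_fraction):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0,1]")

    def samples(self) -> list[SampleMeta]:
        return [
            SampleMeta(strain, stage, rep)
            for strain in STRAINS
            for stage in self.stages
            for rep in range(1, self.n_replicas + 1)
        ]


# ---------------------------------------------------------------------------
# genome and gene models
# ---------------------------------------------------------------------------


def _random_seq(rng, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(NUCLEOTIDES))[rng.choice(4, size=n, p=p)])


def make_genome_and_models(
    n_genes: int = 180, seed: int = 0, lnc_fraction: float = 0.15, gc: float = 0.36
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random two-chromosome genome with multi-exon genes on both strands.

    Coding genes get UTRs at their transcriptional ends; a fraction are
    single- or multi-exon lncRNAs.  Deterministic per seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA17]))
    chrom_names = ["chrI", "chrII"]
    cursors = {c: 0 for c in chrom_names}
    pieces: dict[str, list[str]] = {c: [] for c in chrom_names}
    models: list[GeneModel] = []
    for g in range(n_genes):
        chrom = chrom_names[g % len(chrom_names)]
        gap = int(rng.integers(150, 400))
        pieces[chrom].append(_random_seq(rng, gap, gc))
        cursors[chrom] += gap
        start = cursors[chrom] + 1
        strand = "+" if rng.random() < 0.5 else "-"
        is_lnc = rng.random() < lnc_fraction
        n_exons = int(rng.integers(1, 5))
        u5 = int(rng.integers(30, 90))
        u3 = int(rng.integers(50, 140))
        exons = []
        pos = start
        for e in range(n_exons):
            elen = int(rng.integers(150, 400))
            if not is_lnc:
                # terminal exons must fit their UTR plus >=30 nt of CDS
                need = 30 + (u5 if e == 0 else 0) + (u3 if e == n_exons - 1 else 0)
                elen = max(elen, need)
            exons.append((pos, pos + elen - 1))
            pos += elen
            if e < n_exons - 1:
                pos += int(rng.integers(60, 300))
        span_len = pos - start
        pieces[chrom].append(_random_seq(rng, span_len, gc))
        cursors[chrom] += span_len

        gene_id = f"gene{g:04d}"
        t = Transcript(transcript_id=f"{gene_id}.t1", exons=list(exons))
        if is_lnc:
            gm = GeneModel(gene_id, chrom, strand, biotype="lncRNA", transcripts=[t])
        else:
            # UTR5 at the transcriptional start, UTR3 at the end
            first, last = exons[0], exons[-1]
            if strand == "+":
                utr5 = [(first[0], first[0] + u5 - 1)]
                utr3 = [(last[1] - u3 + 1, last[1])]
            else:
                utr5 = [(last[1] - u5 + 1, last[1])]
                utr3 = [(first[0], first[0] + u3 - 1)]
            cds = []
            for s, e in exons:
                cs, ce = s, e
                for us, ue in utr5 + utr3:
                    if us <= cs <= ue:
                        cs = ue + 1
                    if us <= ce <= ue:
                        ce = us - 1
                if cs <= ce:
                    cds.append((cs, ce))
            t.cds = cds
            t.utr5 = utr5
            t.utr3 = utr3
            gm = GeneModel(gene_id, chrom, strand, biotype="coding", transcripts=[t])
        gm.validate()
        models.append(gm)
    for chrom in chrom_names:
        tail = int(rng.integers(200, 400))
        pieces[chrom].append(_random_seq(rng, tail, gc))
    genome = {c: "".join(pieces[c]) for c in chrom_names}
    return genome, models


def write_gff(models: Sequence[GeneModel], path) -> None:
    """GFF3-like annotation with gene/transcript/exon/CDS/UTR hierarchy."""
    ttype = {"coding": "mRNA", "lncRNA": "lnc_RNA", "other": "transcript"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in models:
            s, e = gm.span
            fh.write(
                f"{gm.chrom}\tedicall\tgene\t{s}\t{e}\t.\t{gm.strand}\t.\t"
                f"ID={gm.gene_id};biotype={gm.biotype}\n"
            )
            for t in gm.transcripts:
                ts, te = t.span
                fh.write(
                    f"{gm.chrom}\tedicall\t{ttype[gm.biotype]}\t{ts}\t{te}\t.\t"
                    f"{gm.strand}\t.\tID={t.transcript_id};Parent={gm.gene_id}\n"
                )
                rows = [("exon", iv) for iv in t.exons]
                rows += [("CDS", iv) for iv in t.cds]
                rows += [("five_prime_UTR", iv) for iv in t.utr5]
                rows += [("three_prime_UTR", iv) for iv in t.utr3]
                for i, (ftype, (fs, fe)) in enumerate(sorted(rows, key=lambda r: r[1])):
                    fh.write(
                        f"{gm.chrom}\tedicall\t{ftype}\t{fs}\t{fe}\t.\t{gm.strand}\t.\t"
                        f"ID={t.transcript_id}.{ftype}.{i};Parent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# truth planning
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "region",
    "gene_id",
    "kind",  # true | artifact_shared | artifact_adar_only | snp
    "alt",
    "level_wild_type",
    "level_adbp1_mutant",
    "level_adar_null",
]


def plan_truth_sites(
    models: Sequence[GeneModel],
    genome: Mapping[str, str],
    profile: SimProfile = SimProfile(),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw the ground-truth editing sites, artifact sites and SNPs.

    True sites sit on gene-strand adenosines drawn from the strain's
    region mix; a minus-strand gene's site therefore carries a T>C
    signature on the plus strand.  Artifact sites mimic the A-to-I
    signature at 5-10% and are present either in every strain (systematic
    artifacts the ADAR-null subtraction must remove) or only in the
    ADAR-null strain.  SNPs are homozygous alternative alleles.
    """
    from .context import _adenosine_positions_by_region

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB33]))
    pool = _adenosine_positions_by_region(genome, models)
    gene_by_pos: dict[tuple[str, int], str] = {}
    for gm in models:
        s, e = gm.span
        for p in range(s, e + 1):
            gene_by_pos.setdefault((gm.chrom, p), gm.gene_id)
    used: set[tuple[str, int]] = set()
    rows = []

    def draw_from(region: str, n: int) -> list[tuple[str, int, str]]:
        regions = ("utr5", "utr3") if region == "utr" else (region,)
        candidates = sorted(
            {c for r in regions for c in pool.get(r, []) if (c[0], c[1]) not in used}
        )
        if len(candidates) < n:
            raise ValueError(
                f"region {region!r}: need {n} adenosines, only {len(candidates)} free"
            )
        picked = [candidates[i] for i in rng.choice(len(candidates), n, replace=False)]
        used.update((c, p) for c, p, _ in picked)
        return picked

    lo, hi = profile.level_range
    for strain in ("wild_type", "adbp1_mutant"):
        n_total = profile.n_sites.get(strain, 0)
        if n_total == 0:
            continue
        mix = profile.region_mix[strain]
        regions = sorted(mix)
        # largest-remainder allocation: the planned region mix matches the
        # profile exactly, so recovered-fraction checks reflect the caller,
        # not planning noise
        exact = np.array([mix[r] * n_total for r in regions])
        n_per = np.floor(exact).astype(int)
        remainder = exact - n_per
        for i in np.argsort(-remainder)[: n_total - int(n_per.sum())]:
            n_per[i] += 1
        for region, n in zip(regions, n_per):
            for chrom, pos, strand in draw_from(region, int(n)):
                level = float(rng.uniform(lo, hi))
                rows.append(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "strand": strand,
                        "region": region,
                        "gene_id": gene_by_pos.get((chrom, pos), ""),
                        "kind": "true",
                        "alt": "G" if strand == "+" else "C",
                        "level_wild_type": level if strain == "wild_type" else 0.0,
                        "level_adbp1_mutant": level if strain == "adbp1_mutant" else 0.0,
                        "level_adar_null": 0.0,
                    }
                )

    # artifact sites: A-to-I-like changes that are not editing
    alo, ahi = profile.artifact_level_range
    n_shared = int(round(profile.n_artifacts * profile.artifact_shared_fraction))
    art_regions = ["cds_exon", "intron"]
    art_sites = []
    for i in range(profile.n_artifacts):
        art_sites.extend(draw_from(art_regions[i % 2], 1))
    for i, (chrom, pos, strand) in enumerate(art_sites):
        level = float(rng.uniform(alo, ahi))
        shared = i < n_shared
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "strand": strand,
                "region": "artifact",
                "gene_id": gene_by_pos.get((chrom, pos), ""),
                "kind": "artifact_shared" if shared else "artifact_adar_only",
                "alt": "G" if strand == "+" else "C",
                "level_wild_type": level if shared else 0.0,
                "level_adbp1_mutant": level if shared else 0.0,
                "level_adar_null": level,
            }
        )

    # homozygous SNPs anywhere in gene spans
    genic = sorted(gene_by_pos)
    free = [k for k in genic if k not in used]
    idx = rng.choice(len(free), size=min(profile.n_snps, len(free)), replace=False)
    for i in sorted(idx):
        chrom, pos = free[i]
        ref = genome[chrom][pos - 1]
        alts = [nt for nt in NUCLEOTIDES if nt != ref]
        alt = alts[int(rng.integers(0, 3))]
        used.add((chrom, pos))
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "strand": "+",
                "region": "snp",
                "gene_id": gene_by_pos.get((chrom, pos), ""),
                "kind": "snp",
                "alt": alt,
                "level_wild_type": 1.0,
                "level_adbp1_mutant": 1.0,
                "level_adar_null": 1.0,
            }
        )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return truth.sort_values(["chrom", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# pileup simulation
# ---------------------------------------------------------------------------

_BYTE = {nt: ord(nt) for nt in NUCLEOTIDES}
_LOWER = {nt: ord(nt.lower()) for nt in NUCLEOTIDES}


def _strain_levels(truth: pd.DataFrame, strain: str, multiplier: float):
    """Per-chrom {pos: (alt, level)} for sites active in this strain."""
    col = f"level_{strain}"
    out: dict[str, dict[int, tuple[str, float]]] = {}
    active = truth[truth[col] > 0]
    for chrom, pos, alt, level, kind in zip(
        active["chrom"], active["pos"], active["alt"], active[col], active["kind"]
    ):
        level = 1.0 if kind == "snp" else min(1.0, level * multiplier)
        out.setdefault(chrom, {})[int(pos)] = (alt, float(level))
    return out


def simulate_sample_pileup(
    genome: Mapping[str, str],
    models: Sequence[GeneModel],
    truth: pd.DataFrame,
    profile: SimProfile,
    sample: SampleMeta,
    seed: int,
    path,
) -> None:
    """Write one sample's text pileup over all gene spans.

    Depth is negative-binomial around the coverage mean; edited reads at
    active truth sites are Binomial(depth, level); every read suffers the
    base error rate (errors uniform over the three non-ref bases); read
    strand is an unstranded coin flip; qualities are drawn i.i.d. from the
    two-point Phred model so low-quality calls pair with bases at random.
    """
    import zlib

    rng = np.random.default_rng(
        np.random.SeedSequence([seed, 0xC0FFEE, zlib.crc32(sample.sample_id.encode())])
    )
    mult = profile.stage_level_multiplier.get(sample.stage, 1.0)
    levels = _strain_levels(truth, sample.strain, mult)
    r = profile.coverage_dispersion
    p_nb = r / (r + profile.coverage_mean)
    err = profile.error_rate
    q_hi = bytes([profile.q_high + 33])
    q_lo = bytes([profile.q_low + 33])
    spans: dict[str, list[tuple[int, int]]] = {}
    for gm in models:
        spans.setdefault(gm.chrom, []).append(gm.span)
    with open(path, "wb") as fh:
        for chrom in sorted(spans):
            seq = genome[chrom]
            site_map = levels.get(chrom, {})
            for start, end in sorted(spans[chrom]):
                n = end - start + 1
                depths = rng.negative_binomial(r, p_nb, size=n)
                total = int(depths.sum())
                qual_low = rng.random(total) < profile.p_low_quality
                qual_all = np.where(qual_low, q_lo[0], q_hi[0]).astype(np.uint8).tobytes()
                offsets = np.concatenate([[0], np.cumsum(depths)])
                err_totals = rng.binomial(depths, err)
                lines = []
                for i in range(n):
                    d = int(depths[i])
                    if d == 0:
                        continue
                    pos = start + i
                    ref = seq[pos - 1]
                    site = site_map.get(pos)
                    t = 0
                    alt = None
                    if site is not None:
                        alt, level = site
                        t = int(rng.binomial(d, level)) if level < 1.0 else d
                    e = int(err_totals[i])
                    e = min(e, d - t)
                    n_ref = d - t - e
                    k = int(rng.binomial(n_ref, 0.5))
                    parts = [b"." * k, b"," * (n_ref - k)]
                    if t:
                        u = int(rng.binomial(t, 0.5))
                        parts.append(bytes([_BYTE[alt]]) * u)
                        parts.append(bytes([_LOWER[alt]]) * (t - u))
                    if e:
                        others = [nt for nt in NUCLEOTIDES if nt != ref]
                        e1 = int(rng.binomial(e, 1 / 3))
                        e2 = int(rng.binomial(e - e1, 1 / 2))
                        for nt, cnt in zip(others, (e1, e2, e - e1 - e2)):
                            if cnt:
                                u = int(rng.binomial(cnt, 0.5))
                                parts.append(bytes([_BYTE[nt]]) * u)
                                parts.append(bytes([_LOWER[nt]]) * (cnt - u))
                    bases = b"".join(parts)
                    quals = qual_all[offsets[i] : offsets[i] + d]
                    lines.append(
                        b"\t".join(
                            [
                                chrom.encode(),
                                str(pos).encode(),
                                ref.encode(),
                                str(d).encode(),
                                bases,
                                quals,
                            ]
                        )
                    )
                if lines:
                    fh.write(b"\n".join(lines) + b"\n")


# ---------------------------------------------------------------------------
# counts table
# ---------------------------------------------------------------------------


def simulate_counts(
    models: Sequence[GeneModel],
    profile: SimProfile,
    seed: int = 0,
    class_shift: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Simple per-gene negative-binomial count table for all samples.

    ``class_shift`` maps strain -> {gene_id: log2 shift} to plant
    expression differences (e.g. down-regulation of a 3'UTR-edited class
    in the mutant).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD00D]))
    genes = [gm.gene_id for gm in models]
    base = rng.lognormal(mean=5.0, sigma=1.0, size=len(genes))
    samples = profile.samples()
    data = {}
    size = 5.0
    for meta in samples:
        mu = base.copy()
        if class_shift and meta.strain in class_shift:
            shifts = class_shift[meta.strain]
            for j, g in enumerate(genes):
                if g in shifts:
                    mu[j] *= 2.0 ** shifts[g]
        p = size / (size + mu)
        data[meta.sample_id] = rng.negative_binomial(size, p)
    return pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))


# ---------------------------------------------------------------------------
# fixture emission
# ---------------------------------------------------------------------------


def emit_sample_set(
    profile: SimProfile = SimProfile(), outdir="fixtures", seed: int = 0
) -> dict:
    """Write a complete self-describing fixture directory.

    Contents: genome.fa, annotation.gff3, truth.tsv, known_sites.tsv (the
    wild-type truth plus shared artifact sites — a realistic catalogue
    containing a few non-editing entries), snps.tsv and dna_variants.tsv
    masks, counts.tsv, one pileup per sample under pileups/, and a
    manifest.  Returns the manifest dict.
    """
    outdir = Path(outdir)
    (outdir / "pileups").mkdir(parents=True, exist_ok=True)
    genome, models = make_genome_and_models(
        profile.n_genes, seed, profile.lnc_fraction, profile.gc_content
    )
    truth = plan_truth_sites(models, genome, profile, seed)
    write_fasta(genome, outdir / "genome.fa")
    write_gff(models, outdir / "annotation.gff3")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    catalogue = [
        (r.chrom, int(r.pos), genome[r.chrom][int(r.pos) - 1])
        for r in truth.itertuples()
        if (r.kind == "true" and r.level_wild_type > 0) or r.kind == "artifact_shared"
    ]
    write_catalogue(sorted(catalogue), outdir / "known_sites.tsv")

    snps = truth[truth["kind"] == "snp"]
    half = len(snps) // 2
    write_variant_mask(
        [(r.chrom, int(r.pos), r.alt) for r in snps.iloc[:half].itertuples()],
        outdir / "dna_variants.tsv",
    )
    write_variant_mask(
        [(r.chrom, int(r.pos), r.alt) for r in snps.iloc[half:].itertuples()],
        outdir / "snps.tsv",
    )

    pileups = {}
    for meta in profile.samples():
        path = outdir / "pileups" / f"{meta.sample_id}.pileup"
        simulate_sample_pileup(genome, models, truth, profile, meta, seed, path)
        pileups[meta.sample_id] = str(path)

    counts = simulate_counts(models, profile, seed)
    write_counts(counts, outdir / "counts.tsv")

    manifest = {
        "seed": seed,
        "n_genes": profile.n_genes,
        "coverage_mean": profile.coverage_mean,
        "error_rate": profile.error_rate,
        "genome_length": {c: len(s) for c, s in genome.items()},
        "n_truth_sites": int((truth["kind"] == "true").sum()),
        "n_artifacts": int(truth["kind"].str.startswith("artifact").sum()),
        "n_snps": int((truth["kind"] == "snp").sum()),
        "samples": sorted(pileups),
        "files": {
            "genome": "genome.fa",
            "annotation": "annotation.gff3",
            "truth": "truth.tsv",
            "known_sites": "known_sites.tsv",
            "snps": "snps.tsv",
            "dna_variants": "dna_variants.tsv",
            "counts": "counts.tsv",
            "pileup_dir": "pileups",
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_sample_paths(fixture_dir) -> dict[SampleMeta, Path]:
    """Rebuild SampleMeta -> pileup path from a fixture directory."""
    fixture_dir = Path(fixture_dir)
    out = {}
    for path in sorted((fixture_dir / "pileups").glob("*.pileup")):
        strain, stage, rep = path.stem.rsplit("_", 2)
        out[SampleMeta(strain, stage, int(rep.removeprefix("rep")))] = path
    return out
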