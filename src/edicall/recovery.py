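"""Recovery evaluation of the calling pipeline against synthetic truth.

Runs the known-site and de-novo analyses on a fixture directory written by
:mod:`edicall.synthio` and scores the output against the planted truth:
sensitivity over detectable sites, false-positive rate over non-edited
adenosines, per-site level accuracy, recovered region mixes, and leakage
of artifact/SNP positions through the subtraction steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import annotate_sites, build_interval_index
from .denovo import DenovoConfig, run_denovo_analysis
from .formats import read_fasta, read_gene_models, read_variant_mask
from .known_sites import EditingConfig, read_catalogue, run_known_site_analysis
from .synthio import load_sample_paths


@dataclass
class RecoveryReport:
    stage: str
    n_truth: dict[str, int]
    n_detectable: dict[str, int]
    n_detected: dict[str, int]
    sensitivity: dict[str, float]
    n_negative_adenosines: int
    n_false_positives: int
    false_positive_rate: float
    level_mae: float
    level_mae_bound: float  # 2x mean binomial standard error
    region_fractions: dict[str, dict[str, float]]
    n_artifact_or_snp_leaks: int
    n_adar_only_leaks: int
    extras: dict = field(default_factory=dict)


def _binom_se(level: float, depth: int) -> float:
    return math.sqrt(level * (1 - level) / depth) if depth else float("inf")


def evaluate_recovery(
    fixture_dir,
    stage: str = "embryo",
    e_config: EditingConfig = EditingConfig(),
    d_config: DenovoConfig = DenovoConfig(),
    min_expected_edited_reads: float = 3.0,
) -> RecoveryReport:
    """Score the full pipeline on one stage of a synthetic fixture.

    A truth site counts as detectable when its expected number of edited
    reads per replica (level x mean coverage) reaches
    ``min_expected_edited_reads``; detection means the position appears in
    the strain's known-site or de-novo output.  The false-positive
    denominator is every covered gene-span position whose reference is A
    or T (an adenosine on one strand) and that carries no planted change.
    """
    fixture = Path(fixture_dir)
    truth = pd.read_csv(fixture / "truth.tsv", sep="\t")
    import json

    manifest = json.loads((fixture / "manifest.json").read_text())
    samples = load_sample_paths(fixture)
    catalogue = read_catalogue(fixture / "known_sites.tsv")
    genome = read_fasta(fixture / "genome.fa")
    models = read_gene_models(fixture / "annotation.gff3")
    index = build_interval_index(models)

    known = run_known_site_analysis(samples, catalogue, e_config, stage=stage)
    wt_known_positions = {
        (r.chrom, r.pos) for r in known.records_by_group.get(("wild_type", stage), [])
    }
    dn = run_denovo_analysis(
        samples,
        dna_mask=read_variant_mask(fixture / "dna_variants.tsv"),
        snp_mask=read_variant_mask(fixture / "snps.tsv"),
        config=d_config,
        wt_known_positions=wt_known_positions,
        stage=stage,
    )

    detected: dict[str, set[tuple[str, int]]] = {}
    for strain in ("wild_type", "adbp1_mutant"):
        pos = {
            (r.chrom, r.pos)
            for r in known.records_by_group.get((strain, stage), [])
        }
        pos |= {(r.chrom, r.pos) for r in dn.records_by_group.get((strain, stage), [])}
        detected[strain] = pos

    coverage_mean = float(manifest.get("coverage_mean", 60.0))
    n_truth, n_detectable, n_detected, sensitivity = {}, {}, {}, {}
    level_errors: list[float] = []
    level_bounds: list[float] = []
    known_wt = {
        (r.chrom, r.pos): r
        for r in known.records_by_group.get(("wild_type", stage), [])
    }
    true_rows = truth[truth["kind"] == "true"]
    for strain in ("wild_type", "adbp1_mutant"):
        col = f"level_{strain}"
        active = true_rows[true_rows[col] > 0]
        n_truth[strain] = len(active)
        det = 0
        detect = 0
        for row in active.itertuples():
            expected = getattr(row, col) * coverage_mean
            if expected < min_expected_edited_reads:
                continue
            detect += 1
            if (row.chrom, int(row.pos)) in detected[strain]:
                det += 1
            if strain == "wild_type":
                rec = known_wt.get((row.chrom, int(row.pos)))
                if rec is not None:
                    level_errors.append(abs(rec.level - getattr(row, col)))
                    level_bounds.append(_binom_se(getattr(row, col), rec.n_total))
        n_detectable[strain] = detect
        n_detected[strain] = det
        sensitivity[strain] = det / detect if detect else float("nan")

    # false positives over non-edited adenosines
    planted = {(r.chrom, int(r.pos)) for r in truth.itertuples()}
    n_neg = 0
    for gm in models:
        seq = genome[gm.chrom]
        s, e = gm.span
        for pos in range(s, e + 1):
            if seq[pos - 1] in "AT" and (gm.chrom, pos) not in planted:
                n_neg += 1
    all_calls = detected["wild_type"] | detected["adbp1_mutant"]
    fp = {p for p in all_calls if p not in planted}
    fp_rate = len(fp) / n_neg if n_neg else float("nan")

    # region mixes of the recovered sets
    region_fracs: dict[str, dict[str, float]] = {}
    from .annotate import region_fractions as _rf

    wt_records = annotate_sites(
        known.records_by_group.get(("wild_type", stage), [])
        + [
            r
            for r in dn.records_by_group.get(("wild_type", stage), [])
            if (r.chrom, r.pos) not in wt_known_positions
        ],
        index,
    )
    adbp1_records = annotate_sites(
        known.records_by_group.get(("adbp1_mutant", stage), [])
        + dn.records_by_group.get(("adbp1_mutant", stage), []),
        index,
    )
    region_fracs["wild_type"] = _rf(wt_records)
    region_fracs["adbp1_mutant"] = _rf(adbp1_records)

    bad = truth[truth["kind"].isin(["artifact_shared", "artifact_adar_only", "snp"])]
    bad_pos = {(r.chrom, int(r.pos)) for r in bad.itertuples()}
    adar_only = {
        (r.chrom, int(r.pos))
        for r in truth[truth["kind"] == "artifact_adar_only"].itertuples()
    }
    leaks = all_calls & bad_pos
    adar_leaks = all_calls & adar_only

    mae = float(np.mean(level_errors)) if level_errors else float("nan")
    bound = 2 * float(np.mean(level_bounds)) if level_bounds else float("nan")
    return RecoveryReport(
        stage=stage,
        n_truth=n_truth,
        n_detectable=n_detectable,
        n_detected=n_detected,
        sensitivity=sensitivity,
        n_negative_adenosines=n_neg,
        n_false_positives=len(fp),
        false_positive_rate=fp_rate,
        level_mae=mae,
        level_mae_bound=bound,
        region_fractions=region_fracs,
        n_artifact_or_snp_leaks=len(leaks),
        n_adar_only_leaks=len(adar_leaks),
        extras={
            "n_blacklisted": len(known.blacklisted),
            "n_denovo_adbp1": len(
                [
                    r
                    for r in dn.records_by_group.get(("adbp1_mutant", stage), [])
                    if r.status == "de_novo"
                ]
            ),
        },
    )
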