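"""Synthetic-data generator: determinism, region mixes, noise calibration."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from edicall.formats import NT_CODE, SampleMeta, read_pileup
from edicall.known_sites import NucCounts
from edicall.synthio import (
    SimProfile,
    emit_sample_set,
    load_sample_paths,
    make_genome_and_models,
    plan_truth_sites,
    simulate_counts,
    simulate_sample_pileup,
)


def dir_digest(path: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(p for p in Path(path).rglob("*") if p.is_file()):
        h.update(str(f.relative_to(path)).encode())
        h.update(f.read_bytes())
    return h.hexdigest()


class TestGenomeAndModels:
    def test_same_seed_byte_identical(self):
        g1, m1 = make_genome_and_models(n_genes=30, seed=1)
        g2, m2 = make_genome_and_models(n_genes=30, seed=1)
        assert g1 == g2
        assert [(m.gene_id, m.span, m.strand) for m in m1] == [
            (m.gene_id, m.span, m.strand) for m in m2
        ]
        g3, _ = make_genome_and_models(n_genes=30, seed=2)
        assert g1 != g3

    def test_exon_intron_arithmetic(self):
        _, models = make_genome_and_models(n_genes=40, seed=2)
        for gm in models:
            for t in gm.transcripts:
                assert len(t.exons) >= 1
                assert len(t.introns) == len(t.exons) - 1

    def test_gc_content_in_plausible_band(self):
        genome, _ = make_genome_and_models(n_genes=40, seed=3)
        seq = "".join(genome.values())
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.3 <= gc <= 0.7

    def test_both_strands_and_biotypes_present(self):
        _, models = make_genome_and_models(n_genes=60, seed=4)
        strands = {m.strand for m in models}
        biotypes = {m.biotype for m in models}
        assert strands == {"+", "-"} and "lncRNA" in biotypes


@pytest.fixture(scope="module")
def planned():
    genome, models = make_genome_and_models(n_genes=120, seed=5)
    profile = SimProfile(n_genes=120)
    truth = plan_truth_sites(models, genome, profile, seed=5)
    return genome, models, profile, truth


class TestTruthPlanning:
    def test_wild_type_intron_fraction_within_ci(self, planned):
        _, _, profile, truth = planned
        wt = truth[(truth["kind"] == "true") & (truth["level_wild_type"] > 0)]
        frac = (wt["region"] == "intron").mean()
        n = len(wt)
        assert n == profile.n_sites["wild_type"]
        assert abs(frac - 0.80) <= 1.96 * np.sqrt(0.8 * 0.2 / n)

    def test_adbp1_exon_fraction_within_ci(self, planned):
        _, _, _, truth = planned
        mut = truth[(truth["kind"] == "true") & (truth["level_adbp1_mutant"] > 0)]
        frac = (mut["region"] == "cds_exon").mean()
        assert abs(frac - 0.655) <= 1.96 * np.sqrt(0.655 * 0.345 / len(mut))

    def test_adar_null_has_no_true_editing(self, planned):
        _, _, _, truth = planned
        true_rows = truth[truth["kind"] == "true"]
        assert (true_rows["level_adar_null"] == 0).all()

    def test_sites_are_adenosines_on_their_strand(self, planned):
        genome, _, _, truth = planned
        for r in truth[truth["kind"] == "true"].itertuples():
            base = genome[r.chrom][r.pos - 1]
            assert base == ("A" if r.strand == "+" else "T")
            assert r.alt == ("G" if r.strand == "+" else "C")

    def test_snps_disjoint_from_truth_sites(self, planned):
        _, _, _, truth = planned
        keys = list(zip(truth["chrom"], truth["pos"]))
        assert len(keys) == len(set(keys))

    def test_levels_within_configured_range(self, planned):
        _, _, profile, truth = planned
        lo, hi = profile.level_range
        wt = truth[(truth["kind"] == "true") & (truth["level_wild_type"] > 0)]
        assert wt["level_wild_type"].between(lo, hi).all()


@pytest.fixture(scope="module")
def sim(tmp_path_factory):
    genome, models = make_genome_and_models(n_genes=60, seed=6)
    profile = SimProfile(
        n_genes=60,
        n_sites={"wild_type": 50, "adbp1_mutant": 50, "adar_null": 0},
        n_snps=30,
        n_artifacts=10,
        stages=("embryo",),
    )
    truth = plan_truth_sites(models, genome, profile, seed=6)
    path = tmp_path_factory.mktemp("sim") / "wt1.pileup"
    meta = SampleMeta("wild_type", "embryo", 1)
    simulate_sample_pileup(genome, models, truth, profile, meta, 6, path)
    return genome, models, profile, truth, path


class TestPileupSimulation:
    def test_seeded_determinism(self, sim, tmp_path):
        genome, models, profile, truth, path = sim
        again = tmp_path / "again.pileup"
        meta = SampleMeta("wild_type", "embryo", 1)
        simulate_sample_pileup(genome, models, truth, profile, meta, 6, again)
        assert again.read_bytes() == Path(path).read_bytes()

    def test_error_rate_calibrated(self, sim):
        """Mean mismatch rate at unplanted positions tracks the error rate."""
        genome, models, profile, truth, path = sim
        planted = set(zip(truth["chrom"], truth["pos"]))
        mismatches = depth = 0
        for col in read_pileup(path):
            if (col.chrom, col.pos) in planted:
                continue
            ref_code = NT_CODE[col.ref]
            depth += col.depth
            mismatches += int((col.codes != ref_code).sum())
        observed = mismatches / depth
        assert depth > 10**6
        assert abs(observed - profile.error_rate) <= 0.2 * profile.error_rate

    def test_coverage_near_mean(self, sim):
        *_, path = sim
        depths = [col.depth for col in read_pileup(path)]
        assert np.mean(depths) == pytest.approx(60, rel=0.05)

    def test_snp_positions_emit_alternative_allele(self, sim):
        genome, models, profile, truth, path = sim
        snps = {
            (r.chrom, int(r.pos)): r.alt
            for r in truth[truth["kind"] == "snp"].itertuples()
        }
        seen = 0
        for col in read_pileup(path):
            alt = snps.get((col.chrom, col.pos))
            if alt is None or col.depth == 0:
                continue
            seen += 1
            assert (col.codes == NT_CODE[alt]).all()
        assert seen > 0

    def test_adar_null_lacks_wild_type_editing(self, sim, tmp_path):
        genome, models, profile, truth, _ = sim
        path = tmp_path / "adar.pileup"
        meta = SampleMeta("adar_null", "embryo", 1)
        simulate_sample_pileup(genome, models, truth, profile, meta, 6, path)
        wt_sites = {
            (r.chrom, int(r.pos)): r.alt
            for r in truth[
                (truth["kind"] == "true") & (truth["level_wild_type"] > 0)
            ].itertuples()
        }
        target = total = 0
        for col in read_pileup(path):
            alt = wt_sites.get((col.chrom, col.pos))
            if alt is None:
                continue
            target += int((col.codes == NT_CODE[alt]).sum())
            total += col.depth
        # only error-rate mismatches: ~1/3 of 0.001
        assert total > 2000
        assert target / total < 0.002

    def test_level_converges_at_extreme_depth(self, tmp_path):
        genome, models = make_genome_and_models(n_genes=4, seed=7)
        profile = SimProfile(
            n_genes=4,
            n_sites={"wild_type": 3, "adbp1_mutant": 0, "adar_null": 0},
            region_mix={"wild_type": {"intron": 0.5, "cds_exon": 0.5}},
            n_snps=0,
            n_artifacts=0,
            coverage_mean=10_000,
            stages=("embryo",),
        )
        truth = plan_truth_sites(models, genome, profile, seed=7)
        path = tmp_path / "deep.pileup"
        meta = SampleMeta("wild_type", "embryo", 1)
        simulate_sample_pileup(genome, models, truth, profile, meta, 7, path)
        sites = {
            (r.chrom, int(r.pos)): (r.alt, r.level_wild_type)
            for r in truth[truth["kind"] == "true"].itertuples()
        }
        for col in read_pileup(path):
            hit = sites.get((col.chrom, col.pos))
            if hit is None:
                continue
            alt, level = hit
            observed = (col.codes == NT_CODE[alt]).mean()
            se = np.sqrt(level * (1 - level) / col.depth)
            assert abs(observed - level) <= 3 * se + 0.001


class TestEmitSampleSet:
    def test_full_design_is_eighteen_samples(self, tmp_path):
        profile = SimProfile(
            n_genes=6,
            n_sites={"wild_type": 5, "adbp1_mutant": 5, "adar_null": 0},
            n_snps=4,
            n_artifacts=2,
        )
        manifest = emit_sample_set(profile, tmp_path / "fx", seed=9)
        pileups = list((tmp_path / "fx" / "pileups").glob("*.pileup"))
        assert len(pileups) == 18  # 3 strains x 2 stages x 3 replicas
        assert len(manifest["samples"]) == 18
        samples = load_sample_paths(tmp_path / "fx")
        assert len(samples) == 18
        assert all(isinstance(m, SampleMeta) for m in samples)

    def test_regeneration_identical_digest(self, tmp_path):
        profile = SimProfile(
            n_genes=6,
            n_sites={"wild_type": 5, "adbp1_mutant": 5, "adar_null": 0},
            n_snps=4,
            n_artifacts=2,
            stages=("embryo",),
        )
        emit_sample_set(profile, tmp_path / "a", seed=10)
        emit_sample_set(profile, tmp_path / "b", seed=10)
        assert dir_digest(tmp_path / "a") == dir_digest(tmp_path / "b")

    def test_catalogue_matches_wild_type_truth(self, small_fixture):
        d = small_fixture["dir"]
        from edicall.known_sites import read_catalogue

        truth = pd.read_csv(d / "truth.tsv", sep="\t")
        cat = {(c, p) for c, p, _ in read_catalogue(d / "known_sites.tsv")}
        wt = {
            (r.chrom, int(r.pos))
            for r in truth[
                (truth["kind"] == "true") & (truth["level_wild_type"] > 0)
            ].itertuples()
        }
        shared = {
            (r.chrom, int(r.pos))
            for r in truth[truth["kind"] == "artifact_shared"].itertuples()
        }
        assert cat == wt | shared


class TestSimulatedCounts:
    def test_planted_class_shift_changes_means(self):
        _, models = make_genome_and_models(n_genes=40, seed=11)
        profile = SimProfile(n_genes=40, stages=("embryo",))
        shifted_genes = {m.gene_id: -1.5 for m in models[:10]}
        counts = simulate_counts(
            models, profile, seed=11, class_shift={"adbp1_mutant": shifted_genes}
        )
        wt_cols = [c for c in counts.columns if c.startswith("wild_type")]
        mut_cols = [c for c in counts.columns if c.startswith("adbp1_mutant")]
        ratio = (counts.loc[list(shifted_genes), mut_cols].mean(axis=1) + 1) / (
            counts.loc[list(shifted_genes), wt_cols].mean(axis=1) + 1
        )
        assert np.median(ratio) < 0.6
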