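import numpy as np
import pytest

from edicall.formats import GeneModel, Transcript
from edicall.synthio import SimProfile, emit_sample_set


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A desk-scale single-stage fixture shared by pipeline-level tests."""
    out = tmp_path_factory.mktemp("fixture_small")
    profile = SimProfile(
        n_genes=24,
        n_sites={"wild_type": 40, "adbp1_mutant": 40, "adar_null": 0},
        n_snps=20,
        n_artifacts=8,
        stages=("embryo",),
    )
    manifest = emit_sample_set(profile, out, seed=11)
    return {"dir": out, "profile": profile, "manifest": manifest, "seed": 11}


@pytest.fixture
def hand_models():
    """Two hand-built genes: a plus-strand coding gene and a minus-strand
    coding gene whose isoforms disagree at one position."""
    plus = GeneModel(
        gene_id="gplus",
        chrom="chrT",
        strand="+",
        biotype="coding",
        transcripts=[
            Transcript(
                transcript_id="gplus.t1",
                exons=[(100, 200), (301, 400)],
                utr5=[(100, 129)],
                cds=[(130, 200), (301, 360)],
                utr3=[(361, 400)],
            ),
            # second isoform skips the intron region entirely: position
            # 250 is intronic for t1 but exonic (CDS) for t2
            Transcript(
                transcript_id="gplus.t2",
                exons=[(100, 400)],
                utr5=[(100, 129)],
                cds=[(130, 360)],
                utr3=[(361, 400)],
            ),
        ],
    )
    minus = GeneModel(
        gene_id="gminus",
        chrom="chrT",
        strand="-",
        biotype="coding",
        transcripts=[
            Transcript(
                transcript_id="gminus.t1",
                exons=[(1000, 1100), (1201, 1300)],
                # transcription right-to-left: UTR5 at the right end
                utr5=[(1271, 1300)],
                cds=[(1050, 1100), (1201, 1270)],
                utr3=[(1000, 1049)],
            )
        ],
    )
    lnc = GeneModel(
        gene_id="glnc",
        chrom="chrT",
        strand="+",
        biotype="lncRNA",
        transcripts=[
            Transcript(transcript_id="glnc.t1", exons=[(2000, 2150), (2251, 2400)])
        ],
    )
    return [plus, minus, lnc]


@pytest.fixture
def hand_genome(hand_models):
    rng = np.random.default_rng(3)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=3000)])
    return {"chrT": seq}
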