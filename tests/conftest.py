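import pytest

from fusiontriage import fusion_io
from fusiontriage.synthetic_data import generate_cohort, paper_fixture


@pytest.fixture(scope="session")
def paper_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("paper_bundle")
    return paper_fixture(out)


@pytest.fixture(scope="session")
def paper_genes(paper_bundle):
    return fusion_io.read_gene_models(paper_bundle["gtf"])


@pytest.fixture(scope="session")
def paper_cytobands(paper_bundle):
    return fusion_io.read_cytobands(paper_bundle["cytobands"])


@pytest.fixture(scope="session")
def paper_candidates(paper_bundle):
    return fusion_io.read_fusion_table(paper_bundle["chimerascan"],
                                       "chimerascan")


@pytest.fixture(scope="session")
def cohort_bundle(tmp_path_factory):
    """One default synthetic cohort shared by read-only tests."""
    out = tmp_path_factory.mktemp("cohort_s1")
    return generate_cohort(1, 4, out_dir=out)


@pytest.fixture()
def cohort_factory(tmp_path):
    def make(seed, n_samples=4, **kwargs):
        return generate_cohort(seed, n_samples,
                               out_dir=tmp_path / f"cohort_{seed}", **kwargs)

    return make


def make_gene(symbol="GENEA", chrom="chr1", start=10_000, strand="+",
              n_exons=3, exon_len=1_500, intron_len=1_500, cds_pad=300):
    """Small multi-exon coding gene for unit tests."""
    exons = []
    pos = start
    for _ in range(n_exons):
        exons.append((pos, pos + exon_len - 1))
        pos += exon_len + intron_len
    cds_lo = exons[0][0] + cds_pad
    cds_hi = exons[-1][1] - cds_pad
    total = sum(min(b, cds_hi) - max(a, cds_lo) + 1 for a, b in exons
                if max(a, cds_lo) <= min(b, cds_hi))
    cds_hi -= total % 3  # keep the CDS a codon multiple
    if strand == "-":
        exons = exons[::-1]
    return fusion_io.GeneModel(gene_id=symbol, transcript_id=f"{symbol}-T1",
                               chrom=chrom, strand=strand, exons=exons,
                               cds_start=cds_lo, cds_end=cds_hi)


def make_candidate(g5, g3, pos5=None, pos3=None, sample="S1", split=10,
                   spanning=5, ds=None, strand5=None, strand3=None,
                   caller="chimerascan"):
    return fusion_io.FusionCandidate(
        sample_id=sample, gene5=g5.gene_id, gene3=g3.gene_id,
        chrom5=g5.chrom, pos5=pos5 if pos5 is not None else g5.start + 400,
        strand5=strand5 or g5.strand,
        chrom3=g3.chrom, pos3=pos3 if pos3 is not None else g3.start + 400,
        strand3=strand3 or g3.strand,
        split_reads=split, spanning_reads=spanning, driver_score=ds,
        caller=caller)
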