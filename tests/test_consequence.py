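import random

import pytest
from Bio.Seq import Seq, reverse_complement
from hypothesis import given, settings
from hypothesis import strategies as st

from fusiontriage.consequence import (classify_orientation, determine_frame,
                                      enumerate_isoforms,
                                      fusion_protein_extent,
                                      junction_contexts, microhomology_length)
from fusiontriage.fusion_io import GeneModel
from fusiontriage.synthetic_data import (acceptor_breakpoint,
                                         donor_breakpoint)

from conftest import make_candidate, make_gene


def cds_gene(symbol, chrom, start, strand, cds_nt, utr=200):
    """Single-exon gene with a CDS of ``cds_nt`` bases."""
    end = start + utr + cds_nt + utr - 1
    return GeneModel(gene_id=symbol, transcript_id=f"{symbol}-T1",
                     chrom=chrom, strand=strand, exons=[(start, end)],
                     cds_start=start + utr, cds_end=start + utr + cds_nt - 1)


def frame_case(c5, s3, l5=900, l3=900):
    g5 = cds_gene("DON", "chr1", 10_000, "+", l5)
    g3 = cds_gene("ACC", "chr2", 10_000, "+", l3)
    cand = make_candidate(g5, g3, pos5=donor_breakpoint(g5, c5),
                          pos3=acceptor_breakpoint(g3, s3))
    return cand, g5, g3


class TestDetermineFrame:
    def test_congruent_in_frame(self):
        cand, g5, g3 = frame_case(300, 33)
        fr = determine_frame(cand, g5, g3)
        assert fr.status == "in_frame" and (fr.c5, fr.s3) == (300, 33)

    def test_incongruent_out_of_frame(self):
        cand, g5, g3 = frame_case(301, 33)
        assert determine_frame(cand, g5, g3).status == "out_of_frame"

    def test_published_junction_in_frame(self, paper_genes, paper_candidates):
        cand = next(c for c in paper_candidates if c.gene5 == "ZEB2")
        g5, g3 = paper_genes.get("ZEB2"), paper_genes.get("BCL11B")
        fr = determine_frame(cand, g5, g3)
        assert fr.status == "in_frame"
        assert fr.c5 == 72 and fr.s3 == 57
        extent = fusion_protein_extent(fr, g5, g3)
        assert extent.first_acceptor_codon == 20

    def test_noncoding_partner(self):
        g5 = cds_gene("DON", "chr1", 10_000, "+", 900)
        g3 = GeneModel(gene_id="NC", transcript_id="NC-T1", chrom="chr2",
                       strand="+", exons=[(10_000, 12_000)])
        cand = make_candidate(g5, g3, pos5=donor_breakpoint(g5, 300),
                              pos3=10_500)
        assert determine_frame(cand, g5, g3).status == "noncoding"

    def test_promoter_swap(self):
        g5 = cds_gene("DON", "chr1", 10_000, "+", 900, utr=500)
        g3 = cds_gene("ACC", "chr2", 10_000, "+", 900, utr=500)
        # Junction in the donor 5'UTR and upstream of the acceptor CDS.
        cand = make_candidate(g5, g3, pos5=g5.start + 100, pos3=g3.start + 100)
        assert determine_frame(cand, g5, g3).status == "promoter_swap"

    def test_donor_full_orf_is_not_promoter_swap(self):
        g5 = cds_gene("DON", "chr1", 10_000, "+", 900, utr=500)
        g3 = cds_gene("ACC", "chr2", 10_000, "+", 900, utr=500)
        cand = make_candidate(g5, g3, pos5=g5.end - 10, pos3=g3.start + 100)
        assert determine_frame(cand, g5, g3).status == "out_of_frame"

    def test_inverted_acceptor_out_of_frame(self):
        g5 = cds_gene("DON", "chr1", 10_000, "+", 900)
        g3 = cds_gene("ACC", "chr2", 10_000, "-", 900)
        cand = make_candidate(g5, g3, pos5=donor_breakpoint(g5, 300),
                              pos3=10_500, strand3="+")
        assert determine_frame(cand, g5, g3).status == "out_of_frame"

    def test_outside_span_is_contract_violation(self):
        cand, g5, g3 = frame_case(300, 33)
        cand.pos5 = g5.end + 10_000
        with pytest.raises(ValueError):
            determine_frame(cand, g5, g3)

    def test_intronic_breakpoint_snaps_to_exon_boundary(self):
        g5 = make_gene("DON", "chr1", 10_000)
        g3 = make_gene("ACC", "chr2", 10_000)
        exon1_end = sorted(g5.exons)[0][1]
        intronic = make_candidate(g5, g3, pos5=exon1_end + 700,
                                  pos3=g3.start + 400)
        snapped = make_candidate(g5, g3, pos5=exon1_end,
                                 pos3=g3.start + 400)
        fr_a = determine_frame(intronic, g5, g3)
        fr_b = determine_frame(snapped, g5, g3)
        assert (fr_a.status, fr_a.c5, fr_a.s3) == (fr_b.status, fr_b.c5,
                                                   fr_b.s3)

    def test_unsnappable_breakpoint_undetermined(self):
        g5 = GeneModel(gene_id="HUGE", transcript_id="HUGE-T1", chrom="chr1",
                       strand="+", exons=[(1_000, 2_000), (900_000, 903_000)],
                       cds_start=1_200, cds_end=902_999)
        g3 = cds_gene("ACC", "chr2", 10_000, "+", 900)
        cand = make_candidate(g5, g3, pos5=600_000,
                              pos3=acceptor_breakpoint(g3, 33))
        assert determine_frame(cand, g5, g3).status == "undetermined"

    def test_translate_and_scan_oracle(self):
        """Frame congruence must agree with actually translating the fused
        CDS: in frame iff the acceptor's stop is reached in frame with no
        premature stop (junction codon excepted)."""
        rng = random.Random(42)
        codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
        sense = [c for c in codons if c not in ("TAA", "TAG", "TGA")]
        for _ in range(500):
            n5, n3 = rng.randint(20, 120), rng.randint(20, 120)
            cds5 = "".join(rng.choice(sense) for _ in range(n5))
            cds3 = "".join(rng.choice(sense) for _ in range(n3)) + "TAA"
            c5 = rng.randint(1, len(cds5))
            s3 = rng.randint(0, len(cds3) - 3)
            fused = cds5[:c5] + cds3[s3:]
            junction_codon = c5 // 3 if c5 % 3 else None
            oracle = len(fused) % 3 == 0
            if oracle:
                aa = str(Seq(fused).translate())
                n_codons = len(fused) // 3
                for i, residue in enumerate(aa):
                    if residue == "*" and i != n_codons - 1 \
                            and i != junction_codon:
                        oracle = False
                        break
                else:
                    oracle = oracle and aa.endswith("*")
            cand, g5, g3 = frame_case(c5, s3, l5=len(cds5), l3=len(cds3))
            got = determine_frame(cand, g5, g3).status
            assert got == ("in_frame" if oracle else "out_of_frame"), \
                (c5, s3, got, oracle)


class TestClassifyOrientation:
    def test_both_conserved(self):
        g5 = cds_gene("A", "chr1", 1_000, "+", 300)
        g3 = cds_gene("B", "chr2", 1_000, "+", 300)
        cand = make_candidate(g5, g3)
        o = classify_orientation(cand, g5, g3)
        assert (o.orient5, o.orient3) == ("conserved", "conserved")

    def test_published_mixed_orientation(self, paper_genes, paper_candidates):
        cand = next(c for c in paper_candidates if c.gene5 == "CNOT2")
        o = classify_orientation(cand, paper_genes.get("CNOT2"),
                                 paper_genes.get("WT1"))
        assert (o.orient5, o.orient3) == ("conserved", "inverted")

    def test_both_inverted(self):
        g5 = cds_gene("A", "chr1", 1_000, "-", 300)
        g3 = cds_gene("B", "chr2", 1_000, "-", 300)
        cand = make_candidate(g5, g3, strand5="+", strand3="+")
        o = classify_orientation(cand, g5, g3)
        assert (o.orient5, o.orient3) == ("inverted", "inverted")


class TestEnumerateIsoforms:
    def test_published_three_isoforms(self, paper_genes, paper_candidates):
        cand = next(c for c in paper_candidates if c.gene5 == "ZEB2")
        isoforms = enumerate_isoforms(cand, paper_genes.get("ZEB2"),
                                      paper_genes.get("BCL11B"), max_skip=2)
        assert [i.label for i in isoforms] == ["type 1", "type 2", "type 3"]
        # exon 2 of the donor joined to exons 2, 3 and 4 of the acceptor
        assert [i.junction for i in isoforms] == [(1, 1), (1, 2), (1, 3)]
        assert [i.skipped_acceptor_exons for i in isoforms] == [0, 1, 2]

    def test_max_skip_zero(self, paper_genes, paper_candidates):
        cand = next(c for c in paper_candidates if c.gene5 == "ZEB2")
        isoforms = enumerate_isoforms(cand, paper_genes.get("ZEB2"),
                                      paper_genes.get("BCL11B"), max_skip=0)
        assert len(isoforms) == 1 and isoforms[0].label == "type 1"

    def test_capped_by_exon_availability(self, paper_genes, paper_candidates):
        cand = next(c for c in paper_candidates if c.gene5 == "ZEB2")
        isoforms = enumerate_isoforms(cand, paper_genes.get("ZEB2"),
                                      paper_genes.get("BCL11B"), max_skip=5)
        assert len(isoforms) == 3  # only exons 2-4 available downstream

    def test_negative_max_skip_raises(self, paper_genes, paper_candidates):
        cand = next(c for c in paper_candidates if c.gene5 == "ZEB2")
        with pytest.raises(ValueError):
            enumerate_isoforms(cand, paper_genes.get("ZEB2"),
                               paper_genes.get("BCL11B"), max_skip=-1)

    def test_isoform_frames_consistent_with_shifted_junction(
            self, paper_genes, paper_candidates):
        cand = next(c for c in paper_candidates if c.gene5 == "ZEB2")
        g5, g3 = paper_genes.get("ZEB2"), paper_genes.get("BCL11B")
        for iso in enumerate_isoforms(cand, g5, g3, max_skip=2):
            shifted = make_candidate(
                g5, g3, pos5=cand.pos5,
                pos3=g3.exon_tx_start(iso.junction[1])
                if iso.skipped_acceptor_exons else cand.pos3)
            direct = determine_frame(shifted, g5, g3)
            assert iso.frame.status == direct.status
            assert (iso.frame.c5, iso.frame.s3) == (direct.c5, direct.s3)


class TestFusionProteinExtent:
    def test_published_extent(self, paper_genes, paper_candidates):
        cand = next(c for c in paper_candidates if c.gene5 == "ZEB2")
        g5, g3 = paper_genes.get("ZEB2"), paper_genes.get("BCL11B")
        fr = determine_frame(cand, g5, g3)
        ext = fusion_protein_extent(fr, g5, g3)
        assert ext.residues5 == 24
        assert ext.residues3 == 803
        assert ext.total_acceptor_residues == 823
        assert ext.first_acceptor_codon == 20
        assert ext.junction_codon_donor_bases == 0

    def test_initiator_only(self):
        from fusiontriage.consequence import FrameResult

        g5 = cds_gene("A", "chr1", 1_000, "+", 300)
        g3 = cds_gene("B", "chr2", 1_000, "+", 2_469)
        ext = fusion_protein_extent(FrameResult("in_frame", c5=3, s3=0),
                                    g5, g3)
        assert ext.residues5 == 1
        assert ext.residues3 == 822  # every acceptor amino acid retained

    def test_entire_acceptor_cds_removed(self):
        from fusiontriage.consequence import FrameResult

        g5 = cds_gene("A", "chr1", 1_000, "+", 300)
        g3 = cds_gene("B", "chr2", 1_000, "+", 300)
        ext = fusion_protein_extent(FrameResult("in_frame", c5=300, s3=300),
                                    g5, g3)
        assert ext.residues3 == 0

    def test_out_of_frame_is_contract_violation(self):
        from fusiontriage.consequence import FrameResult

        g5 = cds_gene("A", "chr1", 1_000, "+", 300)
        g3 = cds_gene("B", "chr2", 1_000, "+", 300)
        with pytest.raises(ValueError):
            fusion_protein_extent(FrameResult("out_of_frame"), g5, g3)

    def test_length_conservation(self):
        from fusiontriage.consequence import FrameResult

        g5 = cds_gene("A", "chr1", 1_000, "+", 300)
        g3 = cds_gene("B", "chr2", 1_000, "+", 2_469)
        for s3 in range(0, 2_469 - 3, 3):
            ext = fusion_protein_extent(
                FrameResult("in_frame", c5=300, s3=s3), g5, g3)
            # retained residues + removed codons + stop = all codons
            assert ext.residues3 + s3 // 3 + 1 == ext.total_acceptor_residues


class TestMicrohomology:
    def test_published_three_cytosines(self):
        donor = "GATTACAGATTACAGATTACAACCC"
        acceptor = "TGACCAGGTAGGATCATCCC" + "GGATCCAGGTT"
        assert microhomology_length(donor, acceptor, max_k=20,
                                    junction_offset=20) == 3

    def test_no_shared_base(self):
        donor = "G" * 20 + "ACGA"
        acceptor = "C" * 16 + "TTTT" + "AAAA" + "G" * 10
        assert microhomology_length(donor, acceptor, max_k=20,
                                    junction_offset=20) == 0

    def test_cap_reported_when_hit(self):
        donor = "A" * 30
        acceptor = "A" * 40
        assert microhomology_length(donor, acceptor, max_k=8,
                                    junction_offset=20) == 8

    def test_short_context_raises(self):
        with pytest.raises(ValueError):
            microhomology_length("ACGT", "ACGTACGT", max_k=20)

    def test_brute_force_slide_oracle(self):
        rng = random.Random(99)
        for _ in range(1000):
            max_k = rng.randint(1, 12)
            donor = "".join(rng.choice("ACGT") for _ in range(max_k + 10))
            offset = max_k + rng.randint(0, 5)
            acceptor = "".join(rng.choice("ACGT")
                               for _ in range(offset + max_k + 5))
            fused0 = donor + acceptor[offset:]
            oracle = 0
            for k in range(1, max_k + 1):
                if donor[:-k] + acceptor[offset - k:] == fused0:
                    oracle = k
                else:
                    break
            got = microhomology_length(donor, acceptor, max_k=max_k,
                                       junction_offset=offset)
            assert got == oracle

    @given(st.text(alphabet="ACGT", min_size=25, max_size=40),
           st.text(alphabet="ACGT", min_size=45, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_complement_invariance(self, donor, acceptor):
        comp = str.maketrans("ACGT", "TGCA")
        assert microhomology_length(donor, acceptor) == \
            microhomology_length(donor.translate(comp),
                                 acceptor.translate(comp))

    def test_reverse_complement_junction_mirror(self):
        """Reading the same physical junction on the opposite strand swaps
        the left- and right-slide ambiguities; their sum is invariant."""
        rng = random.Random(5)
        for _ in range(50):
            h_left, h_right = rng.randint(0, 6), rng.randint(0, 6)
            hl = "".join(rng.choice("ACGT") for _ in range(h_left))
            hr = "".join(rng.choice("ACGT") for _ in range(h_right))
            filler = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
            # chrA: donor retained U ends at 500; continuation starts 501.
            u = filler(460 - h_left - 1) + "G" + hl
            dc = hr + "T" + filler(499 - h_right - 1)
            chr_a = filler(40) + u + dc
            # chrB: acceptor context Au ends at 600; retained V starts 601.
            au = filler(560 - h_left - 1) + "C" + hl
            v = hr + "A" + filler(399 - h_right - 1)
            chr_b = filler(40) + au + v
            genome = {"chrA": chr_a, "chrB": chr_b}
            fwd = make_candidate(
                cds_gene("D", "chrA", 1, "+", 300),
                cds_gene("A", "chrB", 1, "+", 300),
                pos5=500, pos3=601, strand5="+", strand3="+")
            rev = make_candidate(
                cds_gene("A", "chrB", 1, "-", 300),
                cds_gene("D", "chrA", 1, "-", 300),
                pos5=601, pos3=500, strand5="-", strand3="-")
            results = []
            for cand in (fwd, rev):
                donor, acceptor, offset = junction_contexts(genome, cand)
                results.append(microhomology_length(donor, acceptor,
                                                    junction_offset=offset))
            assert results[0] == h_left
            assert results[1] == h_right
            assert sum(results) == h_left + h_right

    def test_junction_contexts_mixed_strands(self):
        rng = random.Random(8)
        filler = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
        hom = "CCC"
        donor_chr = filler(496) + "A" + hom  # retained ends at 500
        acc_up = filler(96) + "T" + hom      # bases just 5' of the junction
        acc_ret = filler(400)
        # '-'-strand acceptor: upstream context lies at higher coordinates.
        acc_chr = filler(100) + reverse_complement(acc_up + acc_ret)
        genome = {"chrA": donor_chr + filler(100), "chrB": acc_chr}
        pos3 = 100 + len(acc_ret)  # first retained base, reading '-'
        cand = make_candidate(cds_gene("D", "chrA", 1, "+", 300),
                              cds_gene("A", "chrB", 1, "-", 300),
                              pos5=500, pos3=pos3, strand5="+", strand3="-")
        donor, acceptor, offset = junction_contexts(genome, cand)
        assert microhomology_length(donor, acceptor,
                                    junction_offset=offset) == 3
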