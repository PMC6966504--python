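"""Functional annotation of a chimeric junction: reading frame, partner
orientation, splicing isoforms, fusion-protein extent and junction
microhomology."""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import reverse_complement

from .fusion_io import FusionCandidate, GeneModel

FRAME_STATUSES = ("in_frame", "out_of_frame", "promoter_swap", "noncoding",
                  "undetermined")

#: Give up snapping an intronic breakpoint that is further than this from
#: the nearest usable exon boundary.
MAX_SNAP_DISTANCE = 500_000

DEFAULT_MAX_SKIP = 2
DEFAULT_MAX_K = 20


@dataclass
class FrameResult:
    """Reading-frame verdict at a chimeric junction.

    ``c5``: coding nucleotides of the 5' partner retained upstream of (and
    including) the junction.  ``s3``: coding nucleotides of the 3' partner
    upstream of (removed by) the junction.
    """

    status: str
    c5: int = 0
    s3: int = 0

    def __post_init__(self) -> None:
        if self.status not in FRAME_STATUSES:
            raise ValueError(f"unknown frame status {self.status!r}")


@dataclass
class OrientationClass:
    orient5: str  # conserved | inverted
    orient3: str


@dataclass
class IsoformModel:
    label: str
    skipped_acceptor_exons: int
    junction: tuple[int, int]  # (5' exon index, 3' exon index), 0-based
    frame: FrameResult


@dataclass
class ProteinExtent:
    residues5: int
    residues3: int
    total_acceptor_residues: int  # acceptor CDS codon count incl. stop
    first_acceptor_codon: int    # 1-based index of first fused acceptor codon
    junction_codon_donor_bases: int  # >0 when the junction splits a codon


def classify_orientation(fusion: FusionCandidate, g5: GeneModel,
                         g3: GeneModel) -> OrientationClass:
    """'conserved' when the fused transcript traverses the partner in its
    native 5'->3' direction, 'inverted' otherwise."""
    return OrientationClass(
        orient5="conserved" if fusion.strand5 == g5.strand else "inverted",
        orient3="conserved" if fusion.strand3 == g3.strand else "inverted",
    )


def _snap_donor(gene: GeneModel, pos: int) -> int | None:
    """Snap an intronic donor breakpoint to the nearest transcriptionally
    upstream exon boundary (spliced-fusion assumption)."""
    if gene.exonic(pos):
        return pos
    best = None
    for a, b in gene.exons:
        edge = b if gene.strand == "+" else a
        if gene.tx_cmp(edge, pos) < 0:  # edge upstream of pos
            if best is None or gene.tx_cmp(edge, best) > 0:
                best = edge
    if best is None or abs(best - pos) > MAX_SNAP_DISTANCE:
        return None
    return best


def _snap_acceptor(gene: GeneModel, pos: int) -> int | None:
    """Snap an intronic acceptor breakpoint to the nearest downstream exon
    start."""
    if gene.exonic(pos):
        return pos
    best = None
    for a, b in gene.exons:
        edge = a if gene.strand == "+" else b
        if gene.tx_cmp(edge, pos) > 0:
            if best is None or gene.tx_cmp(edge, best) < 0:
                best = edge
    if best is None or abs(best - pos) > MAX_SNAP_DISTANCE:
        return None
    return best


def _junction_in_cds(gene: GeneModel, pos: int) -> bool:
    return any(a <= pos <= b for a, b in gene.cds_intervals())


def determine_frame(fusion: FusionCandidate, g5: GeneModel,
                    g3: GeneModel) -> FrameResult:
    """Reading-frame call for a junction with breakpoints inside the gene
    spans.

    in_frame requires both junctions inside coding sequence, both partners
    read in their native direction, and ``c5 === s3 (mod 3)``; an acceptor
    junction at/upstream of the acceptor CDS start is a promoter swap;
    a transcript without CDS on either side is noncoding; an intronic
    breakpoint that cannot be snapped to an exon boundary is undetermined.
    """
    if not g5.contains(fusion.pos5) or not g3.contains(fusion.pos3):
        raise ValueError("breakpoint outside gene span; candidate should "
                         "carry the unreliable_structure flag")
    if not g5.is_coding or not g3.is_coding:
        return FrameResult("noncoding")
    pos5 = _snap_donor(g5, fusion.pos5)
    pos3 = _snap_acceptor(g3, fusion.pos3)
    if pos5 is None or pos3 is None:
        return FrameResult("undetermined")
    c5 = g5.coding_bases_upstream(pos5, inclusive=True)
    s3 = g3.coding_bases_upstream(pos3, inclusive=False)
    # Promoter swap: the 3' junction lies at or upstream of the acceptor CDS
    # start (acceptor ORF intact) while the donor contributes only its
    # transcript leader, not coding sequence of its own.
    if s3 == 0 and g3.tx_cmp(pos3, g3.cds_tx_start()) <= 0 and c5 == 0:
        return FrameResult("promoter_swap", c5=c5, s3=s3)
    orient = classify_orientation(fusion, g5, g3)
    if orient.orient5 == "inverted" or orient.orient3 == "inverted":
        return FrameResult("out_of_frame", c5=c5, s3=s3)
    if (_junction_in_cds(g5, pos5) and _junction_in_cds(g3, pos3)
            and c5 % 3 == s3 % 3):
        return FrameResult("in_frame", c5=c5, s3=s3)
    return FrameResult("out_of_frame", c5=c5, s3=s3)


def enumerate_isoforms(fusion: FusionCandidate, g5: GeneModel, g3: GeneModel,
                       max_skip: int = DEFAULT_MAX_SKIP) -> list[IsoformModel]:
    """Splicing isoforms skipping 0..max_skip acceptor exons immediately
    downstream of the junction, labelled 'type 1', 'type 2', ... in skip
    order; each carries its own frame call."""
    if max_skip < 0:
        raise ValueError("max_skip must be >= 0")
    pos5 = _snap_donor(g5, fusion.pos5)
    pos3 = _snap_acceptor(g3, fusion.pos3)
    if pos5 is None or pos3 is None:
        return []
    e5 = g5.exon_index_of(pos5)
    e3 = g3.exon_index_of(pos3)
    remaining = len(g3.exons) - e3
    n_isoforms = min(max_skip, remaining - 1) + 1
    out: list[IsoformModel] = []
    for skip in range(n_isoforms):
        if skip == 0:
            shifted_pos3 = pos3
        else:
            shifted_pos3 = g3.exon_tx_start(e3 + skip)
        shifted = FusionCandidate(
            sample_id=fusion.sample_id, gene5=fusion.gene5, gene3=fusion.gene3,
            chrom5=fusion.chrom5, pos5=fusion.pos5, strand5=fusion.strand5,
            chrom3=fusion.chrom3, pos3=shifted_pos3, strand3=fusion.strand3,
            split_reads=fusion.split_reads,
            spanning_reads=fusion.spanning_reads)
        frame = determine_frame(shifted, g5, g3)
        out.append(IsoformModel(label=f"type {skip + 1}",
                                skipped_acceptor_exons=skip,
                                junction=(e5, e3 + skip), frame=frame))
    return out


def fusion_protein_extent(frame: FrameResult, g5: GeneModel,
                          g3: GeneModel) -> ProteinExtent:
    """Residue bookkeeping for an in-frame fusion.

    ``total_acceptor_residues`` is the acceptor CDS codon count (stop codon
    included, matching how fusion-protein extents are conventionally
    printed); ``residues3`` counts retained amino acids, i.e. excludes the
    stop codon.
    """
    if frame.status != "in_frame":
        raise ValueError("fusion_protein_extent requires an in_frame result")
    cds_len = g3.cds_length()
    total = cds_len // 3
    residues5 = frame.c5 // 3
    residues3 = max(0, (cds_len - frame.s3) // 3 - 1)
    return ProteinExtent(
        residues5=residues5,
        residues3=residues3,
        total_acceptor_residues=total,
        first_acceptor_codon=frame.s3 // 3 + 1,
        junction_codon_donor_bases=frame.c5 % 3,
    )


def microhomology_length(donor_seq: str, acceptor_seq: str,
                         max_k: int = DEFAULT_MAX_K,
                         junction_offset: int | None = None) -> int:
    """Length of the junction microhomology: the largest k <= max_k such
    that sliding the junction left by 1..k bases leaves the fused sequence
    identical; equivalently the longest common suffix of the donor's last
    bases and the bases immediately 5' of the acceptor junction.

    ``donor_seq`` ends at the last retained donor base (fused-transcript
    orientation).  ``acceptor_seq`` carries the ``junction_offset``
    (default ``max_k``) bases preceding the acceptor junction followed by
    the retained acceptor sequence.
    """
    if max_k < 0:
        raise ValueError("max_k must be >= 0")
    offset = max_k if junction_offset is None else junction_offset
    if len(donor_seq) < max_k + 1:
        raise ValueError(f"donor context shorter than max_k+1={max_k + 1}")
    if offset < max_k or len(acceptor_seq) < offset + 1:
        raise ValueError("acceptor context lacks the required pre-junction "
                         "and retained bases")
    donor = donor_seq.upper()
    pre = acceptor_seq[offset - max_k:offset].upper()
    k = 0
    while k < max_k and donor[-(k + 1)] == pre[-(k + 1)]:
        k += 1
    return k


def junction_contexts(genome: dict[str, str], fusion: FusionCandidate,
                      flank: int = DEFAULT_MAX_K + 10,
                      ) -> tuple[str, str, int] | None:
    """Extract (donor_seq, acceptor_seq, junction_offset) around a junction
    in fused-transcript orientation from a forward-strand genome.

    Returns None when a contig is missing or the flanks run off its ends.
    """
    from .fusion_io import normalize_chrom

    contigs = {normalize_chrom(k): v for k, v in genome.items()}
    c5 = contigs.get(normalize_chrom(fusion.chrom5))
    c3 = contigs.get(normalize_chrom(fusion.chrom3))
    if c5 is None or c3 is None:
        return None
    p5, p3 = fusion.pos5, fusion.pos3
    try:
        if fusion.strand5 == "+":
            if p5 - flank < 0:
                return None
            donor = c5[p5 - flank:p5]
        else:
            donor = reverse_complement(c5[p5 - 1:p5 - 1 + flank])
        if fusion.strand3 == "+":
            if p3 - 1 - flank < 0:
                return None
            acceptor = c3[p3 - 1 - flank:p3 - 1 + flank]
        else:
            acceptor = reverse_complement(c3[p3 - flank:p3 + flank])
    except IndexError:
        return None
    if len(donor) < flank or len(acceptor) < 2 * flank:
        return None
    return donor, acceptor, flank
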