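"""Interstitial copy-number-loss inference from intrachromosomal
flanking-gene fusions, and comparison against SNP-array segments."""

from __future__ import annotations

from dataclasses import dataclass, field

from .fusion_io import FusionCandidate, GeneModelIndex, normalize_chrom

#: Fraction of the inferred interval a CN segment must cover to count.
SEGMENT_OVERLAP_FRACTION = 0.5


@dataclass
class DeletionCall:
    chrom: str
    start: int
    end: int
    encompassed_genes: list[str] = field(default_factory=list)
    evidence_fusion: str = ""
    approximate: bool = False
    cn_support: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("deletion interval start > end")

    @property
    def size_bp(self) -> int:
        return self.end - self.start + 1


def infer_interstitial_deletion(fusion: FusionCandidate,
                                genes: GeneModelIndex,
                                ) -> DeletionCall | None:
    """Infer the genomic interval lost between the retained portions of a
    colinear intrachromosomal fusion; None when the fusion does not imply a
    loss.

    With junction strands (+,+) the retained pieces are [.., pos5] and
    [pos3, ..], so the loss is [pos5+1, pos3-1]; with (-,-) the arithmetic
    mirrors.  Mixed junction strands fold back rather than delete, and an
    orientation placing the acceptor's retained segment upstream of the
    donor's implies duplication, not loss; both return None.  Reading the
    same junction on the opposite strand (roles and strands both swapped)
    therefore yields the identical call.
    """
    if normalize_chrom(fusion.chrom5) != normalize_chrom(fusion.chrom3):
        return None
    g5, g3 = genes.get(fusion.gene5), genes.get(fusion.gene3)
    if g5 is None or g3 is None:
        return None
    # Colinear configuration: partner genes on one strand, junction read
    # consistently (both native or both antisense).
    if g5.strand != g3.strand or fusion.strand5 != fusion.strand3:
        return None
    if fusion.strand5 == "+":
        start, end = fusion.pos5 + 1, fusion.pos3 - 1
    else:
        start, end = fusion.pos3 + 1, fusion.pos5 - 1
    if start > end:
        return None  # no_loss_orientation
    chrom = normalize_chrom(fusion.chrom5)
    approximate = (fusion.pos5 in (g5.start, g5.end)
                   or fusion.pos3 in (g3.start, g3.end))
    encompassed = sorted({
        m.gene_id for m in genes.overlapping(fusion.chrom5, start, end)
        if start <= m.start and m.end <= end
    })
    return DeletionCall(chrom=chrom, start=start, end=end,
                        encompassed_genes=encompassed,
                        evidence_fusion=(f"{fusion.sample_id}:"
                                         f"{fusion.gene5}-{fusion.gene3}"),
                        approximate=approximate)


def intersect_with_cn_segments(deletion: DeletionCall,
                               segments: list[tuple[str, int, int, float]],
                               ) -> str:
    """'supported' when loss segments (CN < 2) cover >= 50% of the interval,
    'contradicted' when neutral/gain segments do, 'untested' otherwise."""
    loss_cov = neutral_cov = 0
    for chrom, start, end, cn in segments:
        if start > end:
            raise ValueError(f"malformed segment {chrom}:{start}-{end}")
        if normalize_chrom(chrom) != deletion.chrom:
            continue
        ov = min(end, deletion.end) - max(start, deletion.start) + 1
        if ov <= 0:
            continue
        if cn < 2:
            loss_cov += ov
        else:
            neutral_cov += ov
    threshold = SEGMENT_OVERLAP_FRACTION * deletion.size_bp
    if loss_cov >= threshold:
        return "supported"
    if neutral_cov >= threshold:
        return "contradicted"
    return "untested"
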