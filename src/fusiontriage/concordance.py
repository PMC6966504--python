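"""Cytogenetic concordance: does a karyotype event explain a fusion?

Band distance is computed on major-band integers of the same arm
(q22.3 -> major 22); sub-band precision is deliberately ignored because
chromosome banding calls are coarser than sequence coordinates.  Band-range
tokens such as 'q14-q23' match if any major band in the range is within
tolerance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .fusion_io import (CytobandMap, FusionCandidate, GeneModel,
                        GeneModelIndex, normalize_chrom)
from .iscn import Karyotype, StructuralEvent, extract_translocation_like

_BAND_PART_RE = re.compile(r"^([pq])(\d+)(?:\.\d+)?$")
_BAND_RANGE_RE = re.compile(r"^([pq])(\d+)(?:\.\d+)?-([pq])?(\d+)(?:\.\d+)?$")

DEFAULT_TOLERANCE = 1


@dataclass
class ConcordanceResult:
    matched: bool
    event: StructuralEvent | None = None
    band5: str | None = None
    band3: str | None = None
    band_distance: int | None = None


def gene_to_band(gene: GeneModel, cytobands: CytobandMap) -> str:
    """Cytoband of a gene: the band containing its midpoint, or the band
    with the larger overlap when the gene spans a boundary."""
    entries = cytobands.bands(gene.chrom)
    overlaps = []
    for label, start, end in entries:
        ov = min(end, gene.end) - max(start, gene.start) + 1
        if ov > 0:
            overlaps.append((ov, label, start, end))
    if not overlaps:
        return cytobands.band_at(gene.chrom, (gene.start + gene.end) // 2)
    if len(overlaps) == 1:
        return overlaps[0][1]
    best = max(overlaps, key=lambda t: t[0])
    ties = [o for o in overlaps if o[0] == best[0]]
    if len(ties) > 1:
        mid = (gene.start + gene.end) // 2
        for _, label, start, end in ties:
            if start <= mid <= end:
                return label
    return best[1]


def _majors(band: str) -> tuple[str, list[int]] | None:
    """Arm + candidate major-band integers for a band or band-range label."""
    if m := _BAND_PART_RE.match(band):
        return m.group(1), [int(m.group(2))]
    if m := _BAND_RANGE_RE.match(band):
        arm, lo, arm2, hi = m.group(1), int(m.group(2)), m.group(3), int(m.group(4))
        if arm2 is not None and arm2 != arm:
            return arm, [lo]  # cross-arm range: keep the first arm only
        lo, hi = min(lo, hi), max(lo, hi)
        return arm, list(range(lo, hi + 1))
    return None


def band_distance(event_band: str, gene_band: str) -> int | None:
    """Distance in major bands on the same arm; None when incomparable."""
    a, b = _majors(event_band), _majors(gene_band)
    if a is None or b is None or a[0] != b[0]:
        return None
    return min(abs(x - y) for x in a[1] for y in b[1])


def _pair_match(event: StructuralEvent, chrom5: str, band5: str,
                chrom3: str, band3: str, tolerance: int) -> int | None:
    """Best (max-of-two-sides) band distance pairing the fusion partners to
    the event's chromosome/band columns, or None when no pairing fits."""
    best = None
    n = len(event.chroms)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if (normalize_chrom(event.chroms[i]) != chrom5
                    or normalize_chrom(event.chroms[j]) != chrom3):
                continue
            d5 = band_distance(event.bands[i], band5)
            d3 = band_distance(event.bands[j], band3)
            if d5 is None or d3 is None:
                continue
            d = max(d5, d3)
            if d <= tolerance and (best is None or d < best):
                best = d
    return best


def _inversion_match(event: StructuralEvent, chrom5: str, band5: str,
                     chrom3: str, band3: str, tolerance: int) -> int | None:
    """Inversions match only intrachromosomal fusions whose breakpoints fall
    in the two inversion bands (either assignment)."""
    if chrom5 != chrom3 or len(event.chroms) != 1 or len(event.bands) != 2:
        return None
    if normalize_chrom(event.chroms[0]) != chrom5:
        return None
    best = None
    for ea, eb in ((0, 1), (1, 0)):
        d5 = band_distance(event.bands[ea], band5)
        d3 = band_distance(event.bands[eb], band3)
        if d5 is None or d3 is None:
            continue
        d = max(d5, d3)
        if d <= tolerance and (best is None or d < best):
            best = d
    return best


def match_fusion_to_karyotype(fusion: FusionCandidate, karyotype: Karyotype,
                              cytobands: CytobandMap, genes: GeneModelIndex,
                              tolerance: int = DEFAULT_TOLERANCE,
                              ) -> ConcordanceResult:
    """Tier-1 evidence check: is the fusion explained by a translocation-like
    event in the sample's karyotype (union of all clones)?"""
    g5, g3 = genes.get(fusion.gene5), genes.get(fusion.gene3)
    if g5 is None or g3 is None:
        return ConcordanceResult(matched=False)
    try:
        band5 = g5.band or gene_to_band(g5, cytobands)
        band3 = g3.band or gene_to_band(g3, cytobands)
    except Exception:
        return ConcordanceResult(matched=False)
    chrom5 = normalize_chrom(fusion.chrom5)
    chrom3 = normalize_chrom(fusion.chrom3)

    best: tuple[int, StructuralEvent] | None = None
    for event in extract_translocation_like(karyotype):
        if event.kind == "inversion":
            d = _inversion_match(event, chrom5, band5, chrom3, band3, tolerance)
        else:
            d = _pair_match(event, chrom5, band5, chrom3, band3, tolerance)
            if d is None:  # matching is symmetric under partner swap
                d = _pair_match(event, chrom3, band3, chrom5, band5, tolerance)
        if d is not None and (best is None or d < best[0]):
            best = (d, event)
    if best is None:
        return ConcordanceResult(matched=False, band5=band5, band3=band3)
    return ConcordanceResult(matched=True, event=best[1], band5=band5,
                             band3=band3, band_distance=best[0])
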