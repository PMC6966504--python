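"""Removal cascade applied to merged caller outputs.

Every decision is recorded as a flag on the candidate rather than by
deleting rows, because the tier-3 rescue needs low-driver-score fusions to
survive to tiering.  All flag predicates are independent and idempotent, so
core and cohort filters commute and re-application adds nothing.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .fusion_io import (FusionCandidate, GeneModelIndex, normalize_chrom,
                        normalize_symbol)

#: Closed vocabulary of filter-flag labels.
FLAG_VOCABULARY = frozenset({
    "no_split_reads",
    "unannotated_partner",
    "healthy_panel",
    "unreliable_structure",
    "promiscuous_gene",
    "readthrough",
    "cohort_recurrent",
    "ds_conflict",
})

#: Flags that annotate but do not reject a candidate.
WARNING_FLAGS = frozenset({"ds_conflict"})

#: Recurrently fused genes with many partners, removed outright.
DEFAULT_PROMISCUOUS = frozenset({"HBB", "HBA", "HBD", "MPO", "DLG2"})


@dataclass
class FilterConfig:
    min_split_reads: int = 1
    healthy_panel: set[frozenset] = field(default_factory=set)
    promiscuous_static: frozenset = DEFAULT_PROMISCUOUS
    promiscuous_partner_threshold: int = 3
    readthrough_max_gap: int = 200_000
    ds_threshold: float = 0.7

    def __post_init__(self) -> None:
        if self.min_split_reads < 0 or self.promiscuous_partner_threshold < 0 \
                or self.readthrough_max_gap < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0.0 <= self.ds_threshold <= 1.0:
            raise ValueError("ds_threshold must lie in [0,1]")
        self.promiscuous_static = frozenset(
            normalize_symbol(s) for s in self.promiscuous_static)

    def as_dict(self) -> dict:
        return {
            "min_split_reads": self.min_split_reads,
            "healthy_panel": sorted("|".join(sorted(p))
                                    for p in self.healthy_panel),
            "promiscuous_static": sorted(self.promiscuous_static),
            "promiscuous_partner_threshold": self.promiscuous_partner_threshold,
            "readthrough_max_gap": self.readthrough_max_gap,
            "ds_threshold": self.ds_threshold,
        }


MERGE_BREAKPOINT_TOLERANCE = 10  # bp
DS_CONFLICT_TOLERANCE = 0.05


def _same_event(a: FusionCandidate, b: FusionCandidate) -> bool:
    if a.sample_id != b.sample_id or a.pair != b.pair:
        return False
    direct = (a.chrom5 == b.chrom5 and a.chrom3 == b.chrom3
              and abs(a.pos5 - b.pos5) <= MERGE_BREAKPOINT_TOLERANCE
              and abs(a.pos3 - b.pos3) <= MERGE_BREAKPOINT_TOLERANCE)
    swapped = (a.chrom5 == b.chrom3 and a.chrom3 == b.chrom5
               and abs(a.pos5 - b.pos3) <= MERGE_BREAKPOINT_TOLERANCE
               and abs(a.pos3 - b.pos5) <= MERGE_BREAKPOINT_TOLERANCE)
    return direct or swapped


def merge_callsets(callsets: list[list[FusionCandidate]]) -> list[FusionCandidate]:
    """Merge per-caller candidate lists.

    Candidates describing the same unordered partner pair in the same sample
    with breakpoints within 10 bp collapse into one record keeping the
    maximum read support and any present driver score; the caller set is
    recorded.  Driver scores differing by more than 0.05 raise the warning
    flag ``ds_conflict`` and the maximum is kept.
    """
    groups: dict[tuple, list[FusionCandidate]] = defaultdict(list)
    order: list[tuple] = []
    for callset in callsets:
        for cand in callset:
            key = (cand.sample_id, cand.pair)
            if key not in groups:
                order.append(key)
            groups[key].append(cand)

    merged: list[FusionCandidate] = []
    for key in order:
        clusters: list[FusionCandidate] = []
        for cand in groups[key]:
            home = next((c for c in clusters if _same_event(c, cand)), None)
            if home is None:
                clusters.append(cand)
                continue
            home.split_reads = max(home.split_reads, cand.split_reads)
            home.spanning_reads = max(home.spanning_reads, cand.spanning_reads)
            if cand.driver_score is not None:
                if home.driver_score is not None and \
                        abs(home.driver_score - cand.driver_score) > DS_CONFLICT_TOLERANCE:
                    home.add_flag("ds_conflict")
                home.driver_score = (cand.driver_score
                                     if home.driver_score is None
                                     else max(home.driver_score,
                                              cand.driver_score))
            home.callers |= cand.callers
        merged.extend(clusters)
    merged.sort(key=lambda c: c.key)
    return merged


def _transcribable(cand: FusionCandidate, g5, g3) -> bool:
    """The 5' partner must contribute its transcript prefix, i.e. be read in
    its native direction; an inverted (antisense) 3' suffix is still a
    transcribable chimera."""
    return cand.strand5 == g5.strand


def apply_core_filters(candidates: list[FusionCandidate], cfg: FilterConfig,
                       genes: GeneModelIndex) -> list[FusionCandidate]:
    """Per-candidate filters: split-read support, partner annotation, healthy
    panel and structural reliability.  Never raises on data."""
    for cand in candidates:
        if cand.split_reads < max(cfg.min_split_reads, 1):
            cand.add_flag("no_split_reads")
        if not (cand.annotated5 and cand.annotated3):
            cand.add_flag("unannotated_partner")
        if cand.pair in cfg.healthy_panel:
            cand.add_flag("healthy_panel")
        g5, g3 = genes.get(cand.gene5), genes.get(cand.gene3)
        if g5 is not None and g3 is not None:
            inside = (normalize_chrom(g5.chrom) == normalize_chrom(cand.chrom5)
                      and g5.contains(cand.pos5)
                      and normalize_chrom(g3.chrom) == normalize_chrom(cand.chrom3)
                      and g3.contains(cand.pos3))
            if not inside or not _transcribable(cand, g5, g3):
                cand.add_flag("unreliable_structure")
    return candidates


def _gene_gap(g5, g3) -> int:
    """Distance between two gene spans (0 when they touch or overlap)."""
    if g5.end < g3.start:
        return g3.start - g5.end - 1
    if g3.end < g5.start:
        return g5.start - g3.end - 1
    return 0


def is_readthrough(cand: FusionCandidate, genes: GeneModelIndex,
                   max_gap: int) -> bool:
    """Colinear same-strand neighbours within ``max_gap``: the classic
    conjoined-gene artifact."""
    g5, g3 = genes.get(cand.gene5), genes.get(cand.gene3)
    if g5 is None or g3 is None:
        return False
    if normalize_chrom(g5.chrom) != normalize_chrom(g3.chrom):
        return False
    if g5.strand != g3.strand:
        return False
    # 5' partner upstream of the 3' partner in transcriptional direction.
    if g5.strand == "+":
        colinear = g5.end < g3.start
    else:
        colinear = g3.end < g5.start
    return colinear and _gene_gap(g5, g3) <= max_gap


def apply_cohort_filters(candidates: list[FusionCandidate],
                         cfg: FilterConfig,
                         genes: GeneModelIndex) -> list[FusionCandidate]:
    """Cohort-level filters: promiscuous partners, read-throughs, and pairs
    recurring in more than one sample."""
    partners: dict[str, set[str]] = defaultdict(set)
    pair_samples: dict[frozenset, set[str]] = defaultdict(set)
    for cand in candidates:
        s5, s3 = normalize_symbol(cand.gene5), normalize_symbol(cand.gene3)
        partners[s5].add(s3)
        partners[s3].add(s5)
        pair_samples[cand.pair].add(cand.sample_id)

    k = cfg.promiscuous_partner_threshold
    for cand in candidates:
        s5, s3 = normalize_symbol(cand.gene5), normalize_symbol(cand.gene3)
        if (s5 in cfg.promiscuous_static or s3 in cfg.promiscuous_static
                or len(partners[s5]) >= k or len(partners[s3]) >= k):
            cand.add_flag("promiscuous_gene")
        if is_readthrough(cand, genes, cfg.readthrough_max_gap):
            cand.add_flag("readthrough")
        if len(pair_samples[cand.pair]) >= 2:
            cand.add_flag("cohort_recurrent")
    return candidates
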