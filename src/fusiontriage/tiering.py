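"""Tier assignment (1: cytogenetically concordant; 2: high driver score;
3: out-of-frame tumor-suppressor rescue) and cohort summary statistics."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .concordance import ConcordanceResult
from .consequence import FrameResult, IsoformModel
from .cn_inference import DeletionCall
from .filters import FilterConfig, WARNING_FLAGS
from .fusion_io import FusionCandidate, normalize_symbol

TIERS = ("tier1", "tier2", "tier3", "rejected")

MUTATION_STATES = ("POS", "NEG", "VARIANT", "NA")
VAF_CLASSES = (">0.5", "<0.5", "NA")


@dataclass
class TierReport:
    fusion: FusionCandidate
    tier: str
    concordance: ConcordanceResult | None = None
    frame: FrameResult | None = None
    isoforms: list[IsoformModel] = field(default_factory=list)
    deletion: DeletionCall | None = None
    microhomology: int | None = None
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")


def assign_tier(fusion: FusionCandidate, concordance: ConcordanceResult,
                frame: FrameResult, tsg: set[str], cfg: FilterConfig,
                isoforms: list[IsoformModel] | None = None,
                deletion: DeletionCall | None = None,
                microhomology: int | None = None) -> TierReport:
    """Assign a tier with precedence tier1 > tier2 > tier3 > rejected.

    Any hard filter flag rejects the candidate outright; a candidate with no
    driver score can still reach tier 1 or tier 3 but never tier 2.
    """
    reasons: list[str] = []
    hard_flags = sorted(fusion.flags - WARNING_FLAGS)
    if hard_flags:
        reasons.append("filtered:" + ",".join(hard_flags))
        if concordance.matched:
            # Log the counterfactual: concordant but filter-failing.
            reasons.append("concordant_but_filtered")
        return TierReport(fusion=fusion, tier="rejected",
                          concordance=concordance, frame=frame,
                          isoforms=isoforms or [], deletion=deletion,
                          microhomology=microhomology, reasons=reasons)

    ds = fusion.driver_score
    tsg_norm = {normalize_symbol(g) for g in tsg}
    in_tsg = bool({normalize_symbol(fusion.gene5),
                   normalize_symbol(fusion.gene3)} & tsg_norm)

    if concordance.matched:
        tier = "tier1"
        reasons.append(f"karyotype_concordant:{concordance.event.raw}")
    elif ds is not None and ds >= cfg.ds_threshold:
        tier = "tier2"
        reasons.append(f"driver_score:{ds:g}>={cfg.ds_threshold:g}")
    elif (frame.status == "out_of_frame" and in_tsg
          and (ds is None or ds < cfg.ds_threshold)):
        tier = "tier3"
        reasons.append("tsg_rescue:out_of_frame")
    else:
        tier = "rejected"
        reasons.append("not_concordant")
        if ds is None:
            reasons.append("no_driver_score")
        else:
            reasons.append(f"driver_score:{ds:g}<{cfg.ds_threshold:g}")
        if frame.status != "out_of_frame":
            reasons.append(f"frame:{frame.status}")
        if not in_tsg:
            reasons.append("no_tsg_partner")
    return TierReport(fusion=fusion, tier=tier, concordance=concordance,
                      frame=frame, isoforms=isoforms or [],
                      deletion=deletion, microhomology=microhomology,
                      reasons=reasons)


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------

@dataclass
class PatientRecord:
    sample_id: str
    sex: str
    age: int
    who_class: str
    mutations: dict[str, str] = field(default_factory=dict)  # column -> state
    vaf_classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col, state in self.mutations.items():
            if state not in MUTATION_STATES:
                raise ValueError(f"{self.sample_id}/{col}: bad state {state!r}")


@dataclass
class CohortSummary:
    n: int
    median_age: float
    gene_altered: dict[str, tuple[int, int]]  # gene -> (altered, evaluable)
    itd_alone_high_vaf: int

    def altered_fraction(self, gene: str) -> float:
        altered, evaluable = self.gene_altered.get(gene, (0, 0))
        return altered / evaluable if evaluable else 0.0


def _column_gene(column: str) -> str:
    return column.split("-", 1)[0]


def read_cohort_table(path: str | Path) -> list[PatientRecord]:
    """CSV with sample_id, gender, age, who_class, then one column per
    screened marker (POS/NEG/VARIANT/NA); '*-VAF' columns carry allele
    frequency classes ('>0.5', '<0.5', NA)."""
    records: list[PatientRecord] = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            mutations, vafs = {}, {}
            for col, value in row.items():
                if col in ("sample_id", "gender", "age", "who_class"):
                    continue
                value = (value or "NA").strip().replace(",", ".") or "NA"
                if col.endswith("-VAF"):
                    vafs[col[:-4]] = value if value in VAF_CLASSES else "NA"
                else:
                    mutations[col] = value if value in MUTATION_STATES else "NA"
            records.append(PatientRecord(
                sample_id=row["sample_id"], sex=row.get("gender", ""),
                age=int(row["age"]), who_class=row.get("who_class", ""),
                mutations=mutations, vaf_classes=vafs))
    return records


def cohort_summary(records: list[PatientRecord]) -> CohortSummary:
    """Median age (lower median for even n), per-gene alteration fractions
    (altered = any related column POS; patients with all-NA columns for a
    gene are excluded from that denominator) and the count of patients with
    FLT3-ITD alone (no TKD mutation) at VAF class > 0.5."""
    if not records:
        raise ValueError("empty cohort table")
    ages = sorted(r.age for r in records)
    median_age = ages[(len(ages) - 1) // 2]

    genes = sorted({_column_gene(c) for r in records for c in r.mutations})
    gene_altered: dict[str, tuple[int, int]] = {}
    for gene in genes:
        altered = evaluable = 0
        for r in records:
            states = [s for c, s in r.mutations.items()
                      if _column_gene(c) == gene]
            if not states or all(s == "NA" for s in states):
                continue
            evaluable += 1
            if any(s == "POS" for s in states):
                altered += 1
        gene_altered[gene] = (altered, evaluable)

    itd_alone = 0
    for r in records:
        itd = r.mutations.get("FLT3-ITD", "NA")
        tkd = r.mutations.get("FLT3-TKD", "NA")
        vaf = r.vaf_classes.get("FLT3-ITD", "NA")
        if itd == "POS" and tkd != "POS" and vaf == ">0.5":
            itd_alone += 1

    return CohortSummary(n=len(records), median_age=median_age,
                         gene_altered=gene_altered,
                         itd_alone_high_vaf=itd_alone)
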