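"""Input/output layer: fusion candidate tables, GTF gene models, cytobands,
gene lists and the final report files.

All internal coordinates are 1-based inclusive on the forward genomic
strand.  ``pos5`` is the last retained base of the 5' partner and ``pos3``
the first retained base of the 3' partner, both in forward-genome
coordinates regardless of gene strand.
"""

from __future__ import annotations

import csv
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gffutils

from .errors import CytobandMapError, FormatError, GeneModelError, LookupError_

CHIMERASCAN_COLUMNS = [
    "sample_id", "gene5", "gene3", "chrom5", "pos5", "strand5",
    "chrom3", "pos3", "strand3", "split_reads", "spanning_reads",
    "driver_score",
]

DEFUSE_COLUMNS = [
    "cluster_id", "sample_id", "gene_name1", "gene_name2",
    "chromosome1", "genomic_break_pos1", "genomic_strand1",
    "chromosome2", "genomic_break_pos2", "genomic_strand2",
    "splitr_count", "span_count", "probability",
]

_BAND_RE = re.compile(r"^[pq]\d+(\.\d+)?$")


def normalize_chrom(name: str) -> str:
    """Strip a leading 'chr' prefix so GTF/cytoband/ISCN names agree."""
    return name[3:] if name.lower().startswith("chr") else name


def normalize_symbol(symbol: str) -> str:
    """Case-fold a gene symbol and drop a trailing '.N' version suffix."""
    return re.sub(r"\.\d+$", "", symbol.strip()).upper()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FusionCandidate:
    """One caller-reported chimeric junction."""

    sample_id: str
    gene5: str
    gene3: str
    chrom5: str
    pos5: int
    strand5: str
    chrom3: str
    pos3: int
    strand3: str
    split_reads: int
    spanning_reads: int
    driver_score: float | None = None
    caller: str = "other"
    annotated5: bool = False
    annotated3: bool = False
    flags: set[str] = field(default_factory=set)
    callers: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.pos5 < 1 or self.pos3 < 1:
            raise ValueError(f"positions must be >= 1: {self.pos5}, {self.pos3}")
        if self.split_reads < 0 or self.spanning_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.driver_score is not None and not 0.0 <= self.driver_score <= 1.0:
            raise ValueError(f"driver_score {self.driver_score} outside [0,1]")
        if not self.callers:
            self.callers = {self.caller}

    @property
    def pair(self) -> frozenset:
        return frozenset((normalize_symbol(self.gene5), normalize_symbol(self.gene3)))

    @property
    def key(self) -> tuple:
        return (self.sample_id, self.gene5, self.gene3,
                self.chrom5, self.pos5, self.chrom3, self.pos3)

    def add_flag(self, label: str) -> None:
        from .filters import FLAG_VOCABULARY  # closed vocabulary lives there

        if label not in FLAG_VOCABULARY:
            raise ValueError(f"unknown filter flag {label!r}")
        self.flags.add(label)

    @property
    def passing(self) -> bool:
        from .filters import WARNING_FLAGS

        return not (self.flags - WARNING_FLAGS)


@dataclass
class GeneModel:
    """Exon/CDS structure of one transcript.

    ``exons`` are 1-based inclusive genomic intervals listed in
    transcription order (ascending coordinates on '+', descending on '-').
    ``cds_start``/``cds_end`` are the genomic (forward-strand) bounds of the
    coding region, or None for non-coding transcripts.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None
    band: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise GeneModelError(f"{self.transcript_id}: no exons")
        order = sorted(self.exons)
        for (a1, b1), (a2, _) in zip(order, order[1:]):
            if a2 <= b1:
                raise GeneModelError(f"{self.transcript_id}: overlapping exons")
        expected = order if self.strand == "+" else order[::-1]
        if list(self.exons) != expected:
            raise GeneModelError(
                f"{self.transcript_id}: exons not in transcription order")
        if (self.cds_start is None) != (self.cds_end is None):
            raise GeneModelError(f"{self.transcript_id}: half-open CDS bounds")
        if self.cds_start is not None:
            if not any(a <= self.cds_start <= b for a, b in self.exons) or \
               not any(a <= self.cds_end <= b for a, b in self.exons):
                raise GeneModelError(
                    f"{self.transcript_id}: CDS bounds outside exons")

    @property
    def start(self) -> int:
        return min(a for a, _ in self.exons)

    @property
    def end(self) -> int:
        return max(b for _, b in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def exonic(self, pos: int) -> bool:
        return any(a <= pos <= b for a, b in self.exons)

    def exon_index_of(self, pos: int) -> int | None:
        """0-based exon index in transcription order, or None if intronic."""
        for i, (a, b) in enumerate(self.exons):
            if a <= pos <= b:
                return i
        return None

    def cds_intervals(self) -> list[tuple[int, int]]:
        """Genomic CDS pieces (exon ∩ CDS bounds), in transcription order."""
        if not self.is_coding:
            return []
        lo, hi = min(self.cds_start, self.cds_end), max(self.cds_start, self.cds_end)
        out = []
        for a, b in self.exons:
            s, e = max(a, lo), min(b, hi)
            if s <= e:
                out.append((s, e))
        return out

    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds_intervals())

    def coding_bases_upstream(self, pos: int, *, inclusive: bool) -> int:
        """Number of CDS bases transcriptionally at/5' of ``pos``.

        With ``inclusive`` the base at ``pos`` counts when it is coding
        (donor-side arithmetic); without, only bases strictly upstream count
        (acceptor-side arithmetic).
        """
        total = 0
        for a, b in self.cds_intervals():
            if self.strand == "+":
                cut = pos if inclusive else pos - 1
                s, e = a, min(b, cut)
            else:
                cut = pos if inclusive else pos + 1
                s, e = max(a, cut), b
            if s <= e:
                total += e - s + 1
        return total

    def tx_cmp(self, a: int, b: int) -> int:
        """-1/0/+1 if genomic position ``a`` is transcriptionally before /
        equal to / after ``b``."""
        d = (a - b) if self.strand == "+" else (b - a)
        return (d > 0) - (d < 0)

    def cds_tx_start(self) -> int | None:
        """Genomic coordinate of the first coding base in transcription order."""
        if not self.is_coding:
            return None
        pieces = self.cds_intervals()
        return pieces[0][0] if self.strand == "+" else pieces[0][1]

    def exon_tx_start(self, index: int) -> int:
        """Genomic coordinate of the transcriptionally first base of an exon."""
        a, b = self.exons[index]
        return a if self.strand == "+" else b


class CytobandMap:
    """Per-chromosome ordered cytogenetic bands, 1-based inclusive."""

    def __init__(self, bands: dict[str, list[tuple[str, int, int]]]):
        self._bands: dict[str, list[tuple[str, int, int]]] = {}
        self._spelling: dict[str, str] = {
            normalize_chrom(c): c for c in bands}
        for chrom, entries in bands.items():
            entries = sorted(entries, key=lambda t: t[1])
            prev_end = 0
            for label, start, end in entries:
                if start != prev_end + 1:
                    raise CytobandMapError(
                        f"{chrom}: band {label} starts at {start}, "
                        f"expected {prev_end + 1}")
                if end < start:
                    raise CytobandMapError(f"{chrom}:{label} empty interval")
                if not _BAND_RE.match(label):
                    raise CytobandMapError(f"{chrom}: bad band label {label!r}")
                prev_end = end
            self._bands[normalize_chrom(chrom)] = entries

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._bands)

    def spelling(self, chrom: str) -> str:
        """Chromosome name as spelled in the source file."""
        return self._spelling.get(normalize_chrom(chrom), chrom)

    def bands(self, chrom: str) -> list[tuple[str, int, int]]:
        chrom = normalize_chrom(chrom)
        if chrom not in self._bands:
            raise LookupError_(f"chromosome {chrom!r} absent from cytoband map")
        return list(self._bands[chrom])

    def band_at(self, chrom: str, pos: int) -> str:
        entries = self.bands(chrom)
        starts = [s for _, s, _ in entries]
        i = bisect_right(starts, pos) - 1
        if i < 0 or pos > entries[i][2]:
            raise LookupError_(f"position {chrom}:{pos} outside mapped bands")
        return entries[i][0]


# ---------------------------------------------------------------------------
# Gene-model index
# ---------------------------------------------------------------------------

class GeneModelIndex:
    """Transcript models indexed by gene symbol and by genomic interval."""

    def __init__(self, models: Iterable[GeneModel]):
        self._by_symbol: dict[str, list[GeneModel]] = {}
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for m in models:
            self._by_symbol.setdefault(normalize_symbol(m.gene_id), []).append(m)
            self._by_chrom.setdefault(normalize_chrom(m.chrom), []).append(m)
        self._starts: dict[str, list[int]] = {}
        self._maxend: dict[str, list[int]] = {}
        for chrom, ms in self._by_chrom.items():
            ms.sort(key=lambda m: (m.start, m.end, m.transcript_id))
            self._starts[chrom] = [m.start for m in ms]
            running, acc = 0, []
            for m in ms:
                running = max(running, m.end)
                acc.append(running)
            self._maxend[chrom] = acc

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_symbol.values())

    def __iter__(self) -> Iterator[GeneModel]:
        for ms in self._by_chrom.values():
            yield from ms

    def symbols(self) -> list[str]:
        return sorted(self._by_symbol)

    def by_symbol(self, symbol: str) -> list[GeneModel]:
        return list(self._by_symbol.get(normalize_symbol(symbol), []))

    def get(self, symbol: str) -> GeneModel | None:
        """Canonical model for a symbol: longest CDS, then longest span."""
        models = self.by_symbol(symbol)
        if not models:
            return None
        return max(models, key=lambda m: (m.cds_length(), m.end - m.start,
                                          m.transcript_id))

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        """Transcripts whose span intersects [start, end] on ``chrom``."""
        chrom = normalize_chrom(chrom)
        ms = self._by_chrom.get(chrom, [])
        if not ms:
            return []
        hi = bisect_right(self._starts[chrom], end)
        out = []
        for i in range(hi - 1, -1, -1):
            if self._maxend[chrom][i] < start:
                break
            if ms[i].end >= start:
                out.append(ms[i])
        out.reverse()
        return out

    def assign_bands(self, cytobands: CytobandMap) -> None:
        from .concordance import gene_to_band

        for m in self:
            try:
                m.band = gene_to_band(m, cytobands)
            except LookupError_:
                m.band = None


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _parse_float(text: str) -> float | None:
    text = text.strip()
    if text in ("", ".", "NA", "nan"):
        return None
    return float(text)


def read_fusion_table(path: str | Path, dialect: str) -> list[FusionCandidate]:
    """Read a fusion-candidate TSV in the 'chimerascan' or 'defuse' dialect."""
    if dialect not in ("chimerascan", "defuse"):
        raise ValueError(f"unknown dialect {dialect!r}")
    expected = CHIMERASCAN_COLUMNS if dialect == "chimerascan" else DEFUSE_COLUMNS
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        missing = [c for c in expected if c not in header]
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s) "
                              f"{', '.join(missing)} for dialect {dialect}")
        idx = {c: header.index(c) for c in expected}
        out: list[FusionCandidate] = []
        seen_defuse: set[tuple] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                if dialect == "chimerascan":
                    cand = FusionCandidate(
                        sample_id=row[idx["sample_id"]],
                        gene5=row[idx["gene5"]], gene3=row[idx["gene3"]],
                        chrom5=row[idx["chrom5"]],
                        pos5=int(row[idx["pos5"]]),
                        strand5=row[idx["strand5"]],
                        chrom3=row[idx["chrom3"]],
                        pos3=int(row[idx["pos3"]]),
                        strand3=row[idx["strand3"]],
                        split_reads=int(row[idx["split_reads"]]),
                        spanning_reads=int(row[idx["spanning_reads"]]),
                        driver_score=_parse_float(row[idx["driver_score"]]),
                        caller="chimerascan",
                    )
                else:
                    cand = FusionCandidate(
                        sample_id=row[idx["sample_id"]],
                        gene5=row[idx["gene_name1"]],
                        gene3=row[idx["gene_name2"]],
                        chrom5=row[idx["chromosome1"]],
                        pos5=int(row[idx["genomic_break_pos1"]]),
                        strand5=row[idx["genomic_strand1"]],
                        chrom3=row[idx["chromosome2"]],
                        pos3=int(row[idx["genomic_break_pos2"]]),
                        strand3=row[idx["genomic_strand2"]],
                        split_reads=int(row[idx["splitr_count"]]),
                        spanning_reads=int(row[idx["span_count"]]),
                        driver_score=_parse_float(row[idx["probability"]]),
                        caller="defuse",
                    )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if dialect == "defuse":
                # deFuse reports both orientations of one event; deduplicate
                # by unordered partner pair + positions.
                dedup = (cand.sample_id, cand.pair,
                         frozenset(((cand.chrom5, cand.pos5),
                                    (cand.chrom3, cand.pos3))))
                if dedup in seen_defuse:
                    continue
                seen_defuse.add(dedup)
            out.append(cand)
    return out


def write_fusion_table(candidates: Iterable[FusionCandidate],
                       path: str | Path) -> None:
    """Write candidates in the chimerascan dialect (canonical form)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CHIMERASCAN_COLUMNS)
        for c in sorted(candidates, key=lambda c: c.key):
            writer.writerow([
                c.sample_id, c.gene5, c.gene3, c.chrom5, c.pos5, c.strand5,
                c.chrom3, c.pos3, c.strand3, c.split_reads, c.spanning_reads,
                "" if c.driver_score is None else f"{c.driver_score:g}",
            ])


def read_gene_models(path: str | Path) -> GeneModelIndex:
    """Parse a GTF of exon and CDS features into an indexed model set.

    Both Ensembl-style (gene_name) and RefSeq-style (gene_id only)
    attribute conventions are accepted.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            raise GeneModelError(f"{path}: feature without transcript_id")
        gene = (feat.attributes.get("gene_name", [None])[0]
                or feat.attributes.get("gene_id", [None])[0] or tid)
        meta.setdefault(tid, (gene, feat.seqid, feat.strand))
        target = exons if feat.featuretype == "exon" else cds
        target.setdefault(tid, []).append((feat.start, feat.end))

    models = []
    for tid, (gene, chrom, strand) in meta.items():
        ex = sorted(exons.get(tid, []))
        if not ex:
            raise GeneModelError(f"transcript {tid}: CDS without exons")
        cds_start = cds_end = None
        if tid in cds:
            pieces = sorted(cds[tid])
            cds_start = pieces[0][0]
            cds_end = pieces[-1][1]
            for a, b in pieces:
                if not any(ea <= a and b <= eb for ea, eb in ex):
                    raise GeneModelError(
                        f"transcript {tid}: CDS [{a},{b}] outside exons")
        if strand == "-":
            ex = ex[::-1]
        models.append(GeneModel(gene_id=gene, transcript_id=tid, chrom=chrom,
                                strand=strand, exons=ex,
                                cds_start=cds_start, cds_end=cds_end))
    models.sort(key=lambda m: (normalize_chrom(m.chrom), m.start, m.transcript_id))
    return GeneModelIndex(models)


def read_cytobands(path: str | Path) -> CytobandMap:
    """Read a UCSC cytoBand.txt table (0-based half-open starts) and convert
    to 1-based inclusive coordinates."""
    bands: dict[str, list[tuple[str, int, int]]] = {}
    with Path(path).open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 columns")
            chrom, start, end, label = row[0], int(row[1]), int(row[2]), row[3]
            bands.setdefault(chrom, []).append((label, start + 1, end))
    return CytobandMap(bands)


def write_cytobands(cytobands: CytobandMap, path: str | Path) -> None:
    """Write back to the UCSC dialect (involutive with read_cytobands)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for chrom in cytobands.chromosomes:
            for label, start, end in cytobands.bands(chrom):
                writer.writerow([cytobands.spelling(chrom), start - 1, end,
                                 label, "gneg"])


def read_karyotype_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV: sample_id, ISCN string."""
    out: dict[str, str] = {}
    with Path(path).open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#") or row[0] == "sample_id":
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            out[row[0]] = row[1]
    return out


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(normalize_symbol(line))
    return out


def read_healthy_panel(path: str | Path) -> set[frozenset]:
    """TSV of unordered gene pairs seen in healthy samples."""
    out = set()
    with Path(path).open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#") or row[0] == "geneA":
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            out.add(frozenset((normalize_symbol(row[0]),
                               normalize_symbol(row[1]))))
    return out


def read_cn_segments(path: str | Path) -> list[tuple[str, int, int, float]]:
    """4-column TSV: chrom, start, end, copy_number (1-based inclusive)."""
    out = []
    with Path(path).open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#") or row[0] == "chrom":
                continue
            if len(row) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            start, end = int(row[1]), int(row[2])
            if start > end:
                raise ValueError(f"{path}:{lineno}: start > end")
            out.append((row[0], start, end, float(row[3])))
    return out


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "sample_id", "gene5", "gene3", "tier", "concordant_event", "frame",
    "n_isoforms", "microhomology", "deletion_interval", "driver_score",
    "flags", "reasons",
]


def write_report(reports: list, path: str | Path) -> None:
    """Write the tier report TSV plus a BEDPE companion of surviving fusions.

    Row order is canonical (sample_id, then gene5-gene3 lexicographic) so the
    output is byte-identical for any input ordering.
    """
    path = Path(path)
    ordered = sorted(reports, key=lambda r: (r.fusion.sample_id,
                                             r.fusion.gene5, r.fusion.gene3,
                                             r.fusion.key))
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REPORT_COLUMNS)
        for r in ordered:
            f = r.fusion
            writer.writerow([
                f.sample_id, f.gene5, f.gene3, r.tier,
                r.concordance.event.raw if (r.concordance and
                                            r.concordance.event) else "",
                r.frame.status if r.frame else "",
                len(r.isoforms),
                "" if r.microhomology is None else r.microhomology,
                (f"{r.deletion.chrom}:{r.deletion.start}-{r.deletion.end}"
                 if r.deletion else ""),
                "" if f.driver_score is None else f"{f.driver_score:g}",
                ";".join(sorted(f.flags)),
                ";".join(r.reasons),
            ])
    bedpe = path.with_suffix(".bedpe")
    with bedpe.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["#chrom5", "start5", "end5", "chrom3", "start3",
                         "end3", "name", "score", "strand5", "strand3"])
        for r in ordered:
            if r.tier == "rejected":
                continue
            f = r.fusion
            writer.writerow([
                f.chrom5, f.pos5 - 1, f.pos5, f.chrom3, f.pos3 - 1, f.pos3,
                f"{f.sample_id}:{f.gene5}-{f.gene3}", ".",
                f.strand5, f.strand3,
            ])


def annotate_partners(candidates: Iterable[FusionCandidate],
                      genes: GeneModelIndex) -> None:
    """Resolve annotated5/annotated3 against the gene-model index.

    Unknown symbols set the flag to False rather than raising; unannotated
    partners are a filter criterion, not an input error.
    """
    for c in candidates:
        c.annotated5 = genes.get(c.gene5) is not None
        c.annotated3 = genes.get(c.gene3) is not None
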