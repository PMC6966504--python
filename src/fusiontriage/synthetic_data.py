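"""Self-contained cohort generation with planted ground truth, plus a
deterministic fixture bundle encoding the published worked examples.

Everything is emitted as plain text (FASTA, GTF, UCSC-dialect cytobands,
TSV/CSV, YAML, JSON) so a bundle can be rebuilt byte-for-byte from a seed.
The generator deliberately writes cytobands in the 0-based UCSC dialect to
exercise the coordinate-conversion path in the reader.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import GeneratorConfigError
from .fusion_io import FusionCandidate, GeneModel, write_fusion_table

CATEGORIES = ("tier1", "tier2", "tier3", "readthrough_artifact",
              "promiscuous_artifact", "healthy_panel", "no_split_support",
              "unreliable", "cohort_recurrent")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

BUNDLE_FILES = {
    "genome": "genome.fa",
    "gtf": "genes.gtf",
    "cytobands": "cytobands.txt",
    "karyotypes": "karyotypes.tsv",
    "chimerascan": "fusions_chimerascan.tsv",
    "defuse": "fusions_defuse.tsv",
    "healthy_panel": "healthy_panel.tsv",
    "tsg": "tsg.txt",
    "cn_segments": "cn_segments.tsv",
    "cohort": "cohort.csv",
    "config": "config.yaml",
    "truth": "truth.json",
}


@dataclass
class TruthRecord:
    fusion_id: str
    sample_id: str
    gene5: str
    gene3: str
    category: str
    frame: str | None = None
    microhomology: int | None = None
    deletion: dict | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown truth category {self.category!r}")


@dataclass
class GeneratorConfig:
    n_samples: int = 4
    n_contigs: int = 4
    contig_length: int = 200_000
    genes_per_contig: int = 10
    gene_length: int = 8_000
    slot_spacing: int = 12_000
    readthrough_max_gap: int = 20_000
    microhomology_max: int = 6
    category_counts: dict = field(
        default_factory=lambda: {**{c: 1 for c in CATEGORIES}, "tier2": 2})


# ---------------------------------------------------------------------------
# Small sequence/gene helpers
# ---------------------------------------------------------------------------

def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _make_gene(symbol: str, chrom: str, start: int, strand: str) -> GeneModel:
    """A 3-exon coding gene on a fixed internal layout (~8 kb span,
    3900 nt CDS)."""
    rel_exons = [(0, 1499), (3000, 4499), (6500, 7999)]
    exons = [(start + a, start + b) for a, b in rel_exons]
    cds_lo = exons[0][0] + 300
    cds_hi = exons[2][1] - 300
    if strand == "-":
        exons = exons[::-1]
    return GeneModel(gene_id=symbol, transcript_id=f"{symbol}-T1", chrom=chrom,
                     strand=strand, exons=exons, cds_start=cds_lo,
                     cds_end=cds_hi)


def pos_at_coding_offset(gene: GeneModel, offset: int) -> int:
    """Genomic position of the ``offset``-th coding base (1-based) in
    transcription order."""
    if offset < 1 or offset > gene.cds_length():
        raise ValueError(f"coding offset {offset} outside CDS")
    acc = 0
    for a, b in gene.cds_intervals():
        length = b - a + 1
        if acc + length >= offset:
            i = offset - acc
            return a + i - 1 if gene.strand == "+" else b - i + 1
        acc += length
    raise AssertionError("unreachable")


def donor_breakpoint(gene: GeneModel, c5: int) -> int:
    """Breakpoint such that ``c5`` coding bases are retained (inclusive)."""
    return pos_at_coding_offset(gene, c5)


def acceptor_breakpoint(gene: GeneModel, s3: int) -> int:
    """Breakpoint such that ``s3`` coding bases lie strictly upstream."""
    return pos_at_coding_offset(gene, s3 + 1)


def _donor_window(pos5: int, strand: str, k: int) -> list[int]:
    """Genomic positions of the k fused-orientation bases ending at the
    junction, 5'->3'."""
    if strand == "+":
        return list(range(pos5 - k + 1, pos5 + 1))
    return list(range(pos5 + k - 1, pos5 - 1, -1))


def _acceptor_pre_window(pos3: int, strand: str, k: int) -> list[int]:
    """Genomic positions of the k bases immediately 5' of the acceptor
    junction in fused orientation."""
    if strand == "+":
        return list(range(pos3 - k, pos3))
    return list(range(pos3 + k, pos3, -1))


def _write_window(contig: bytearray, positions: list[int], strand: str,
                  text: str) -> None:
    for p, base in zip(positions, text):
        if strand == "-":
            base = base.translate(_COMPLEMENT)
        contig[p - 1] = ord(base)


def _plant_microhomology(contigs: dict[str, bytearray],
                         fusion: FusionCandidate, h: int,
                         rng: random.Random) -> None:
    """Edit the genome so the junction microhomology is exactly ``h``."""
    c5 = contigs[fusion.chrom5]
    c3 = contigs[fusion.chrom3]
    if h > 0:
        homology = "".join(rng.choice("ACGT") for _ in range(h))
        _write_window(c5, _donor_window(fusion.pos5, fusion.strand5, h),
                      fusion.strand5, homology)
        _write_window(c3, _acceptor_pre_window(fusion.pos3, fusion.strand3, h),
                      fusion.strand3, homology)
    # Force a mismatch at h+1 so the homology cannot extend.
    dpos = _donor_window(fusion.pos5, fusion.strand5, h + 1)[0]
    apos = _acceptor_pre_window(fusion.pos3, fusion.strand3, h + 1)[0]
    _write_window(c5, [dpos], fusion.strand5, "A")
    _write_window(c3, [apos], fusion.strand3, "C")


# ---------------------------------------------------------------------------
# Emission helpers
# ---------------------------------------------------------------------------

def _write_fasta(contigs: dict[str, bytearray], path: Path) -> None:
    with path.open("w") as fh:
        for name in contigs:
            fh.write(f">{name}\n")
            seq = contigs[name].decode()
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def write_gtf(genes: list[GeneModel], path: Path) -> None:
    with path.open("w") as fh:
        for g in genes:
            attrs = (f'gene_id "{g.gene_id}"; gene_name "{g.gene_id}"; '
                     f'transcript_id "{g.transcript_id}";')
            for a, b in sorted(g.exons):
                fh.write(f"{g.chrom}\tsynthetic\texon\t{a}\t{b}\t.\t"
                         f"{g.strand}\t.\t{attrs}\n")
            for a, b in sorted(g.cds_intervals()):
                fh.write(f"{g.chrom}\tsynthetic\tCDS\t{a}\t{b}\t.\t"
                         f"{g.strand}\t0\t{attrs}\n")


def _write_cytobands_ucsc(bands: dict[str, list[tuple[str, int, int]]],
                          path: Path) -> None:
    """``bands`` carries 1-based inclusive coordinates; emit 0-based
    half-open UCSC rows."""
    with path.open("w") as fh:
        for chrom, entries in bands.items():
            for label, start, end in entries:
                fh.write(f"{chrom}\t{start - 1}\t{end}\t{label}\tgneg\n")


def _write_tsv(rows: list[list], path: Path, header: list[str] | None = None) -> None:
    with path.open("w") as fh:
        if header:
            fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _band_of(bands: dict, chrom: str, pos: int) -> str:
    for label, start, end in bands[chrom]:
        if start <= pos <= end:
            return label
    raise AssertionError(f"{chrom}:{pos} outside synthetic bands")


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

def generate_cohort(seed: int, n_samples: int = 4,
                    params: GeneratorConfig | None = None,
                    out_dir: str | Path = ".") -> tuple[dict, dict]:
    """Generate a cohort bundle with planted ground truth.

    Returns ``(paths, truth)`` where ``paths`` maps logical names to files
    under ``out_dir`` and ``truth`` is the parsed truth JSON.  Deterministic
    for a fixed seed.
    """
    cfg = params or GeneratorConfig()
    cfg.n_samples = n_samples
    if n_samples < 1:
        raise GeneratorConfigError("n_samples must be >= 1")
    counts = dict(cfg.category_counts)
    if counts.get("cohort_recurrent", 0) and n_samples < 2:
        raise GeneratorConfigError(
            "cohort_recurrent events need at least two samples")
    needed_slots = cfg.genes_per_contig * cfg.slot_spacing + 10_000
    if needed_slots > cfg.contig_length:
        raise GeneratorConfigError(
            f"{cfg.genes_per_contig} genes do not fit in a "
            f"{cfg.contig_length} bp contig")
    for cat in counts:
        if cat not in CATEGORIES:
            raise GeneratorConfigError(f"unknown category {cat!r}")

    rng = random.Random(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    contig_names = [f"chr{i + 1}" for i in range(cfg.n_contigs)]
    contigs = {
        name: bytearray("".join(rng.choice("ACGT")
                                for _ in range(cfg.contig_length)).encode())
        for name in contig_names
    }

    quarter = cfg.contig_length // 4
    bands = {
        name: [("p11", 1, quarter),
               ("q11", quarter + 1, 2 * quarter),
               ("q21", 2 * quarter + 1, 3 * quarter),
               ("q22", 3 * quarter + 1, cfg.contig_length)]
        for name in contig_names
    }

    # Regular '+'-strand genes on a slot grid; chr4 reserves its upper half
    # for the flanking-gene trio used by the deletion branch.
    genes: list[GeneModel] = []
    pools: dict[str, list[GeneModel]] = {name: [] for name in contig_names}
    for ci, name in enumerate(contig_names):
        n_here = cfg.genes_per_contig if name != "chr4" else 4
        for gi in range(n_here):
            start = 10_000 + gi * cfg.slot_spacing
            sym = f"GENE{ci + 1:d}{gi + 1:02d}"
            g = _make_gene(sym, name, start, "+")
            genes.append(g)
            pools[name].append(g)
    mpo = _make_gene("MPO", "chr3", 10_000 + cfg.genes_per_contig *
                     cfg.slot_spacing, "+")
    genes.append(mpo)
    flk_a = _make_gene("FLKA", "chr4", 120_000, "-")
    nf1_like = _make_gene("NF1L", "chr4", 90_000, "+")
    flk_b = _make_gene("FLKB", "chr4", 60_000, "-")
    genes.extend([flk_a, nf1_like, flk_b])

    taken: dict[str, int] = {name: 0 for name in contig_names}

    def next_gene(chrom: str) -> GeneModel:
        i = taken[chrom]
        if i >= len(pools[chrom]):
            raise GeneratorConfigError(f"gene pool exhausted on {chrom}")
        taken[chrom] += 1
        return pools[chrom][i]

    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    sample_sex = {s: rng.choice(["XX", "XY"]) for s in samples}
    karyotype_events: dict[str, list[str]] = {s: [] for s in samples}

    candidates: list[FusionCandidate] = []
    truth_records: list[TruthRecord] = []
    mh_plants: list[tuple[FusionCandidate, int]] = []

    def reads() -> tuple[int, int]:
        return rng.randint(5, 50), rng.randint(2, 30)

    def breakpoints(g5: GeneModel, g3: GeneModel,
                    in_frame: bool) -> tuple[int, int, str]:
        c5 = 3 * rng.randint(50, 200)
        s3 = 3 * rng.randint(10, 100)
        if not in_frame:
            c5 += rng.randint(1, 2)
        frame = "in_frame" if c5 % 3 == s3 % 3 else "out_of_frame"
        return donor_breakpoint(g5, c5), acceptor_breakpoint(g3, s3), frame

    def add(sample: str, g5: GeneModel, g3: GeneModel, category: str,
            pos5: int, pos3: int, split: int, spanning: int,
            ds: float | None, frame: str | None = None,
            mh: int | None = None, deletion: dict | None = None) -> FusionCandidate:
        cand = FusionCandidate(
            sample_id=sample, gene5=g5.gene_id, gene3=g3.gene_id,
            chrom5=g5.chrom, pos5=pos5, strand5=g5.strand,
            chrom3=g3.chrom, pos3=pos3, strand3=g3.strand,
            split_reads=split, spanning_reads=spanning, driver_score=ds,
            caller="chimerascan")
        candidates.append(cand)
        truth_records.append(TruthRecord(
            fusion_id=f"{sample}:{g5.gene_id}-{g3.gene_id}",
            sample_id=sample, gene5=g5.gene_id, gene3=g3.gene_id,
            category=category, frame=frame, microhomology=mh,
            deletion=deletion))
        if mh is not None:
            mh_plants.append((cand, mh))
        return cand

    sample_cycle = {cat: i for i, cat in enumerate(CATEGORIES)}

    for cat in CATEGORIES:
        for rep in range(counts.get(cat, 0)):
            sample = samples[(sample_cycle[cat] + rep) % n_samples]
            split, spanning = reads()
            mh = rng.randint(0, cfg.microhomology_max)
            if cat == "tier1":
                g5, g3 = next_gene("chr1"), next_gene("chr2")
                pos5, pos3, frame = breakpoints(g5, g3, rng.random() < 0.5)
                add(sample, g5, g3, cat, pos5, pos3, split, spanning,
                    ds=round(rng.uniform(0.0, 1.0), 4), frame=frame, mh=mh)
                b5 = _band_of(bands, g5.chrom, (g5.start + g5.end) // 2)
                b3 = _band_of(bands, g3.chrom, (g3.start + g3.end) // 2)
                c5n, c3n = g5.chrom[3:], g3.chrom[3:]
                karyotype_events[sample].append(
                    f"t({c5n};{c3n})({b5};{b3})")
            elif cat == "tier2":
                # One exact-threshold plant per cohort pins the >= rule.
                exact = rep == 0
                chroms = ("chr2", "chr3") if rep % 2 == 0 else ("chr3", "chr1")
                g5, g3 = next_gene(chroms[0]), next_gene(chroms[1])
                pos5, pos3, frame = breakpoints(g5, g3, True)
                ds = 0.7 if exact else round(rng.uniform(0.7, 1.0), 4)
                add(sample, g5, g3, cat, pos5, pos3, split, spanning,
                    ds=ds, frame=frame, mh=mh)
            elif cat == "tier3":
                g5, g3 = flk_a, flk_b
                pos5, pos3, frame = breakpoints(g5, g3, False)
                deletion = {"chrom": "4", "start": pos3 + 1, "end": pos5 - 1}
                add(sample, g5, g3, cat, pos5, pos3, split, spanning,
                    ds=round(rng.uniform(0.0, 0.69), 4), frame=frame, mh=mh,
                    deletion=deletion)
            elif cat == "readthrough_artifact":
                g5, g3 = next_gene("chr3"), next_gene("chr3")
                pos5, pos3, _ = breakpoints(g5, g3, True)
                add(sample, g5, g3, cat, pos5, pos3, split, spanning,
                    ds=round(rng.uniform(0.0, 1.0), 4))
            elif cat == "promiscuous_artifact":
                g5, g3 = mpo, next_gene("chr1")
                pos5, pos3, _ = breakpoints(g5, g3, True)
                add(sample, g5, g3, cat, pos5, pos3, split, spanning,
                    ds=round(rng.uniform(0.0, 1.0), 4))
            elif cat == "healthy_panel":
                g5, g3 = next_gene("chr1"), next_gene("chr4")
                pos5, pos3, _ = breakpoints(g5, g3, True)
                add(sample, g5, g3, cat, pos5, pos3, split, spanning,
                    ds=round(rng.uniform(0.0, 1.0), 4))
            elif cat == "no_split_support":
                g5, g3 = next_gene("chr2"), next_gene("chr4")
                pos5, pos3, _ = breakpoints(g5, g3, True)
                add(sample, g5, g3, cat, pos5, pos3, 0, spanning,
                    ds=round(rng.uniform(0.0, 1.0), 4))
            elif cat == "unreliable":
                g5, g3 = next_gene("chr1"), next_gene("chr2")
                _, pos3, _ = breakpoints(g5, g3, True)
                pos5 = g5.end + 5_000  # outside the donor span
                add(sample, g5, g3, cat, pos5, pos3, split, spanning,
                    ds=round(rng.uniform(0.0, 1.0), 4))
            elif cat == "cohort_recurrent":
                g5, g3 = next_gene("chr1"), next_gene("chr3")
                pos5, pos3, _ = breakpoints(g5, g3, True)
                other = samples[(sample_cycle[cat] + rep + 1) % n_samples]
                for s in (sample, other):
                    add(s, g5, g3, cat, pos5, pos3, split, spanning,
                        ds=round(rng.uniform(0.0, 1.0), 4))

    healthy_pairs = [(tr.gene5, tr.gene3) for tr in truth_records
                     if tr.category == "healthy_panel"]

    for cand, h in mh_plants:
        _plant_microhomology(contigs, cand, h, rng)

    # Caller tables: everything in the chimerascan dialect; every other
    # candidate duplicated into the deFuse dialect with jittered breakpoints
    # to exercise the merge.
    paths = {k: out_dir / v for k, v in BUNDLE_FILES.items()}
    write_fusion_table(candidates, paths["chimerascan"])
    defuse_rows = []
    for i, c in enumerate(sorted(candidates, key=lambda c: c.key)):
        if i % 2 == 1:
            continue
        jitter = rng.randint(-3, 3)
        defuse_rows.append([
            f"CL{i:04d}", c.sample_id, c.gene5, c.gene3,
            c.chrom5, c.pos5 + jitter, c.strand5,
            c.chrom3, max(1, c.pos3 - jitter), c.strand3,
            c.split_reads, c.spanning_reads,
            "" if c.driver_score is None else f"{c.driver_score:g}",
        ])
    _write_tsv(defuse_rows, paths["defuse"],
               header=["cluster_id", "sample_id", "gene_name1", "gene_name2",
                       "chromosome1", "genomic_break_pos1", "genomic_strand1",
                       "chromosome2", "genomic_break_pos2", "genomic_strand2",
                       "splitr_count", "span_count", "probability"])

    _write_fasta(contigs, paths["genome"])
    write_gtf(genes, paths["gtf"])
    _write_cytobands_ucsc(bands, paths["cytobands"])

    karyotype_rows = []
    for s in samples:
        sex = sample_sex[s]
        events = karyotype_events[s]
        body = ",".join(["46", sex] + events) + f"[{rng.randint(10, 25)}]"
        karyotype_rows.append([s, body])
    _write_tsv(karyotype_rows, paths["karyotypes"],
               header=["sample_id", "karyotype"])

    _write_tsv([[a, b] for a, b in healthy_pairs] or [["DUMA", "DUMB"]],
               paths["healthy_panel"], header=["geneA", "geneB"])
    paths["tsg"].write_text("FLKB\nTSG1\n")

    cn_rows = []
    for tr in truth_records:
        if tr.deletion:
            d = tr.deletion
            cn_rows.append([f"chr{d['chrom']}", max(1, d["start"] - 1_000),
                            d["end"] + 1_000, 1])
    cn_rows.append(["chr1", 1, cfg.contig_length, 2])
    _write_tsv(cn_rows, paths["cn_segments"],
               header=["chrom", "start", "end", "copy_number"])

    cohort_rows = [["sample_id", "gender", "age", "who_class", "FLT3-TKD",
                    "FLT3-ITD", "FLT3-ITD-VAF", "TET2", "DNMT3A"]]
    for s in samples:
        itd = rng.choice(["POS", "NEG"])
        vaf = rng.choice([">0.5", "<0.5"]) if itd == "POS" else "NA"
        cohort_rows.append([
            s, "female" if sample_sex[s] == "XX" else "male",
            rng.randint(25, 85), "AML NOS", rng.choice(["POS", "NEG"]),
            itd, vaf, rng.choice(["POS", "NEG", "VARIANT", "NA"]),
            rng.choice(["POS", "NEG", "NA"]),
        ])
    with paths["cohort"].open("w") as fh:
        for row in cohort_rows:
            fh.write(",".join(str(x) for x in row) + "\n")

    run_config = {
        "inputs": {
            "fusion_tables": [
                {"path": BUNDLE_FILES["chimerascan"], "dialect": "chimerascan"},
                {"path": BUNDLE_FILES["defuse"], "dialect": "defuse"},
            ],
            "gtf": BUNDLE_FILES["gtf"],
            "cytobands": BUNDLE_FILES["cytobands"],
            "karyotypes": BUNDLE_FILES["karyotypes"],
            "healthy_panel": BUNDLE_FILES["healthy_panel"],
            "tsg": BUNDLE_FILES["tsg"],
            "cn_segments": BUNDLE_FILES["cn_segments"],
            "genome": BUNDLE_FILES["genome"],
            "cohort": BUNDLE_FILES["cohort"],
        },
        # Contigs are only 200 kb, so the read-through gap is scaled down
        # with them; the planted deletion gap (~50 kb) stays above it.
        "filters": {"readthrough_max_gap": cfg.readthrough_max_gap},
        "tolerance": 1,
        "max_skip": 2,
        "seed": seed,
    }
    paths["config"].write_text(yaml.safe_dump(run_config, sort_keys=True))

    truth = {
        "seed": seed,
        "n_samples": n_samples,
        "records": [
            {"id": tr.fusion_id, "sample_id": tr.sample_id,
             "gene5": tr.gene5, "gene3": tr.gene3, "category": tr.category,
             "frame": tr.frame, "microhomology": tr.microhomology,
             "deletion": tr.deletion}
            for tr in truth_records
        ],
        "files": {k: str(v.name) for k, v in paths.items()},
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return {k: str(v) for k, v in paths.items()}, truth


# ---------------------------------------------------------------------------
# Paper-style fixture bundle
# ---------------------------------------------------------------------------

def _stub_gene(symbol: str, chrom: str, strand: str,
               exons: list[tuple[int, int]], cds: tuple[int, int] | None,
               ) -> GeneModel:
    if strand == "-":
        exons = sorted(exons)[::-1]
    else:
        exons = sorted(exons)
    cds_lo, cds_hi = cds if cds else (None, None)
    return GeneModel(gene_id=symbol, transcript_id=f"{symbol}-001",
                     chrom=chrom, strand=strand, exons=exons,
                     cds_start=cds_lo, cds_end=cds_hi)


#: Junction sequence contexts for the fixture's exemplar junction; the
#: three shared cytosines make the exact breakpoint ambiguous.
FIXTURE_JUNCTIONS = {
    "59810:ZEB2-BCL11B": {
        "donor": "GTAGGTCAGATTCCAGGTTAACCC",
        "acceptor": "ATGGCTTGACCAGGTATCCCGGATGCGGATCCATGG",
        "junction_offset": 20,
        "max_k": 20,
    },
}


def paper_fixture(out_dir: str | Path) -> dict:
    """Write the deterministic fixture bundle: stylized gene stubs at the
    published coordinates, the eight cohort karyotypes, the candidate fusion
    table, panels and the five-patient mutational-status table.

    The cytoband table is stylized so each stub falls in the band its
    karyotype names; band boundaries are not the real assembly's.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genes = [
        _stub_gene("ZEB2", "chr2", "-",
                   [(145280000, 145282828), (145230500, 145231500),
                    (145180000, 145181000)],
                   (145180200, 145231126)),
        _stub_gene("BCL11B", "chr14", "-",
                   [(99737500, 99738000), (99736000, 99737000),
                    (99690000, 99690500), (99635000, 99637500)],
                   (99636322, 99736788)),
        _stub_gene("CNOT2", "chr12", "+", [(70637000, 70748000)],
                   (70637300, 70638301)),
        _stub_gene("WT1", "chr11", "-", [(32409000, 32457000)],
                   (32410000, 32456001)),
        _stub_gene("CPD", "chr17", "+", [(28700000, 28790000)],
                   (28700300, 28789699)),
        _stub_gene("PXT1", "chr6", "+", [(36360000, 36368000)],
                   (36360300, 36367700)),
        _stub_gene("SAV1", "chr14", "+", [(51000000, 51060000)],
                   (51000300, 51001301)),
        _stub_gene("GYPB", "chr4", "+", [(144917000, 144940000)],
                   (144917300, 144918301)),
        _stub_gene("OAZ1", "chr19", "+", [(2269000, 2273500)],
                   (2269300, 2270301)),
        _stub_gene("MAFK", "chr7", "+", [(1570000, 1582700)],
                   (1570300, 1571301)),
        _stub_gene("UTP6", "chr17", "-", [(30188190, 30230729)],
                   (30188490, 30230429)),
        _stub_gene("CRLF3", "chr17", "-", [(29107702, 29153778)],
                   (29108003, 29153479)),
        _stub_gene("NF1", "chr17", "+", [(29421945, 29709134)],
                   (29422245, 29708246)),
        _stub_gene("PUF60", "chr8", "-", [(144898000, 144913000)],
                   (144899000, 144912001)),
        _stub_gene("TYW1", "chr7", "+", [(66434000, 66470000)],
                   (66434300, 66435301)),
        _stub_gene("CBFB", "chr16", "+", [(67063000, 67134000)],
                   (67063300, 67064301)),
        _stub_gene("MYH11", "chr16", "-", [(15797000, 15950000)],
                   (15798000, 15949001)),
    ]

    bands = {
        "chr2": [("p11", 1, 93_300_000), ("q11", 93_300_001, 130_000_000),
                 ("q21", 130_000_001, 143_000_000),
                 ("q22.3", 143_000_001, 160_000_000),
                 ("q31", 160_000_001, 243_199_373)],
        "chr4": [("p15", 1, 50_000_000), ("q11", 50_000_001, 88_000_000),
                 ("q22", 88_000_001, 120_000_000),
                 ("q31", 120_000_001, 155_000_000),
                 ("q35", 155_000_001, 191_154_276)],
        "chr6": [("p21", 1, 46_000_000), ("q11", 46_000_001, 62_000_000),
                 ("q15", 62_000_001, 114_000_000),
                 ("q25", 114_000_001, 171_115_067)],
        "chr7": [("p22", 1, 25_000_000), ("p11", 25_000_001, 60_000_000),
                 ("q11", 60_000_001, 80_000_000),
                 ("q21", 80_000_001, 159_138_663)],
        "chr8": [("p23", 1, 10_000_000), ("p11", 10_000_001, 45_000_000),
                 ("q11", 45_000_001, 90_000_000),
                 ("q24", 90_000_001, 146_364_022)],
        "chr11": [("p15", 1, 36_000_000), ("p11", 36_000_001, 53_700_000),
                  ("q11", 53_700_001, 70_000_000),
                  ("q22", 70_000_001, 100_000_000),
                  ("q25", 100_000_001, 135_006_516)],
        "chr12": [("p13", 1, 12_000_000), ("p11", 12_000_001, 35_800_000),
                  ("q11", 35_800_001, 46_000_000),
                  ("q15", 46_000_001, 68_000_000),
                  ("q22", 68_000_001, 95_000_000),
                  ("q24", 95_000_001, 133_851_895)],
        "chr14": [("p11", 1, 16_000_000), ("q11", 16_000_001, 40_000_000),
                  ("q22", 40_000_001, 60_000_000),
                  ("q31", 60_000_001, 90_000_000),
                  ("q32.2", 90_000_001, 107_349_540)],
        "chr16": [("p13", 1, 22_000_000), ("p11", 22_000_001, 36_800_000),
                  ("q11", 36_800_001, 50_000_000),
                  ("q22", 50_000_001, 75_000_000),
                  ("q24", 75_000_001, 90_354_753)],
        "chr17": [("p11", 1, 25_000_000), ("q11", 25_000_001, 32_000_000),
                  ("q21", 32_000_001, 45_000_000),
                  ("q24", 45_000_001, 60_000_000),
                  ("q25", 60_000_001, 81_195_210)],
        "chr19": [("p13", 1, 10_000_000), ("p11", 10_000_001, 28_500_000),
                  ("q11", 28_500_001, 40_000_000),
                  ("q13", 40_000_001, 59_128_983)],
    }

    karyotypes = [
        ["59810", "46,XX,t(2;14)(q21;q32),t(11;12)(p15;q22)[17]/46,XX[3]"],
        ["20", "46,XY,t(6;17)(p21;q11)[20]"],
        ["21", "46,XY,t(3;12)(p22;q24),+4,-15,+mar[19]/46,XY[1]"],
        ["32", "45,XY,der(12)t(12;18)(p13;q12),-18[12]/"
               "45,XY,t(4;16)(q31;q22),der(12)t(12;18)(p13;q12),-18[4]/"
               "45,XY,der(6)t(6;12;18)(p21;p13,q12),-18[3]/46,XY[1]"],
        ["84", "47,XX,+8,del(11)(p11p15),t(15;17)(q24q25),inv(16)(p13q22)[20]"],
        ["68187", "46,XX,add(8)(p23),der(16)t(1;16)(q11;q11)[18]/46,XX[2]"],
        ["63569", "46,XY[20]/46,XY,add(10)(p15)[9]/"
                  "46,XY,add(10)(p15),t(1;8)(p36;q13)[2]"],
        ["125", "46,XX[11]/44~47,XX,t(4;17)(p15;q21),del(5)(q13q33),-7,-18,"
                "der(X),+1~3mar[9]"],
    ]

    fusions = [
        # sample, g5, g3, chrom5, pos5, strand5, chrom3, pos3, strand3,
        # split, span, ds
        ["59810", "ZEB2", "BCL11B", "chr2", 145231055, "-",
         "chr14", 99736731, "-", 30, 20, 0.95],
        ["59810", "CNOT2", "WT1", "chr12", 70637599, "+",
         "chr11", 32430000, "+", 12, 8, 0.40],
        ["20", "CPD", "PXT1", "chr17", 28700599, "+",
         "chr6", 36360600, "+", 15, 10, 0.50],
        ["20", "SAV1", "GYPB", "chr14", 51000599, "+",
         "chr4", 144917600, "+", 18, 11, 0.87],
        ["21", "OAZ1", "MAFK", "chr19", 2269599, "+",
         "chr7", 1570600, "+", 9, 6, 0.82],
        ["68187", "UTP6", "CRLF3", "chr17", 30188190, "-",
         "chr17", 29153778, "-", 14, 9, 0.30],
        ["125", "PUF60", "TYW1", "chr8", 144911701, "-",
         "chr7", 66434600, "+", 7, 5, 0.35],
        ["84", "CBFB", "MYH11", "chr16", 67063599, "+",
         "chr16", 15948701, "-", 40, 25, 0.99],
    ]

    cohort = [
        ["sample_id", "gender", "age", "who_class", "FLT3-TKD", "FLT3-ITD",
         "FLT3-ITD-VAF", "DNMT3A", "GATA2", "JAK2", "RUNX1", "SRSF2",
         "TET2", "SETBP1"],
        ["11942", "male", 58, "AML NOS", "NEG", "NEG", "NA",
         "NEG", "NEG", "NEG", "NEG", "NEG", "VARIANT", "NEG"],
        ["11944", "male", 79, "AUL", "NEG", "POS", ">0.5",
         "NEG", "NEG", "NEG", "VARIANT", "POS", "POS", "VARIANT"],
        ["11954", "male", 85, "AML with mutated RUNX1", "NEG", "POS", ">0.5",
         "NEG", "NA", "POS", "POS", "NA", "NEG", "NA"],
        ["11945", "male", 59, "T/myeloid MPAL", "POS", "POS", "<0.5",
         "POS", "POS", "NEG", "VARIANT", "NEG", "NEG", "NEG"],
        ["59810", "female", 40, "AML NOS without maturation", "POS", "POS",
         "<0.5", "NEG", "NEG", "NEG", "NEG", "NEG", "POS", "NEG"],
    ]

    paths = {k: out_dir / v for k, v in BUNDLE_FILES.items()
             if k not in ("genome", "truth")}
    paths["junctions"] = out_dir / "junctions.json"

    write_gtf(genes, paths["gtf"])
    _write_cytobands_ucsc(bands, paths["cytobands"])
    _write_tsv(karyotypes, paths["karyotypes"],
               header=["sample_id", "karyotype"])
    _write_tsv(
        [[r[0], r[1], r[2], r[3], r[4], r[5], r[6], r[7], r[8], r[9], r[10],
          f"{r[11]:g}"] for r in fusions],
        paths["chimerascan"],
        header=["sample_id", "gene5", "gene3", "chrom5", "pos5", "strand5",
                "chrom3", "pos3", "strand3", "split_reads", "spanning_reads",
                "driver_score"])
    _write_tsv([], paths["defuse"],
               header=["cluster_id", "sample_id", "gene_name1", "gene_name2",
                       "chromosome1", "genomic_break_pos1", "genomic_strand1",
                       "chromosome2", "genomic_break_pos2", "genomic_strand2",
                       "splitr_count", "span_count", "probability"])
    _write_tsv([["HBB", "HBA"], ["GAPDH", "ACTB"]], paths["healthy_panel"],
               header=["geneA", "geneB"])
    paths["tsg"].write_text("SAV1\nPUF60\nCNOT2\nWT1\nCRLF3\n")
    _write_tsv([["chr17", 28710000, 30760000, 1],
                ["chr2", 1, 243199373, 2]],
               paths["cn_segments"],
               header=["chrom", "start", "end", "copy_number"])
    with paths["cohort"].open("w") as fh:
        for row in cohort:
            fh.write(",".join(str(x) for x in row) + "\n")
    paths["junctions"].write_text(
        json.dumps(FIXTURE_JUNCTIONS, indent=2, sort_keys=True) + "\n")

    run_config = {
        "inputs": {
            "fusion_tables": [
                {"path": BUNDLE_FILES["chimerascan"], "dialect": "chimerascan"},
                {"path": BUNDLE_FILES["defuse"], "dialect": "defuse"},
            ],
            "gtf": BUNDLE_FILES["gtf"],
            "cytobands": BUNDLE_FILES["cytobands"],
            "karyotypes": BUNDLE_FILES["karyotypes"],
            "healthy_panel": BUNDLE_FILES["healthy_panel"],
            "tsg": BUNDLE_FILES["tsg"],
            "cn_segments": BUNDLE_FILES["cn_segments"],
            "cohort": BUNDLE_FILES["cohort"],
            "junctions": "junctions.json",
        },
        "filters": {},
        "tolerance": 1,
        "max_skip": 2,
        "seed": 0,
    }
    paths["config"].write_text(yaml.safe_dump(run_config, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
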