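"""Parser for ISCN-style karyotype strings into structured clones and events.

Coverage is deliberately partial: translocations, inversions, deletions,
additions, derivatives with embedded translocations, whole-chromosome
gains/losses and markers.  Anything else (range notations, der(X) without an
embedded rearrangement, ider/idic/ins, fragile sites) degrades to
``kind='other'`` with the raw token preserved — never dropped — so that the
input can always be reconstructed and concordance never guesses intent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import IscnParseError

EVENT_KINDS = ("translocation", "inversion", "deletion", "derivative",
               "gain", "loss", "marker", "addition", "other")

_BAND_TOKEN_RE = re.compile(r"[pq]\d+(?:\.\d+)?(?:-[pq]?\d+(?:\.\d+)?)?")
_GAIN_RE = re.compile(r"^\+(\d+|[XY])$")
_LOSS_RE = re.compile(r"^-(\d+|[XY])$")
_MARKER_RE = re.compile(r"^\+?\d*(?:~\d+)?mar$")
_PAIRED_RE = re.compile(r"^(t|inv|del|add)\(([^()]*)\)\(([^()]*)\)$")
_DER_RE = re.compile(r"^der\(([^()]*)\)(.*)$")
_EMBEDDED_T_RE = re.compile(r"^t\(([^()]*)\)\(([^()]*)\)")
_SEX_RE = re.compile(r"^[XY]+$")
_MODAL_RE = re.compile(r"^\d+(~\d+)?$")


@dataclass(frozen=True)
class StructuralEvent:
    """One cytogenetic event extracted from a karyotype clone."""

    kind: str
    chroms: tuple[str, ...]
    bands: tuple[str, ...]
    raw: str

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")

    @property
    def identity(self) -> tuple:
        return (self.kind, self.chroms, self.bands)


@dataclass
class Clone:
    modal: str
    events: list[StructuralEvent]
    cell_count: int | None = None

    def serialize(self) -> str:
        body = ",".join([self.modal] + [e.raw for e in self.events])
        if self.cell_count is not None:
            body += f"[{self.cell_count}]"
        return body


@dataclass
class Karyotype:
    sample_id: str
    clones: list[Clone] = field(default_factory=list)

    def serialize(self) -> str:
        return "/".join(c.serialize() for c in self.clones)

    def all_events(self) -> list[StructuralEvent]:
        return [e for c in self.clones for e in c.events]


def _check_parens(text: str) -> None:
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise IscnParseError("unbalanced parentheses", offset=i)
    if depth != 0:
        raise IscnParseError("unbalanced parentheses", offset=len(text))


def _split_top_level(text: str, sep: str) -> list[str]:
    parts, depth, buf = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == sep and depth == 0:
            parts.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    parts.append("".join(buf))
    return parts


def _bands_from_group(group: str) -> tuple[str, ...]:
    """Extract band labels from a band group; tolerates missing separators
    (e.g. 'q24q25') and mixed ';'/',' separators in three-way events."""
    return tuple(_BAND_TOKEN_RE.findall(group))


def parse_event(token: str) -> StructuralEvent:
    """Classify one comma-level karyotype token."""
    other = StructuralEvent("other", (), (), token)
    if m := _GAIN_RE.match(token):
        return StructuralEvent("gain", (m.group(1),), (), token)
    if m := _LOSS_RE.match(token):
        return StructuralEvent("loss", (m.group(1),), (), token)
    if _MARKER_RE.match(token):
        return StructuralEvent("marker", (), (), token)
    if m := _PAIRED_RE.match(token):
        op, chrom_group, band_group = m.groups()
        chroms = tuple(c for c in re.split(r"[;,]", chrom_group) if c)
        bands = _bands_from_group(band_group)
        kind = {"t": "translocation", "inv": "inversion",
                "del": "deletion", "add": "addition"}[op]
        if kind == "translocation":
            if len(chroms) < 2 or len(bands) != len(chroms):
                return other
        elif len(chroms) != 1 or not 1 <= len(bands) <= 2:
            return other
        return StructuralEvent(kind, chroms, bands, token)
    if m := _DER_RE.match(token):
        rest = m.group(2)
        if t := _EMBEDDED_T_RE.match(rest):
            chroms = tuple(c for c in re.split(r"[;,]", t.group(1)) if c)
            bands = _bands_from_group(t.group(2))
            if len(chroms) >= 2 and len(bands) == len(chroms):
                return StructuralEvent("derivative", chroms, bands, token)
        return other  # der(X) and friends: never guess cytogenetic intent
    return other


def parse_karyotype(text: str, sample_id: str = "") -> Karyotype:
    """Parse an ISCN karyotype string; clones separated by '/', cell counts
    in square brackets."""
    if not text or not text.strip():
        raise IscnParseError("empty karyotype string")
    compact = re.sub(r"\s+", "", text)
    _check_parens(compact)
    karyotype = Karyotype(sample_id=sample_id)
    for clone_text in compact.split("/"):
        if not clone_text:
            raise IscnParseError("empty clone")
        cell_count = None
        if m := re.search(r"\[(\d+)\]$", clone_text):
            cell_count = int(m.group(1))
            clone_text = clone_text[:m.start()]
        tokens = _split_top_level(clone_text, ",")
        if not tokens or not _MODAL_RE.match(tokens[0]):
            raise IscnParseError(f"clone lacks a modal number: {clone_text!r}")
        modal_parts = [tokens[0]]
        rest = tokens[1:]
        if rest and _SEX_RE.match(rest[0]):
            modal_parts.append(rest.pop(0))
        events = [parse_event(tok) for tok in rest]
        karyotype.clones.append(
            Clone(modal=",".join(modal_parts), events=events,
                  cell_count=cell_count))
    return karyotype


def extract_translocation_like(karyotype: Karyotype) -> list[StructuralEvent]:
    """Translocations, inversions and derivative-embedded translocations
    across all clones, deduplicated by (chromosomes, bands)."""
    out: list[StructuralEvent] = []
    seen: set[tuple] = set()
    for event in karyotype.all_events():
        if event.kind not in ("translocation", "inversion", "derivative"):
            continue
        if not event.chroms:
            continue
        key = ("inv" if event.kind == "inversion" else "t",
               event.chroms, event.bands)
        if key in seen:
            continue
        seen.add(key)
        out.append(event)
    return out
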