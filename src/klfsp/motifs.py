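"""Triple-C2H2 architecture scanning and KLF/SP family classification.

KLF and SP transcription factors share a C-terminal DNA-binding domain of
three tandem C2H2 zinc fingers with tightly constrained spacing between the
zinc-coordinating cysteines and histidines.  Candidate screening here is
architecture-based: a window of a protein qualifies when every fixed residue
of the spacer pattern

    C-X4-C-X12-H-X3-H -x7- C-X4-C-X12-H-X3-H -x7- C-X2-C-X12-H-X3-H

is present at its exact offset (X = any residue), and a conserved aspartate
sits at position 44 of the matched window (1-based).  SP family members are
further distinguished from KLFs by a Buttonhead (Btd) box N-terminal to the
zinc fingers.

The literal spacer pattern above sums to 81 positions.  Some descriptions of
this architecture give a total of 88 residues; every spacer length is
therefore exposed through :class:`ArchitecturePattern` / YAML config so that
alternative readings can be encoded without code changes.

Short activator/repressor motifs (SID, PVDLS, R2, R3, SP-box, Btd, 9aaTAD)
vary between studies and are supplied through config.  The defaults shipped
in :data:`DEFAULT_MOTIFS` are *non-canonical placeholders* — plausible
literal/regex stand-ins used by the simulator and the test-suite, not
community consensus strings.  Replace them with curated patterns for real
screens.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")

__all__ = [
    "ProteinRecord",
    "ArchitecturePattern",
    "ZincFingerHit",
    "MotifDefinition",
    "MotifAnnotation",
    "FamilyCall",
    "ConcatBlock",
    "DEFAULT_MOTIFS",
    "DEFAULT_MOTIF_ORDER",
    "scan_architecture",
    "check_d44",
    "annotate_motifs",
    "classify_family",
    "build_concat_block",
    "screen_proteome",
    "read_fasta",
    "write_blocks_fasta",
]


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its taxon of origin.

    ``sequence`` is restricted to the 20 amino acids plus the ambiguity
    character X; anything else is rejected at construction time.
    """

    id: str
    sequence: str
    taxon: str = ""
    lineage: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"{self.id}: invalid characters {sorted(bad)!r}; "
                f"allowed alphabet is the 20 amino acids plus X"
            )


# Pattern elements: a fixed residue is a 1-char string; a spacer is an int
# length (exact).  The ambiguity character X in the *input* matches spacer
# positions only, never a fixed C/H (conservative candidate calling).
_DEFAULT_ELEMENTS: tuple[str | int, ...] = (
    "C", 4, "C", 12, "H", 3, "H", 7,
    "C", 4, "C", 12, "H", 3, "H", 7,
    "C", 2, "C", 12, "H", 3, "H",
)


@dataclass(frozen=True)
class ArchitecturePattern:
    """Zinc-finger spacer architecture: fixed residues and exact spacers.

    ``elements`` alternates fixed residues (``"C"``/``"H"``) and integer
    spacer lengths; it must begin and end with a fixed residue.
    ``d_position`` is the 1-based index of the conserved-aspartate check
    within a matched window (default 44).
    """

    elements: tuple[str | int, ...] = _DEFAULT_ELEMENTS
    d_position: int = 44

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("empty architecture pattern")
        if not isinstance(self.elements[0], str) or not isinstance(self.elements[-1], str):
            raise ValueError("pattern must begin and end with a fixed residue")
        for el in self.elements:
            if isinstance(el, int):
                if el < 0:
                    raise ValueError("spacer lengths must be >= 0")
            elif el not in ("C", "H"):
                raise ValueError(f"fixed residues must be C or H, got {el!r}")
        if self.length < 1:
            raise ValueError("pattern length must be >= 1")

    @property
    def length(self) -> int:
        """Realized window length (all spacers are exact)."""
        return sum(el if isinstance(el, int) else 1 for el in self.elements)

    def fixed_offsets(self) -> list[tuple[int, str]]:
        """(offset, residue) pairs of the fixed positions within a window."""
        out, pos = [], 0
        for el in self.elements:
            if isinstance(el, int):
                pos += el
            else:
                out.append((pos, el))
                pos += 1
        return out

    def finger_spans(self) -> list[tuple[int, int]]:
        """Half-open spans of the C2H2 fingers (C..H units) within a window.

        A finger starts at each C that follows an H (or the window start)
        and ends after the next H that is followed by a C-or-end.
        """
        offs = self.fixed_offsets()
        spans: list[tuple[int, int]] = []
        start = None
        for i, (pos, res) in enumerate(offs):
            if res == "C" and start is None:
                start = pos
            if res == "H" and start is not None:
                nxt = offs[i + 1][1] if i + 1 < len(offs) else None
                if nxt != "H":
                    spans.append((start, pos + 1))
                    start = None
        return spans

    @classmethod
    def from_spacers(cls, spacers: list[int], d_position: int = 44) -> "ArchitecturePattern":
        """Build the triple-C2H2 layout from its 11 spacer lengths.

        ``spacers`` are, in order: within-finger spacings (C-x-C-x-H-x-H)
        for fingers 1..3 interleaved with the two inter-finger linkers:
        [c1a, c1b, h1, link1, c2a, c2b, h2, link2, c3a, c3b, h3].
        """
        if len(spacers) != 11:
            raise ValueError("expected 11 spacer lengths")
        s = spacers
        elements: list[str | int] = []
        for f in range(3):
            elements += ["C", s[4 * f], "C", s[4 * f + 1], "H", s[4 * f + 2], "H"]
            if f < 2:
                elements.append(s[4 * f + 3])
        return cls(tuple(elements), d_position=d_position)


@dataclass(frozen=True)
class ZincFingerHit:
    """One architecture match: window coordinates, finger spans, D44 status."""

    record_id: str
    start: int
    end: int
    finger_spans: tuple[tuple[int, int], ...]
    d44_ok: bool
    matched_subsequence: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("hit start must precede end")
        if len(self.matched_subsequence) != self.end - self.start:
            raise ValueError("matched_subsequence length mismatch")


def scan_architecture(
    record: ProteinRecord, pattern: ArchitecturePattern | None = None
) -> list[ZincFingerHit]:
    """Find every window of ``record`` matching the spacer architecture.

    All matching windows are returned sorted by start, including mutually
    overlapping ones; downstream consumers take the leftmost.  Fixed
    residues must match exactly (input X never satisfies a fixed position);
    spacer positions accept any alphabet character.
    """
    pattern = pattern or ArchitecturePattern()
    seq = record.sequence
    m = pattern.length
    fixed = pattern.fixed_offsets()
    spans = tuple(pattern.finger_spans())
    hits: list[ZincFingerHit] = []
    for start in range(len(seq) - m + 1):
        if all(seq[start + off] == res for off, res in fixed):
            window = seq[start : start + m]
            hits.append(
                ZincFingerHit(
                    record_id=record.id,
                    start=start,
                    end=start + m,
                    finger_spans=tuple((start + a, start + b) for a, b in spans),
                    d44_ok=_d44(window, pattern),
                    matched_subsequence=window,
                )
            )
    return hits


def _d44(window: str, pattern: ArchitecturePattern) -> bool:
    if pattern.d_position > len(window):
        raise ValueError(
            f"d_position {pattern.d_position} exceeds window length {len(window)}"
        )
    return window[pattern.d_position - 1] == "D"


def check_d44(
    hit: ZincFingerHit, record: ProteinRecord, pattern: ArchitecturePattern | None = None
) -> bool:
    """True iff the residue at ``pattern.d_position`` (1-based, within the
    matched window) is aspartate."""
    pattern = pattern or ArchitecturePattern()
    window = record.sequence[hit.start : hit.end]
    if window != hit.matched_subsequence:
        raise ValueError("hit does not belong to this record")
    return _d44(window, pattern)


@dataclass(frozen=True)
class MotifDefinition:
    """A named short motif given as a regular expression over amino acids."""

    name: str
    pattern: str
    source: str = "config"

    def __post_init__(self) -> None:
        re.compile(self.pattern)  # fail fast on bad patterns

    @property
    def regex(self) -> "re.Pattern[str]":
        return re.compile(self.pattern)


# Placeholder motif strings: plausible stand-ins for screening and
# simulation, NOT curated consensus sequences.  Override via config for
# real data.
DEFAULT_MOTIFS: tuple[MotifDefinition, ...] = (
    MotifDefinition("SID", "SID[LM]S", "builtin-placeholder"),
    MotifDefinition("PVDLS", "PVDLS", "builtin-placeholder"),
    MotifDefinition("R2", "RPGRP", "builtin-placeholder"),
    MotifDefinition("R3", "RERRP", "builtin-placeholder"),
    MotifDefinition("SP-box", "SPLALLA", "builtin-placeholder"),
    MotifDefinition("Btd", "C.CP.C", "builtin-placeholder"),
    MotifDefinition("9aaTAD", "D[LIVM].{2}LF", "builtin-placeholder"),
)

DEFAULT_MOTIF_ORDER: tuple[str, ...] = ("SID", "R2", "R3", "SP-box", "Btd", "C2H2")


@dataclass(frozen=True)
class MotifAnnotation:
    record_id: str
    motif_name: str
    start: int
    end: int


def annotate_motifs(
    record: ProteinRecord, defs: list[MotifDefinition] | tuple[MotifDefinition, ...]
) -> list[MotifAnnotation]:
    """Non-overlapping leftmost matches of each motif, sorted by position."""
    anns: list[MotifAnnotation] = []
    for d in defs:
        for m in d.regex.finditer(record.sequence):
            anns.append(MotifAnnotation(record.id, d.name, m.start(), m.end()))
    anns.sort(key=lambda a: (a.start, a.end, a.motif_name))
    return anns


@dataclass(frozen=True)
class FamilyCall:
    record_id: str
    call: str  # "SP" | "KLF" | "non-member"
    evidence: tuple[str, ...] = ()


def classify_family(
    record: ProteinRecord,
    hits: list[ZincFingerHit],
    annotations: list[MotifAnnotation],
) -> FamilyCall:
    """Family call from architecture hits and motif annotations.

    non-member — no architecture hit with the D44 aspartate;
    SP — member with a Btd box ending N-terminal to the first qualifying hit;
    KLF — member otherwise.
    """
    qualifying = [h for h in hits if h.d44_ok]
    if not qualifying:
        return FamilyCall(record.id, "non-member")
    first = min(qualifying, key=lambda h: h.start)
    evidence = [f"architecture@{first.start}"]
    for a in annotations:
        if a.motif_name == "Btd" and a.end <= first.start:
            evidence.append(f"Btd@{a.start}")
            return FamilyCall(record.id, "SP", tuple(evidence))
    return FamilyCall(record.id, "KLF", tuple(evidence))


@dataclass(frozen=True)
class ConcatBlock:
    """Motif segments of one protein concatenated in a configured order.

    Used to build alignment blocks restricted to conserved motifs: segments
    for motifs present in the record, in ``motif_order``, with absent motifs
    listed rather than gap-padded.
    """

    record_id: str
    segments: tuple[tuple[str, str], ...]  # (motif_name, subsequence)
    absent_motifs: tuple[str, ...]

    @property
    def concatenated_sequence(self) -> str:
        return "".join(s for _, s in self.segments)


def build_concat_block(
    record: ProteinRecord,
    annotations: list[MotifAnnotation],
    motif_order: tuple[str, ...] = DEFAULT_MOTIF_ORDER,
    architecture_hits: list[ZincFingerHit] | None = None,
) -> ConcatBlock:
    """Concatenate motif subsequences in ``motif_order``.

    ``C2H2`` in the order refers to the zinc-finger architecture window and
    is taken from ``architecture_hits`` (leftmost) when supplied.  If a motif
    has several annotations, the leftmost is used and a warning logged.
    """
    by_name: dict[str, tuple[int, int]] = {}
    for a in sorted(annotations, key=lambda a: a.start):
        if a.motif_name in by_name:
            warnings.warn(
                f"{record.id}: multiple {a.motif_name} annotations; using leftmost",
                stacklevel=2,
            )
            continue
        by_name[a.motif_name] = (a.start, a.end)
    if architecture_hits:
        h = min(architecture_hits, key=lambda h: h.start)
        by_name.setdefault("C2H2", (h.start, h.end))
    segments, absent = [], []
    for name in motif_order:
        if name in by_name:
            s, e = by_name[name]
            segments.append((name, record.sequence[s:e]))
        else:
            absent.append(name)
    return ConcatBlock(record.id, tuple(segments), tuple(absent))


def screen_proteome(
    records: list[ProteinRecord],
    pattern: ArchitecturePattern | None = None,
    motif_defs: tuple[MotifDefinition, ...] = DEFAULT_MOTIFS,
    motif_order: tuple[str, ...] = DEFAULT_MOTIF_ORDER,
) -> pd.DataFrame:
    """Screen a proteome: one row per record, sorted by record id.

    Columns: record id, taxon, lineage, architecture hit count, D44 status
    of the leftmost hit, family call, and a presence flag per motif.
    """
    pattern = pattern or ArchitecturePattern()
    rows = []
    for rec in sorted(records, key=lambda r: r.id):
        hits = scan_architecture(rec, pattern)
        anns = annotate_motifs(rec, motif_defs)
        call = classify_family(rec, hits, anns)
        row = {
            "record_id": rec.id,
            "taxon": rec.taxon,
            "lineage": rec.lineage or "",
            "n_hits": len(hits),
            "d44_ok": any(h.d44_ok for h in hits),
            "family": call.call,
        }
        present = {a.motif_name for a in anns}
        for d in motif_defs:
            row[f"has_{d.name}"] = d.name in present
        rows.append(row)
    cols = ["record_id", "taxon", "lineage", "n_hits", "d44_ok", "family"] + [
        f"has_{d.name}" for d in motif_defs
    ]
    return pd.DataFrame(rows, columns=cols)


def read_fasta(path: str) -> list[ProteinRecord]:
    """Read protein FASTA; headers are '>id taxon lineage' (space-delimited,
    taxon and lineage optional)."""
    out = []
    for rec in SeqIO.parse(path, "fasta"):
        parts = rec.description.split()
        taxon = parts[1] if len(parts) > 1 else ""
        lineage = parts[2] if len(parts) > 2 else None
        out.append(ProteinRecord(rec.id, str(rec.seq).upper(), taxon, lineage))
    return out


def write_blocks_fasta(blocks: list[ConcatBlock], path: str) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            if b.concatenated_sequence:
                fh.write(f">{b.record_id}\n{b.concatenated_sequence}\n")
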