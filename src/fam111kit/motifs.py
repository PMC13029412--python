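"""Degenerate consensus motifs: patterns, parsing, and sequence scanning.

A motif pattern is an ordered list of position specs — a literal residue, a
two-way alternative ``[A/B]``, or a wildcard ``X`` — in a PROSITE-like
dash-separated syntax (``[AT]-[LV]-x-x-D-G-R-[FL]``).  Patterns must start
and end on a non-wildcard, be at least 5 positions long, and contain at most
3 consecutive wildcards.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

from .seqio import SequenceRecord

MIN_PATTERN_LENGTH = 5
MAX_CONSECUTIVE_WILDCARDS = 3


class MotifError(ValueError):
    pass


@dataclass(frozen=True)
class PositionSpec:
    """One motif position: literal, two-way alternative, or wildcard."""

    kind: str  # 'literal' | 'pair' | 'wildcard'
    residues: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind == "literal" and len(self.residues) != 1:
            raise MotifError("literal position needs exactly one residue")
        if self.kind == "pair" and len(self.residues) != 2:
            raise MotifError("pair position needs exactly two residues")
        if self.kind == "wildcard" and self.residues:
            raise MotifError("wildcard position carries no residues")

    @property
    def is_wildcard(self) -> bool:
        return self.kind == "wildcard"

    def accepts(self, residue: str) -> bool:
        return self.is_wildcard or residue in self.residues

    def to_text(self) -> str:
        if self.kind == "literal":
            return self.residues[0]
        if self.kind == "pair":
            return f"[{self.residues[0]}/{self.residues[1]}]"
        return "X"


def literal(res: str) -> PositionSpec:
    return PositionSpec("literal", (res,))


def pair(a: str, b: str) -> PositionSpec:
    return PositionSpec("pair", (a, b))


WILDCARD = PositionSpec("wildcard")


@dataclass(frozen=True)
class MotifPattern:
    """A named degenerate pattern, optionally anchored to alignment columns
    (``col_span``) or to a residue interval on a named sequence (``ref_span``,
    1-based inclusive)."""

    name: str
    positions: tuple[PositionSpec, ...]
    col_span: tuple[int, int] | None = None
    ref_span: tuple[str, int, int] | None = None

    def __post_init__(self):
        if len(self.positions) < MIN_PATTERN_LENGTH:
            raise MotifError(
                f"pattern {self.name!r}: length {len(self.positions)} < "
                f"{MIN_PATTERN_LENGTH}"
            )
        if self.positions[0].is_wildcard or self.positions[-1].is_wildcard:
            raise MotifError(f"pattern {self.name!r} must start and end on anchors")
        run = 0
        for p in self.positions:
            run = run + 1 if p.is_wildcard else 0
            if run > MAX_CONSECUTIVE_WILDCARDS:
                raise MotifError(
                    f"pattern {self.name!r}: more than "
                    f"{MAX_CONSECUTIVE_WILDCARDS} consecutive wildcards"
                )

    def __len__(self) -> int:
        return len(self.positions)

    def to_text(self) -> str:
        return "-".join(p.to_text() for p in self.positions)

    def mismatches(self, window: str) -> int:
        """Number of window positions violating their spec (wildcards never do)."""
        if len(window) != len(self.positions):
            raise MotifError("window length does not match pattern length")
        return sum(0 if p.accepts(ch) else 1 for p, ch in zip(self.positions, window))


@dataclass(frozen=True)
class MotifCall:
    """Placement of a pattern on a sequence, 1-based inclusive coordinates."""

    pattern_name: str
    sequence_id: str
    start: int
    end: int
    mismatches: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise MotifError("invalid motif call coordinates")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


_TOKEN_RE = re.compile(r"^(?:\[([A-Z])/?([A-Z])\]|([A-Z])|([xX]))$")


def parse_pattern(text: str, name: str = "motif") -> MotifPattern:
    """Parse a dash-separated pattern like ``[AT]-[LV]-x-x-D-G-R-[FL]``.

    ``[AB]`` and ``[A/B]`` are both accepted for two-way alternatives.
    """
    positions: list[PositionSpec] = []
    for tok in text.strip().split("-"):
        m = _TOKEN_RE.match(tok.strip())
        if not m:
            raise MotifError(f"cannot parse pattern token {tok!r} in {text!r}")
        if m.group(1):
            positions.append(pair(m.group(1), m.group(2)))
        elif m.group(3) and m.group(3) not in ("X",):
            positions.append(literal(m.group(3)))
        elif m.group(3) == "X" or m.group(4):
            positions.append(WILDCARD)
    return MotifPattern(name=name, positions=tuple(positions))


def scan_pattern(
    pattern: MotifPattern,
    seq: SequenceRecord | str,
    max_mismatch: int = 0,
    sequence_id: str | None = None,
) -> list[MotifCall]:
    """All windows matching the pattern with at most ``max_mismatch``
    violations, sorted by (mismatches, start); coordinates are 1-based."""
    if isinstance(seq, SequenceRecord):
        residues, sid = seq.residues, seq.id
    else:
        residues, sid = seq, sequence_id or "seq"
    L = len(pattern)
    calls = []
    for start in range(len(residues) - L + 1):
        mm = pattern.mismatches(residues[start : start + L])
        if mm <= max_mismatch:
            calls.append(
                MotifCall(
                    pattern_name=pattern.name,
                    sequence_id=sid,
                    start=start + 1,
                    end=start + L,
                    mismatches=mm,
                )
            )
    calls.sort(key=lambda c: (c.mismatches, c.start))
    return calls


def write_motif_file(patterns: Iterable[MotifPattern], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# name<TAB>pattern (PROSITE-like; [AB] two-way, x wildcard)\n")
        for pat in patterns:
            compact = "-".join(
                "".join(("[", *p.residues, "]")) if p.kind == "pair"
                else ("x" if p.is_wildcard else p.residues[0])
                for p in pat.positions
            )
            fh.write(f"{pat.name}\t{compact}\n")


def load_motif_file(path: str | Path) -> list[MotifPattern]:
    patterns = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, text = line.split("\t", 1)
            patterns.append(parse_pattern(text, name=name))
    return patterns


def reference_motifs() -> list[MotifPattern]:
    """The seven conserved motifs of the FAM111A family, bundled with the
    package, parsed and validated."""
    path = resources.files("fam111kit.data").joinpath("fam111a_conserved_motifs.txt")
    with resources.as_file(path) as p:
        return load_motif_file(p)
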