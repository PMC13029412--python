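"""Physicochemical column conservation scoring and motif segmentation.

Scoring follows the classic alignment-annotation convention: each column is
rated on a 0-11 scale, where 11 means every (non-gap) residue is identical
and 0-10 counts how many of ten binary physicochemical properties
(hydrophobic, polar, small, proline, tiny, aliphatic, aromatic, positive,
negative, charged) are uniformly present or uniformly absent across the
column.  A column is an anchor for motif calling when it is strongly
conserved (score >= 10 at >= 90% frequency, gaps counted in the
denominator), or when two physicochemically compatible residues jointly
cover >= 90% of the column.  Maximal runs of anchors, tolerating short
wildcard stretches, become degenerate consensus motifs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import AlignmentMatrix
from .motifs import WILDCARD, MotifPattern, PositionSpec, literal, pair

_DEFAULT_PROPERTIES: dict[str, frozenset[str]] = {
    "hydrophobic": frozenset("ILVCAGMFYWHKT"),
    "polar": frozenset("YWHKREQDNSTC"),
    "small": frozenset("VCAGDNSTP"),
    "proline": frozenset("P"),
    "tiny": frozenset("AGS"),
    "aliphatic": frozenset("ILV"),
    "aromatic": frozenset("FYWH"),
    "positive": frozenset("HKR"),
    "negative": frozenset("DE"),
    "charged": frozenset("HKRDE"),
}


@dataclass(frozen=True)
class PropertyTable:
    """Ten binary physicochemical properties over the 20 residues."""

    properties: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(_DEFAULT_PROPERTIES)
    )

    def __post_init__(self):
        props = self.properties
        if len(props) != 10:
            raise ValueError("property table must define exactly 10 properties")
        if props.get("proline") != frozenset("P"):
            raise ValueError("proline property must be {P}")
        if props.get("positive") != frozenset("HKR"):
            raise ValueError("positive property must be {H,K,R}")
        if props.get("negative") != frozenset("DE"):
            raise ValueError("negative property must be {D,E}")
        if props.get("charged") != props["positive"] | props["negative"]:
            raise ValueError("charged must be positive | negative")

    def vector(self, residue: str) -> tuple[bool, ...]:
        return tuple(residue in members for members in self.properties.values())

    def pair_score(self, a: str, b: str) -> int:
        """Number of the 10 properties on which residues a and b agree."""
        va, vb = self.vector(a), self.vector(b)
        return sum(x == y for x, y in zip(va, vb))


@dataclass
class Thresholds:
    """Anchor thresholds for motif calling.

    ``min_score``/``min_freq`` gate literal anchors (the published >= 10 /
    >= 90% rule); ``pair_min_score`` is the number of shared properties two
    residues need for a two-way-alternative anchor; ``gap_limit`` is the gap
    fraction above which a column scores 0.
    """

    min_score: int = 10
    min_freq: float = 0.90
    pair_min_score: int = 8
    gap_limit: float = 0.10

    def __post_init__(self):
        if not (0 <= self.min_score <= 11):
            raise ValueError("min_score must be in [0, 11]")
        if not (0.0 < self.min_freq <= 1.0):
            raise ValueError("min_freq must be in (0, 1]")
        if not (0.0 <= self.gap_limit < 1.0):
            raise ValueError("gap_limit must be in [0, 1)")


def column_score(
    column: Iterable[str],
    table: PropertyTable | None = None,
    gap_limit: float = 0.10,
) -> int:
    """Conservation score of one alignment column on the 0-11 scale.

    11 for an identical column, otherwise the number of properties uniformly
    present or uniformly absent across all non-gap residues; 0 when the gap
    fraction exceeds ``gap_limit`` or the column is all gaps.
    """
    table = table or PropertyTable()
    col = list(column)
    if not col:
        raise ValueError("column must be non-empty")
    residues = [c for c in col if c != "-"]
    gap_fraction = 1.0 - len(residues) / len(col)
    if not residues or gap_fraction > gap_limit:
        return 0
    distinct = set(residues)
    if len(distinct) == 1:
        return 11
    score = 0
    for members in table.properties.values():
        flags = {r in members for r in distinct}
        if len(flags) == 1:
            score += 1
    return score


@dataclass
class ColumnProfile:
    column: int
    modal_residue: str
    modal_freq: float
    top2: tuple[str, str] | None
    joint_freq: float
    gap_fraction: float
    score: int
    all_gap: bool = False


@dataclass
class ConservationProfile:
    """Per-column conservation summary of a multiple alignment."""

    entries: list[ColumnProfile]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, i: int) -> ColumnProfile:
        return self.entries[i]

    def to_frame(
        self,
        thresholds: Thresholds | None = None,
        table: PropertyTable | None = None,
        column_map=None,
    ) -> pd.DataFrame:
        thresholds = thresholds or Thresholds()
        table = table or PropertyTable()
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "column": e.column,
                    "ref_position": (
                        column_map.col_to_pos.get(e.column, "") if column_map else ""
                    ),
                    "modal_residue": e.modal_residue,
                    "modal_freq": round(e.modal_freq, 4),
                    "gap_fraction": round(e.gap_fraction, 4),
                    "score": e.score,
                    "class": classify_position(e, thresholds, table),
                }
            )
        return pd.DataFrame(rows)

    def write(self, path: str | Path, **kwargs) -> None:
        self.to_frame(**kwargs).to_csv(path, sep="\t", index=False)


def build_profile(
    msa: AlignmentMatrix,
    table: PropertyTable | None = None,
    gap_limit: float = 0.10,
) -> ConservationProfile:
    """Profile every column: modal residue/frequency (gaps count in the
    denominator), top-two residues with joint frequency, gap fraction, and
    the 0-11 conservation score."""
    table = table or PropertyTable()
    n_rows = msa.n_rows
    entries = []
    for col in range(msa.n_cols):
        column = msa.column(col)
        counts: dict[str, int] = {}
        gaps = 0
        for ch in column:
            if ch == "-":
                gaps += 1
            else:
                counts[ch] = counts.get(ch, 0) + 1
        gap_fraction = gaps / n_rows
        if not counts:
            entries.append(
                ColumnProfile(
                    column=col,
                    modal_residue="-",
                    modal_freq=0.0,
                    top2=None,
                    joint_freq=0.0,
                    gap_fraction=1.0,
                    score=0,
                    all_gap=True,
                )
            )
            continue
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        modal_residue, modal_count = ranked[0]
        top2 = None
        joint = modal_count
        if len(ranked) > 1:
            top2 = (modal_residue, ranked[1][0])
            joint = modal_count + ranked[1][1]
        entries.append(
            ColumnProfile(
                column=col,
                modal_residue=modal_residue,
                modal_freq=modal_count / n_rows,
                top2=top2,
                joint_freq=joint / n_rows,
                gap_fraction=gap_fraction,
                score=column_score(column, table, gap_limit),
            )
        )
    return ConservationProfile(entries=entries)


ANCHOR_LITERAL = "anchor-literal"
ANCHOR_PAIR = "anchor-pair"
WILDCARD_CLASS = "wildcard"


def classify_position(
    entry: ColumnProfile,
    thresholds: Thresholds | None = None,
    table: PropertyTable | None = None,
) -> str:
    """Classify a profiled column as literal anchor, pair anchor or wildcard."""
    thresholds = thresholds or Thresholds()
    table = table or PropertyTable()
    if entry.all_gap:
        return WILDCARD_CLASS
    if entry.score >= thresholds.min_score and entry.modal_freq >= thresholds.min_freq:
        return ANCHOR_LITERAL
    if (
        entry.top2 is not None
        and entry.joint_freq >= thresholds.min_freq
        and table.pair_score(*entry.top2) >= thresholds.pair_min_score
    ):
        return ANCHOR_PAIR
    return WILDCARD_CLASS


@dataclass
class MotifShape:
    """Shape limits for motif segmentation: minimum number of anchors,
    maximum run of wildcards between anchors, and overall length bounds."""

    min_anchors: int = 3
    max_wildcard_run: int = 3
    min_length: int = 5
    max_length: int = 12


def _spec_for(entry: ColumnProfile, cls: str) -> PositionSpec:
    if cls == ANCHOR_LITERAL:
        return literal(entry.modal_residue)
    if cls == ANCHOR_PAIR:
        return pair(*entry.top2)
    return WILDCARD


def call_motifs(
    profile: ConservationProfile,
    thresholds: Thresholds | None = None,
    shape: MotifShape | None = None,
    table: PropertyTable | None = None,
    name_prefix: str = "M",
) -> list[MotifPattern]:
    """Segment a classified profile into degenerate consensus motifs.

    Motifs are maximal column windows starting and ending on anchors with at
    least ``min_anchors`` anchors, at most ``max_wildcard_run`` consecutive
    wildcards, and length within the shape bounds; anchors farther apart than
    the wildcard-run limit start a new motif.  Chains longer than the length
    bound are split greedily at anchor boundaries.
    """
    thresholds = thresholds or Thresholds()
    shape = shape or MotifShape()
    table = table or PropertyTable()
    classes = [classify_position(e, thresholds, table) for e in profile]
    anchors = [i for i, c in enumerate(classes) if c != WILDCARD_CLASS]

    chains: list[list[int]] = []
    for col in anchors:
        if chains and col - chains[-1][-1] - 1 <= shape.max_wildcard_run:
            chains[-1].append(col)
        else:
            chains.append([col])

    patterns: list[MotifPattern] = []
    for chain in chains:
        idx = 0
        while idx < len(chain):
            start = chain[idx]
            window = [c for c in chain[idx:] if c - start + 1 <= shape.max_length]
            end = window[-1]
            length = end - start + 1
            if len(window) >= shape.min_anchors and length >= shape.min_length:
                positions = tuple(
                    _spec_for(profile[c], classes[c]) for c in range(start, end + 1)
                )
                patterns.append(
                    MotifPattern(
                        name=f"{name_prefix}{len(patterns) + 1}",
                        positions=positions,
                        col_span=(start, end),
                    )
                )
            idx += len(window)
    return patterns


def project_motifs(
    patterns: Sequence[MotifPattern], msa: AlignmentMatrix, row_id: str
) -> list[MotifPattern]:
    """Attach 1-based residue intervals on one alignment row to motifs whose
    boundary columns are not gaps in that row; others are returned unchanged."""
    cmap = msa.column_map(row_id)
    out = []
    for pat in patterns:
        if pat.col_span is None:
            out.append(pat)
            continue
        start_col, end_col = pat.col_span
        if start_col in cmap.col_to_pos and end_col in cmap.col_to_pos:
            from dataclasses import replace

            out.append(
                replace(
                    pat,
                    ref_span=(row_id, cmap.col_to_pos[start_col], cmap.col_to_pos[end_col]),
                )
            )
        else:
            out.append(pat)
    return out
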