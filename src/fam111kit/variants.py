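"""Protein-variant parsing, domain/motif annotation, and mutation blocks.

Variants use protein-level (HGVS p.-style) shorthand tokens: ``R569H``
(missense), ``S342del`` (deletion), ``L292fs`` (frameshift), ``K586K``
(synonymous), ``D439`` (position only), and multi-allelic forms like
``S541[Y/P]`` or ``V357[I/fs]`` which expand to one record per alternative.
Disease-associated variants of FAM111A cluster in two positional blocks; the
annotation layer maps each variant onto domains (PIP box, UBL2/DBD, serine
protease domain), called motifs, the S1 pocket, and the catalytic triad, and
verifies every published residue annotation against the reference sequence.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .motifs import MotifCall
from .seqio import SequenceRecord, read_fasta

MISSENSE = "missense"
DELETION = "deletion"
FRAMESHIFT = "frameshift"
SYNONYMOUS = "synonymous"
POSITION_ONLY = "position_only"


class VariantParseError(ValueError):
    def __init__(self, token: str, why: str = ""):
        self.token = token
        super().__init__(f"cannot parse variant token {token!r}" + (f": {why}" if why else ""))


@dataclass(frozen=True)
class VariantRecord:
    """One parsed protein variant (one alternative of a table row)."""

    raw: str
    ref_residue: str
    position: int
    kind: str
    alt_residue: str = ""
    region_labels: tuple[str, ...] = ()
    disease_labels: tuple[str, ...] = ()
    clinvar_flag: bool = False
    row_index: int | None = None

    def __post_init__(self):
        if self.position < 1:
            raise VariantParseError(self.raw, "position must be >= 1")
        if self.kind == MISSENSE and not self.alt_residue:
            raise VariantParseError(self.raw, "missense needs an alternative residue")
        if self.kind == SYNONYMOUS and self.alt_residue != self.ref_residue:
            raise VariantParseError(self.raw, "synonymous must have alt == ref")


_CORE_RE = re.compile(r"^([A-Z])(\d+)\s*(.*)$")
_MULTI_RE = re.compile(r"^\[([^\[\]]+)\]$")


def _one(token: str, ref: str, pos: int, alt_tok: str) -> VariantRecord:
    if alt_tok == "del":
        return VariantRecord(raw=token, ref_residue=ref, position=pos, kind=DELETION)
    if alt_tok == "fs":
        return VariantRecord(raw=token, ref_residue=ref, position=pos, kind=FRAMESHIFT)
    if re.fullmatch(r"[A-Z]", alt_tok):
        kind = SYNONYMOUS if alt_tok == ref else MISSENSE
        return VariantRecord(
            raw=token, ref_residue=ref, position=pos, kind=kind, alt_residue=alt_tok
        )
    raise VariantParseError(token, f"unknown alternative {alt_tok!r}")


def parse_variant(token: str) -> list[VariantRecord]:
    """Parse one variant token into one record per alternative.

    Grammar: ``REF POS (ALT | [A/B/...] | del | fs | nothing)`` with
    single-letter residues; a bare ``REF POS`` is position-only.
    """
    core = token.strip().rstrip("*").strip()
    m = _CORE_RE.match(core)
    if not m:
        raise VariantParseError(token)
    ref, pos, rest = m.group(1), int(m.group(2)), m.group(3).strip()
    if not rest:
        return [VariantRecord(raw=token, ref_residue=ref, position=pos, kind=POSITION_ONLY)]
    multi = _MULTI_RE.match(rest)
    if multi:
        alts = [a.strip() for a in multi.group(1).split("/")]
        if not alts or any(not a for a in alts):
            raise VariantParseError(token)
        return [_one(token, ref, pos, a) for a in alts]
    return [_one(token, ref, pos, rest)]


def format_variant(records: Sequence[VariantRecord]) -> str:
    """Render one or more records for the same site back to a token."""
    if not records:
        raise ValueError("no records to format")
    ref = records[0].ref_residue
    pos = records[0].position
    if any(r.ref_residue != ref or r.position != pos for r in records):
        raise ValueError("records do not share a site")

    def alt_of(r: VariantRecord) -> str:
        if r.kind == DELETION:
            return "del"
        if r.kind == FRAMESHIFT:
            return "fs"
        if r.kind == POSITION_ONLY:
            return ""
        return r.alt_residue

    alts = [alt_of(r) for r in records]
    if len(alts) == 1:
        return f"{ref}{pos}{alts[0]}"
    return f"{ref}{pos}[{'/'.join(alts)}]"


def load_variant_table(path: str | Path) -> list[VariantRecord]:
    """Load a tab-separated variant table (index, token, regions, diseases).

    Region and disease strings split on '|'; a '*' suffix on the token sets
    the ClinVar uncertainty flag.  Multi-allelic tokens expand to one record
    per alternative, all sharing the row index.
    """
    try:
        table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    except pd.errors.EmptyDataError:
        return []
    records: list[VariantRecord] = []
    for row in table.itertuples(index=False):
        token = row.token.strip()
        flag = token.rstrip().endswith("*")
        regions = tuple(x.strip() for x in str(row.regions).split("|") if x.strip())
        diseases = tuple(x.strip() for x in str(row.diseases).split("|") if x.strip())
        for rec in parse_variant(token):
            records.append(
                replace(
                    rec,
                    region_labels=regions,
                    disease_labels=diseases,
                    clinvar_flag=flag,
                    row_index=int(row.index),
                )
            )
    return records


def write_variant_table(rows: pd.DataFrame, path: str | Path) -> None:
    rows.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# domain map


@dataclass(frozen=True)
class DomainMap:
    """Named closed intervals and point annotations on 1-based coordinates."""

    intervals: dict[str, tuple[int, int]]
    points: dict[str, dict[int, str]]
    cleavage_site: tuple[int, int] | None = None

    def domains_at(self, position: int) -> list[str]:
        return [
            name
            for name, (lo, hi) in self.intervals.items()
            if lo <= position <= hi
        ]


def fam111a_domain_map() -> DomainMap:
    """The human FAM111A domain map: PIP box 16-28, UBL2/DBD central region
    176-282, serine protease domain 332-600; catalytic triad H385/D439/S541,
    oxyanion hole G539/S541, S1-pocket residues, cleavage site F334|G335."""
    return DomainMap(
        intervals={
            "PIP": (16, 28),
            "UBL2/DBD": (176, 282),
            "SPD": (332, 600),
        },
        points={
            "catalytic_triad": {385: "H", 439: "D", 541: "S"},
            "oxyanion_hole": {539: "G", 541: "S"},
            "cleavage_site": {334: "F", 335: "G"},
            "s1_pocket": {
                369: "Y", 385: "H", 439: "D", 536: "F", 537: "F", 538: "F",
                541: "S", 556: "H", 557: "A", 558: "A", 559: "G", 560: "F",
                573: "E", 574: "F",
            },
        },
        cleavage_site=(334, 335),
    )


@dataclass
class MutationBlock:
    """A positional cluster of variants along the protein."""

    name: str
    members: list[VariantRecord]
    span: tuple[int, int]
    method: str

    def __post_init__(self):
        lo, hi = self.span
        if self.members and not all(lo <= v.position <= hi for v in self.members):
            raise ValueError(f"block {self.name}: span does not cover members")


def detect_blocks(
    variants: Sequence[VariantRecord],
    method: str = "labels",
    window: int = 60,
    min_count: int = 5,
) -> list[MutationBlock]:
    """Cluster variants into mutation blocks.

    labels mode: one block per distinct "Mutation Block" region label, with
    span from member positions.  density mode: sliding windows of width
    ``window`` holding at least ``min_count`` distinct variant sites qualify,
    and overlapping qualifying windows merge.
    """
    if method == "labels":
        groups: dict[str, list[VariantRecord]] = {}
        for v in variants:
            for lab in v.region_labels:
                if lab.lower().startswith("mutation block"):
                    groups.setdefault(lab, []).append(v)
        blocks = []
        for lab in sorted(groups):
            members = groups[lab]
            pos = [v.position for v in members]
            blocks.append(
                MutationBlock(
                    name=lab, members=members, span=(min(pos), max(pos)), method="labels"
                )
            )
        return blocks
    if method == "density":
        sites = sorted({v.position for v in variants})
        if not sites:
            return []
        qualifying: list[tuple[int, int]] = []
        for start in sites:
            end = start + window - 1
            count = sum(1 for s in sites if start <= s <= end)
            if count >= min_count:
                qualifying.append((start, end))
        merged: list[list[int]] = []
        for lo, hi in qualifying:
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        blocks = []
        for i, (lo, hi) in enumerate(merged, 1):
            members = [v for v in variants if lo <= v.position <= hi]
            pos = [v.position for v in members]
            blocks.append(
                MutationBlock(
                    name=f"D{i}",
                    members=members,
                    span=(min(pos), max(pos)),
                    method="density",
                )
            )
        return blocks
    raise ValueError(f"unknown block detection method {method!r}")


def annotate_variants(
    variants: Sequence[VariantRecord],
    dmap: DomainMap,
    calls: Sequence[MotifCall] = (),
) -> pd.DataFrame:
    """Annotate each variant with computed domain/motif/pocket context.

    Adds the containing domains, containing motif calls, S1-pocket flag and
    distance to the nearest catalytic-triad residue, plus an informational
    discordance column comparing computed domains against the table's
    printed region labels (printed labels are never silently corrected).
    """
    triad = sorted(dmap.points.get("catalytic_triad", {}))
    pocket = set(dmap.points.get("s1_pocket", {}))
    rows = []
    for v in variants:
        domains = dmap.domains_at(v.position)
        in_motifs = sorted(
            {c.pattern_name for c in calls if c.contains(v.position)}
        )
        printed_domains = [
            lab for lab in v.region_labels if lab in dmap.intervals
        ]
        discordant = sorted(set(printed_domains) - set(domains))
        rows.append(
            {
                "row_index": v.row_index,
                "token": v.raw,
                "position": v.position,
                "kind": v.kind,
                "ref": v.ref_residue,
                "alt": v.alt_residue,
                "domains": "|".join(domains),
                "motif_calls": "|".join(in_motifs),
                "in_s1_pocket": v.position in pocket,
                "triad_distance": (
                    min(abs(v.position - t) for t in triad) if triad else ""
                ),
                "printed_regions": "|".join(v.region_labels),
                "domain_discordance": "|".join(discordant),
                "diseases": "|".join(v.disease_labels),
                "clinvar_flag": v.clinvar_flag,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class VerificationReport:
    """Residue-level checks of annotations against a reference sequence."""

    frame: pd.DataFrame

    @property
    def n_checks(self) -> int:
        return len(self.frame)

    @property
    def n_passed(self) -> int:
        return int(self.frame["passed"].sum())

    @property
    def all_passed(self) -> bool:
        return bool(self.frame["passed"].all())

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# verification: {self.n_passed}/{self.n_checks} checks passed\n"
            )
            self.frame.to_csv(fh, sep="\t", index=False)


def verify_annotations(
    seq: SequenceRecord,
    dmap: DomainMap,
    variants: Sequence[VariantRecord] = (),
) -> VerificationReport:
    """Check every point annotation and variant reference residue against a
    sequence.  Mismatches are reported, never raised."""
    rows = []

    def check(group: str, label: str, pos: int, expected: str):
        observed = seq.residues[pos - 1] if 1 <= pos <= seq.length else ""
        rows.append(
            {
                "group": group,
                "check": label,
                "position": pos,
                "expected": expected,
                "observed": observed,
                "passed": observed == expected,
            }
        )

    for group in sorted(dmap.points):
        for pos in sorted(dmap.points[group]):
            check(group, f"{group}@{pos}", pos, dmap.points[group][pos])
    seen = set()
    for v in variants:
        if v.ref_residue and (v.position, v.ref_residue) not in seen:
            seen.add((v.position, v.ref_residue))
            check("variant_ref", f"{v.ref_residue}{v.position}", v.position, v.ref_residue)
    return VerificationReport(frame=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# bundled fixtures


def load_reference_variants() -> list[VariantRecord]:
    """The bundled FAM111A pathogenic/crucial variant table (34 rows)."""
    path = resources.files("fam111kit.data").joinpath("fam111a_pathogenic_variants.tsv")
    with resources.as_file(path) as p:
        return load_variant_table(p)


def load_reference_sequence() -> SequenceRecord:
    """The bundled human FAM111A reference.

    This is a synthetic surrogate sequence (constructed to carry every
    published residue annotation at its published coordinate), not the
    database record; see the FASTA header and the methods note.
    """
    path = resources.files("fam111kit.data").joinpath(
        "fam111a_reference_synthetic.fasta"
    )
    with resources.as_file(path) as p:
        return read_fasta(p)[0]
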