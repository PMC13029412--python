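"""Reading, filtering, dereplicating and summarizing protein datasets.

The curation stage mirrors how a comparative analysis of a protein family is
set up from a database dump: drop entries whose descriptions flag them as
unreliable (synthetic / hypothetical / partial / low quality / predicted),
then collapse near-identical sequences within each taxonomic class to a
single representative, and summarize the class composition of what is left.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")

DEFAULT_EXCLUSION_KEYWORDS = (
    "synthetic",
    "hypothetical",
    "partial",
    "low quality",
    "predicted",
)


class FastaParseError(ValueError):
    """Malformed FASTA input (empty entry, duplicate id, bad residues)."""


class TaxonomyError(KeyError):
    """A sequence id has no taxonomy entry."""

    def __init__(self, missing_ids: Sequence[str]):
        self.missing_ids = list(missing_ids)
        super().__init__(f"missing taxonomy for ids: {', '.join(self.missing_ids)}")


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with parsed NCBI-style header metadata."""

    id: str
    description: str
    organism: str
    residues: str

    def __post_init__(self):
        bad = set(self.residues) - ALPHABET
        if bad:
            raise FastaParseError(
                f"record {self.id!r}: residues outside the amino-acid alphabet: "
                f"{sorted(bad)}"
            )
        if not self.residues:
            raise FastaParseError(f"record {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TaxonomyRecord:
    id: str
    species: str
    class_label: str


@dataclass
class CurationConfig:
    """Keyword exclusion and per-class redundancy-reduction settings."""

    exclusion_keywords: tuple[str, ...] = DEFAULT_EXCLUSION_KEYWORDS
    identity_threshold: float = 0.97
    per_class: bool = True

    def __post_init__(self):
        if not (0.0 < self.identity_threshold <= 1.0):
            raise ValueError("identity_threshold must be in (0, 1]")
        self.exclusion_keywords = tuple(k.lower() for k in self.exclusion_keywords)


_ORGANISM_RE = re.compile(r"\[([^\[\]]+)\]\s*$")


def _parse_header(header_id: str, description: str) -> tuple[str, str]:
    """Extract (description, organism) from an NCBI-style description line.

    The organism is the bracketed trailing token when present, else empty.
    """
    m = _ORGANISM_RE.search(description)
    organism = m.group(1).strip() if m else ""
    return description, organism


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, order preserved.

    Raises FastaParseError on an empty entry or a duplicated id.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FastaParseError(f"duplicate id in {path}: {entry.id!r}")
        seen.add(entry.id)
        residues = str(entry.seq).upper().replace("-", "")
        if not residues:
            raise FastaParseError(f"empty sequence for header {entry.description!r}")
        description, organism = _parse_header(entry.id, entry.description)
        records.append(
            SequenceRecord(
                id=entry.id,
                description=description,
                organism=organism,
                residues=residues,
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description.startswith(rec.id) else (
                f"{rec.id} {rec.description}".strip()
            )
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_taxonomy(path: str | Path) -> dict[str, TaxonomyRecord]:
    """Read the 3-column tab-separated taxonomy table (id, species, class)."""
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    expected = ["id", "species", "class_label"]
    if list(table.columns[:3]) != expected:
        raise ValueError(f"taxonomy table must have columns {expected}")
    out: dict[str, TaxonomyRecord] = {}
    for row in table.itertuples(index=False):
        out[row.id] = TaxonomyRecord(id=row.id, species=row.species, class_label=row.class_label)
    return out


def write_taxonomy(taxonomy: dict[str, TaxonomyRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tspecies\tclass_label\n")
        for rec in taxonomy.values():
            fh.write(f"{rec.id}\t{rec.species}\t{rec.class_label}\n")


def filter_by_keywords(
    records: Sequence[SequenceRecord], cfg: CurationConfig | None = None
) -> list[SequenceRecord]:
    """Drop records whose description contains any exclusion keyword.

    Matching is case-insensitive substring matching on the description only.
    """
    cfg = cfg or CurationConfig()
    kept = []
    for rec in records:
        desc = rec.description.lower()
        if any(kw in desc for kw in cfg.exclusion_keywords):
            continue
        kept.append(rec)
    return kept


def pairwise_identity(a: SequenceRecord, b: SequenceRecord, params=None) -> float:
    """Fraction of identical residue pairs on the optimal global alignment.

    The denominator counts aligned residue pairs only (columns where both
    sequences have a residue); gap columns are excluded.  Symmetric.
    """
    from .align import AlignmentParams, global_align

    if not a.residues or not b.residues:
        raise ValueError("pairwise_identity requires non-empty sequences")
    params = params or AlignmentParams()
    _, ga, gb = global_align(a.residues, b.residues, params)
    matches = 0
    pairs = 0
    for x, y in zip(ga, gb):
        if x != "-" and y != "-":
            pairs += 1
            if x == y:
                matches += 1
    return matches / pairs if pairs else 0.0


@dataclass
class DereplicationResult:
    representatives: list[SequenceRecord]
    cluster_table: pd.DataFrame  # columns: member_id, representative_id

    def write_cluster_table(self, path: str | Path) -> None:
        self.cluster_table.to_csv(path, sep="\t", index=False)


def dereplicate(
    records: Sequence[SequenceRecord],
    taxonomy: dict[str, TaxonomyRecord],
    cfg: CurationConfig | None = None,
    params=None,
) -> DereplicationResult:
    """Greedy within-class identity clustering, keeping cluster founders.

    Records are processed longest-first (ties broken by id) so the longest
    isoform founds, and therefore represents, each cluster.  A record joins
    the first cluster whose representative it matches above the identity
    threshold; clustering never crosses class boundaries.
    """
    cfg = cfg or CurationConfig()
    missing = [r.id for r in records if r.id not in taxonomy]
    if missing:
        raise TaxonomyError(missing)

    by_class: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        key = taxonomy[rec.id].class_label if cfg.per_class else ""
        by_class.setdefault(key, []).append(rec)

    assignments: dict[str, str] = {}
    representatives: list[SequenceRecord] = []
    for key in sorted(by_class):
        members = sorted(by_class[key], key=lambda r: (-r.length, r.id))
        reps: list[SequenceRecord] = []
        for rec in members:
            home = None
            for rep in reps:
                if pairwise_identity(rec, rep, params) > cfg.identity_threshold:
                    home = rep
                    break
            if home is None:
                reps.append(rec)
                assignments[rec.id] = rec.id
            else:
                assignments[rec.id] = home.id
        representatives.extend(reps)

    # restore input order for representatives and the cluster table
    rep_ids = {r.id for r in representatives}
    representatives = [r for r in records if r.id in rep_ids]
    table = pd.DataFrame(
        {
            "member_id": [r.id for r in records],
            "representative_id": [assignments[r.id] for r in records],
        }
    )
    return DereplicationResult(representatives=representatives, cluster_table=table)


def summarize_composition(
    representatives: Sequence[SequenceRecord],
    taxonomy: dict[str, TaxonomyRecord],
) -> pd.DataFrame:
    """Per-class counts and integer-rounded percentages of a dataset."""
    if not representatives:
        return pd.DataFrame(columns=["class_label", "count", "percent"])
    labels = [taxonomy[r.id].class_label for r in representatives]
    counts = pd.Series(labels).value_counts().sort_index()
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "class_label": counts.index,
            "count": counts.to_numpy(),
            "percent": [round(100 * c / total) for c in counts],
        }
    ).reset_index(drop=True)
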