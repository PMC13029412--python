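"""Synthetic protein families with known trees and planted conserved motifs.

The generator emulates the structure of a real cross-phylum protein family:
a clade-structured ultrametric tree (one subtree per taxonomic class, so
class monophyly holds by construction), a conserved core of planted motifs
embedded in variable regions, and indels confined to the variable regions so
that long alignment gaps appear outside the core.  Planted literal columns
keep one residue at >= 90% frequency (any deviants are drawn from that
residue's physicochemical equivalence class, so the column keeps its
conservation score); planted pair columns alternate between two compatible
residues only.  Pattern pairs whose residues are physicochemically
incompatible are planted as their first residue.  Every family ships with a
truth object: the generating tree, the true alignment, and per-taxon motif
spans, so each pipeline stage can be scored against ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .align import AlignmentMatrix
from .conservation import PropertyTable, Thresholds
from .motifs import MotifPattern
from .phylogeny import TreeNode
from .seqio import AMINO_ACIDS, SequenceRecord, TaxonomyRecord
from .variants import parse_variant

DEFAULT_CLASS_STRUCTURE = (
    ("Mammalia", 21),
    ("Actinopterygii", 11),
    ("Reptilia", 7),
    ("Cnidaria", 1),
)


@dataclass
class FamilySpec:
    """Parameters of one simulated family.  The defaults describe a
    40-taxon, four-class family (class proportions mirroring a typical
    metazoan protein-family dataset) of ~360-residue proteins carrying the
    seven reference motifs in a conserved core."""

    seed: int
    class_structure: tuple[tuple[str, int], ...] = DEFAULT_CLASS_STRUCTURE
    tree_height: float = 1.0
    root_length: int = 360
    planted_motifs: tuple[tuple[int, MotifPattern], ...] = ()
    substitution_rate: float = 1.5  # substitutions per site per unit height
    indel_rate: float = 0.02  # indel events per site per unit height
    indel_length_mean: float = 3.0
    long_indel_prob: float = 0.08
    long_indel_range: tuple[int, int] = (20, 60)
    max_deviant_frac: float = 0.10
    scramble_classes: bool = False

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.substitution_rate < 0 or self.indel_rate < 0:
            raise ValueError("rates must be nonnegative")
        if not self.planted_motifs:
            # Motifs sit in a conserved core spanning the middle ~55% of the
            # root sequence, mirroring a family whose terminal regions are
            # variable and gappy while the core carries the motifs.
            from .motifs import reference_motifs

            mots = reference_motifs()
            core_start = int(self.root_length * 0.30)
            core_end = int(self.root_length * 0.85)
            total = sum(len(m) for m in mots)
            gap = (core_end - core_start - total) // (len(mots) + 1)
            placed = []
            cursor = core_start + gap
            for m in mots:
                placed.append((cursor, m))
                cursor += len(m) + gap
            self.planted_motifs = tuple(placed)
        last_end = -10
        for pos, m in sorted(self.planted_motifs):
            if pos <= last_end + 4:
                raise ValueError("planted motifs must be non-overlapping and spaced")
            if pos + len(m) - 1 > self.root_length:
                raise ValueError("planted motif extends beyond the root sequence")
            last_end = pos + len(m) - 1

    @property
    def n_taxa(self) -> int:
        return sum(c for _, c in self.class_structure)


def default_family_spec(seed: int = 17) -> FamilySpec:
    return FamilySpec(seed=seed)


@dataclass
class FamilyTruth:
    """Ground truth emitted with every simulated family."""

    tree: TreeNode
    alignment: AlignmentMatrix  # the true alignment
    records: list[SequenceRecord]
    taxonomy: dict[str, TaxonomyRecord]
    motif_spans: dict[str, dict[str, tuple[int, int]]]  # taxon -> motif -> span
    planted_patterns: list[MotifPattern]

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        rows = []
        for taxon in sorted(self.motif_spans):
            for motif, (lo, hi) in sorted(self.motif_spans[taxon].items()):
                rows.append({"taxon": taxon, "motif": motif, "start": lo, "end": hi})
        pd.DataFrame(rows).to_csv(outdir / "truth_motif_spans.tsv", sep="\t", index=False)
        from .phylogeny import write_newick

        write_newick(self.tree, outdir / "truth_tree.nwk")
        self.alignment.write_fasta(outdir / "truth_alignment.fasta")


def _coalescent(
    leaves: list[TreeNode], lo: float, hi: float, rng: np.random.Generator
) -> TreeNode:
    """Random sequential pairing at sorted heights in (lo, hi]; ultrametric."""
    nodes = list(leaves)
    k = len(nodes) - 1
    if k == 0:
        return nodes[0]
    heights = np.sort(rng.uniform(lo, hi, size=k))
    for h in heights:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        h = max(h, a.height, b.height)  # keep parent above children
        nodes.append(TreeNode(label=None, children=(a, b), height=float(h)))
    return nodes[0]


def simulate_tree(spec: FamilySpec) -> TreeNode:
    """Ultrametric class-structured tree: one subtree per class, classes
    joined above all within-class nodes, root at ``tree_height``."""
    if spec.n_taxa < 2:
        raise ValueError("need at least two taxa")
    rng = np.random.default_rng([spec.seed, 11])
    class_roots = []
    for label, count in spec.class_structure:
        leaves = [
            TreeNode(label=f"{label}_{i + 1:02d}", height=0.0) for i in range(count)
        ]
        class_roots.append(
            _coalescent(leaves, 0.05 * spec.tree_height, 0.45 * spec.tree_height, rng)
        )
    if len(class_roots) == 1:
        return class_roots[0]
    root = _coalescent(
        class_roots, 0.55 * spec.tree_height, spec.tree_height, rng
    )
    return root


def _position_modes(spec: FamilySpec, table: PropertyTable, pair_min_score: int):
    """Per root-column: ('free',), ('wild', motif, k), ('lit', motif, k, res,
    partner-or-None), or ('pair', motif, k, a, b)."""
    modes: dict[int, tuple] = {}
    eq_partner = {}
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            if a != b and table.pair_score(a, b) == 10:
                eq_partner[a] = b
    for pos, motif in spec.planted_motifs:
        for k, p in enumerate(motif.positions):
            col = pos - 1 + k  # 0-based root column
            if p.is_wildcard:
                modes[col] = ("wild", motif.name, k)
            elif p.kind == "pair" and table.pair_score(*p.residues) >= pair_min_score:
                modes[col] = ("pair", motif.name, k, p.residues[0], p.residues[1])
            else:
                res = p.residues[0]
                modes[col] = ("lit", motif.name, k, res, eq_partner.get(res))
    return modes


def evolve_family(
    spec: FamilySpec,
) -> tuple[list[SequenceRecord], dict[str, TaxonomyRecord], FamilyTruth]:
    """Evolve a family down the class tree with planted-motif constraints.

    Substitutions act freely outside motifs, toggle within the pair at pair
    positions, and at literal positions touch at most ``max_deviant_frac`` of
    the taxa and only within the residue's physicochemical equivalence
    class.  Indels never enter motif columns.  The emitted truth alignment
    de-gaps to the emitted sequences exactly.
    """
    table = PropertyTable()
    thresholds = Thresholds()
    tree = simulate_tree(spec)
    rng = np.random.default_rng([spec.seed, 23])
    L = spec.root_length
    modes = _position_modes(spec, table, thresholds.pair_min_score)
    aa = list(AMINO_ACIDS)

    # root sequence over column ids 0..L-1
    master_order: list[int] = list(range(L))
    next_id = L
    root_seq: dict[int, str] = {}
    for col in range(L):
        mode = modes.get(col, ("free",))
        if mode[0] == "lit":
            root_seq[col] = mode[3]
        elif mode[0] == "pair":
            root_seq[col] = mode[3]
        else:
            root_seq[col] = aa[rng.integers(0, 20)]
    motif_cols = set(modes)
    # conserved core: long indels act only outside it, like the long
    # terminal gaps of the family being emulated
    core_lo = min(motif_cols) if motif_cols else 0
    core_hi = max(motif_cols) if motif_cols else -1
    core_cols = set(range(core_lo, core_hi + 1))

    n_taxa = spec.n_taxa
    max_dev = int(np.floor(spec.max_deviant_frac * n_taxa))
    leaf_names = tree.leaf_labels()
    deviants: dict[int, set[str]] = {}
    for col, mode in modes.items():
        if (
            mode[0] == "lit"
            and mode[4] is not None
            and max_dev > 0
            and spec.substitution_rate > 0
        ):
            k = int(min(rng.binomial(n_taxa, 0.05), max_dev))
            if k:
                chosen = rng.choice(len(leaf_names), size=k, replace=False)
                deviants[col] = {leaf_names[i] for i in chosen}

    leaf_seqs: dict[str, dict[int, str]] = {}

    def substitute(seq: dict[int, str], t: float) -> None:
        p = 1.0 - np.exp(-spec.substitution_rate * t)
        for col in list(seq):
            mode = modes.get(col, ("free",))
            if mode[0] == "lit":
                continue
            if rng.random() >= p:
                continue
            if mode[0] == "pair":
                a, b = mode[3], mode[4]
                seq[col] = b if seq[col] == a else a
            else:
                current = seq[col]
                choices = [r for r in aa if r != current]
                seq[col] = choices[rng.integers(0, 19)]

    def apply_indels(seq: dict[int, str], t: float) -> None:
        nonlocal next_id
        n_free = sum(1 for c in seq if c not in motif_cols)
        lam = spec.indel_rate * t * n_free
        n_events = rng.poisson(lam)
        for _ in range(n_events):
            is_long = bool(spec.long_indel_prob) and rng.random() < spec.long_indel_prob
            if is_long:
                lo, hi = spec.long_indel_range
                length = int(rng.integers(lo, hi + 1))
            else:
                length = int(rng.geometric(1.0 / spec.indel_length_mean))
            candidates = [
                c
                for c in master_order
                if c in seq
                and c not in motif_cols
                and not (is_long and c in core_cols)
            ]
            if not candidates:
                continue
            if rng.random() < 0.5:  # deletion of a contiguous eligible run
                start_col = candidates[int(rng.integers(0, len(candidates)))]
                idx = master_order.index(start_col)
                removed = 0
                while idx < len(master_order) and removed < length:
                    col = master_order[idx]
                    if col in motif_cols or (is_long and col in core_cols):
                        break
                    if col in seq:
                        del seq[col]
                        removed += 1
                    idx += 1
            else:  # insertion of fresh columns after an eligible column
                anchor = candidates[int(rng.integers(0, len(candidates)))]
                at = master_order.index(anchor) + 1
                new_ids = list(range(next_id, next_id + length))
                next_id += length
                master_order[at:at] = new_ids
                for cid in new_ids:
                    seq[cid] = aa[rng.integers(0, 20)]
                    if anchor in core_cols:
                        core_cols.add(cid)

    def descend(node: TreeNode, seq: dict[int, str], parent_height: float) -> None:
        t = parent_height - node.height
        seq = dict(seq)
        if t > 0:
            substitute(seq, t)
            apply_indels(seq, t)
        if node.is_leaf:
            for col, who in deviants.items():
                if node.label in who:
                    mode = modes[col]
                    seq[col] = mode[4]  # equivalence-class partner
            leaf_seqs[node.label] = seq
            return
        for child in node.children:
            descend(child, seq, node.height)

    descend(tree, root_seq, tree.height)

    # assemble outputs in tree leaf order
    taxonomy: dict[str, TaxonomyRecord] = {}
    if spec.scramble_classes:
        labels = [lab for lab, cnt in spec.class_structure for _ in range(cnt)]
        perm = np.random.default_rng([spec.seed, 31]).permutation(len(labels))
        scrambled = {leaf_names[i]: labels[perm[i]] for i in range(len(leaf_names))}
    rows, ids, records = [], [], []
    motif_spans: dict[str, dict[str, tuple[int, int]]] = {}
    motif_col_ranges = {
        m.name: (pos - 1, pos - 1 + len(m) - 1) for pos, m in spec.planted_motifs
    }
    for name in leaf_names:
        seq = leaf_seqs[name]
        row = "".join(seq.get(c, "-") for c in master_order)
        rows.append(row)
        ids.append(name)
        residues = row.replace("-", "")
        records.append(
            SequenceRecord(
                id=name,
                description=f"{name} simulated family member",
                organism=name.rsplit("_", 1)[0],
                residues=residues,
            )
        )
        cls = name.rsplit("_", 1)[0]
        if spec.scramble_classes:
            cls = scrambled[name]
        taxonomy[name] = TaxonomyRecord(id=name, species=name, class_label=cls)
        # residue positions of motif spans in this taxon
        pos_of: dict[int, int] = {}
        p = 0
        for c in master_order:
            if c in seq:
                p += 1
                pos_of[c] = p
        spans = {}
        for mname, (c0, c1) in motif_col_ranges.items():
            spans[mname] = (pos_of[c0], pos_of[c1])
        motif_spans[name] = spans

    truth = FamilyTruth(
        tree=tree,
        alignment=AlignmentMatrix(row_ids=ids, rows=rows),
        records=records,
        taxonomy=taxonomy,
        motif_spans=motif_spans,
        planted_patterns=[m for _, m in spec.planted_motifs],
    )
    return records, taxonomy, truth


def recovered_planted_spans(
    truth: FamilyTruth,
    called: Sequence[MotifPattern],
    msa: AlignmentMatrix,
    ref_taxon: str | None = None,
) -> dict[str, bool]:
    """Which planted motifs does a set of called motifs recover exactly?

    A planted motif counts as recovered when some called motif's column span,
    projected onto the reference taxon's residue coordinates, equals the
    planted span for that taxon."""
    ref_taxon = ref_taxon or truth.alignment.row_ids[0]
    cmap = msa.column_map(ref_taxon)
    called_spans = set()
    for pat in called:
        if pat.col_span is None:
            continue
        c0, c1 = pat.col_span
        if c0 in cmap.col_to_pos and c1 in cmap.col_to_pos:
            called_spans.add((cmap.col_to_pos[c0], cmap.col_to_pos[c1]))
    return {
        mname: (span in called_spans)
        for mname, span in truth.motif_spans[ref_taxon].items()
    }


def make_variant_fixture(
    seq_length: int,
    n_variants: int,
    block_spans: Sequence[tuple[int, int]],
    seed: int,
    sequence: str | None = None,
) -> pd.DataFrame:
    """A random variant table in the bundled-table format.

    Positions concentrate inside the given block spans; tokens cover all
    variant kinds and round-trip through the parser.  When ``sequence`` is
    given, reference residues are read from it so residue verification
    passes against that sequence."""
    rng = np.random.default_rng([seed, 47])
    aa = list(AMINO_ACIDS)
    rows = []
    kinds = ["missense", "missense", "missense", "del", "fs", "multi", "syn", "pos"]
    for i in range(1, n_variants + 1):
        lo, hi = block_spans[int(rng.integers(0, len(block_spans)))]
        pos = int(rng.integers(lo, hi + 1))
        ref = sequence[pos - 1] if sequence else aa[rng.integers(0, 20)]
        kind = kinds[int(rng.integers(0, len(kinds)))]
        if kind == "missense":
            alt = aa[rng.integers(0, 20)]
            while alt == ref:
                alt = aa[rng.integers(0, 20)]
            token = f"{ref}{pos}{alt}"
        elif kind == "del":
            token = f"{ref}{pos}del"
        elif kind == "fs":
            token = f"{ref}{pos}fs"
        elif kind == "syn":
            token = f"{ref}{pos}{ref}"
        elif kind == "pos":
            token = f"{ref}{pos}"
        else:
            a1 = aa[rng.integers(0, 20)]
            while a1 == ref:
                a1 = aa[rng.integers(0, 20)]
            a2 = aa[rng.integers(0, 20)]
            while a2 in (ref, a1):
                a2 = aa[rng.integers(0, 20)]
            token = f"{ref}{pos}[{a1}/{a2}]"
        parse_variant(token)  # grammar closure
        block_name = f"Mutation Block {1 + next(j for j, (l, h) in enumerate(block_spans) if l <= pos <= h)}"
        rows.append(
            {
                "index": i,
                "token": token,
                "regions": block_name,
                "diseases": "Simulated",
            }
        )
    return pd.DataFrame(rows, columns=["index", "token", "regions", "diseases"])
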