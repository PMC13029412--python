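"""Independent oracles used by the test suite.

Each oracle recomputes an expected value by a route independent of the
implementation it checks: exhaustive enumeration for global alignment, a
separately transcribed property table with plain set logic for conservation
scores, and compiled regular expressions for motif scanning.
"""
import math
import re

# independently transcribed physicochemical property assignments
ORACLE_PROPERTIES = {
    "hydrophobic": set("ILVCAGMFYWHKT"),
    "polar": set("YWHKREQDNSTC"),
    "small": set("VCAGDNSTP"),
    "proline": set("P"),
    "tiny": set("AGS"),
    "aliphatic": set("ILV"),
    "aromatic": set("FYWH"),
    "positive": set("HKR"),
    "negative": set("DE"),
    "charged": set("HKRDE"),
}


def oracle_column_score(column, gap_limit=0.10):
    """Brute-force 0-11 column score from the transcribed property table."""
    col = list(column)
    residues = [c for c in col if c != "-"]
    if not residues or (len(col) - len(residues)) / len(col) > gap_limit:
        return 0
    if len(set(residues)) == 1:
        return 11
    score = 0
    for members in ORACLE_PROPERTIES.values():
        states = {r in members for r in set(residues)}
        if len(states) == 1:
            score += 1
    return score


def brute_force_global_score(a, b, matrix, gap_open, gap_extend):
    """Exhaustive enumeration over all monotone global alignments.

    A gap run of length k costs gap_open + (k-1)*gap_extend; gap runs in
    different sequences each open.  Exponential: for short sequences only.
    """
    best = [-math.inf]

    def rec(i, j, prev, acc):
        if i == len(a) and j == len(b):
            if acc > best[0]:
                best[0] = acc
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", acc + matrix[a[i], b[j]])
        if i < len(a):
            rec(i + 1, j, "A", acc + (gap_extend if prev == "A" else gap_open))
        if j < len(b):
            rec(i, j + 1, "B", acc + (gap_extend if prev == "B" else gap_open))

    rec(0, 0, "M", 0.0)
    return best[0]


def score_gapped_pair(ga, gb, matrix, gap_open, gap_extend):
    """Score a realized pairwise alignment (affine gaps, both-terminal)."""
    score = 0.0
    prev = "M"
    for x, y in zip(ga, gb):
        if x == "-" and y == "-":
            raise ValueError("double-gap column")
        if x == "-":
            score += gap_extend if prev == "A" else gap_open
            prev = "A"
        elif y == "-":
            score += gap_extend if prev == "B" else gap_open
            prev = "B"
        else:
            score += matrix[x, y]
            prev = "M"
    return score


def pattern_regex(pattern):
    """Compile a MotifPattern into an overlap-aware regex oracle."""
    parts = []
    for p in pattern.positions:
        if p.kind == "literal":
            parts.append(re.escape(p.residues[0]))
        elif p.kind == "pair":
            parts.append("[" + "".join(p.residues) + "]")
        else:
            parts.append(".")
    return re.compile("(?=(" + "".join(parts) + "))")


def regex_scan_starts(pattern, sequence):
    """1-based start positions of exact matches, via the regex oracle."""
    return [m.start() + 1 for m in pattern_regex(pattern).finditer(sequence)]


def cophenetic(tree):
    """Leaf-pair cophenetic distances (2 * height of the LCA)."""
    out = {}

    def walk(node):
        if node.is_leaf:
            return [node.label]
        sides = [walk(c) for c in node.children]
        for i in range(len(sides)):
            for j in range(i + 1, len(sides)):
                for x in sides[i]:
                    for y in sides[j]:
                        out[frozenset((x, y))] = 2.0 * node.height
        return [l for side in sides for l in side]

    walk(tree)
    return out
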