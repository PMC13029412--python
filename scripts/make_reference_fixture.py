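"""One-time construction of the synthetic human FAM111A surrogate fixture.

Builds a 611-residue sequence carrying every published residue annotation
(variant reference residues, catalytic triad, oxyanion hole, cleavage site,
S1-pocket letters, PIP-box shape, instances of the seven conserved motifs)
with seeded-random filler elsewhere.  Output frozen into
src/fam111kit/data/fam111a_reference_synthetic.fasta
"""
import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"
L = 611

pins = {}

def pin(pos, res):
    if pos in pins and pins[pos] != res:
        raise ValueError(f"conflict at {pos}: {pins[pos]} vs {res}")
    pins[pos] = res

# PIP box 16-28, Qxx(phi)xx(psi)(psi)
for p, r in [(16, "Q"), (19, "I"), (22, "F"), (23, "Y")]:
    pin(p, r)
# motif 1 instance 224-231: [A/T]-[L/V]-x-x-D-G-R-[F/L]
for p, r in zip(range(224, 232), "AL??DGRF"):
    if r != "?":
        pin(p, r)
pin(226, "C")  # C226F ref
# variant reference residues outside motifs
for p, r in [(285, "E"), (292, "L"), (311, "I"), (323, "G"), (326, "L"),
             (334, "F"), (335, "G"), (338, "T"), (342, "S")]:
    pin(p, r)
# motif 2 instance 356-360: S-V-x-x-[I/L]  (V357 ref)
for p, r in [(356, "S"), (357, "V"), (360, "I")]:
    pin(p, r)
pin(369, "Y")  # S1 pocket
# motif 3 instance 380-386: [L/V]-[L/F]-T-x-x-H-[V/L]; position 380 is I
# (I380V reference residue) so the instance carries one mismatch, as the
# published placements require.
for p, r in [(380, "I"), (382, "T"), (384, "R"), (385, "H"), (386, "V")]:
    pin(p, r)
# motif 4 instance 439-445: D-x-A-x-L-x-L (catalytic D439)
for p, r in [(439, "D"), (441, "A"), (443, "L"), (445, "L")]:
    pin(p, r)
# motif 5 instance 467-476: I-I-G-H-P-x-[G/E]-x-x-K (H470 ref)
for p, r in [(467, "I"), (468, "I"), (469, "G"), (470, "H"), (471, "P"),
             (473, "G"), (476, "K")]:
    pin(p, r)
for p, r in [(485, "C"), (511, "Y"), (514, "M"), (520, "F"), (527, "P"),
             (528, "D"), (535, "E"), (536, "F"), (537, "F"), (538, "F")]:
    pin(p, r)
# motif 6 instance 539-545: G-x-S-G-S-P-V (oxyanion G539/S541, G542 ref)
for p, r in [(539, "G"), (541, "S"), (542, "G"), (543, "S"), (544, "P"),
             (545, "V")]:
    pin(p, r)
pin(547, "D")
# motif 7 instance 552-559: [L/V]-x-x-x-H-x-x-G (covers H556..G559 S1 letters)
for p, r in [(552, "L"), (555, "M"), (556, "H"), (557, "A"), (558, "A"),
             (559, "G")]:
    pin(p, r)
for p, r in [(560, "F"), (562, "Y"), (569, "R"), (572, "I"), (573, "E"),
             (574, "F"), (586, "K")]:
    pin(p, r)

rng = np.random.default_rng(20260301)
seq = [AA[i] for i in rng.integers(0, 20, size=L)]
for pos, res in pins.items():
    seq[pos - 1] = res
seq = "".join(seq)
assert len(seq) == 611
for pos, res in pins.items():
    assert seq[pos - 1] == res

header = (">NP_001361777.1-synthetic-surrogate synthetic stand-in for human "
          "FAM111A isoform 1 (constructed from published residue annotations,"
          " not the database record) [Homo sapiens]")
with open("src/fam111kit/data/fam111a_reference_synthetic.fasta", "w") as fh:
    fh.write(header + "\n")
    for i in range(0, L, 60):
        fh.write(seq[i:i + 60] + "\n")
print(seq[:60])
print("pins ok:", len(pins))
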