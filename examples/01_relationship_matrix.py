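"""Build the additive relationship matrix for a tiny nested half-sib pedigree.

Two dams mated to one sire give full-sib pairs (relationship 0.5) within
family and paternal half sibs (0.25) across families; founders are assumed
unrelated and non-inbred, so every diagonal is 1.
"""

from hspherit import Pedigree, additive_relationship, relationship_oracle

ped = Pedigree.from_records(
    [
        ("SIRE1", "", ""),
        ("DAM1", "", ""),
        ("DAM2", "", ""),
        ("KID1", "SIRE1", "DAM1"),
        ("KID2", "SIRE1", "DAM1"),
        ("KID3", "SIRE1", "DAM2"),
    ]
)
A = additive_relationship(ped)
print(A.to_frame().round(3))
print()
print("full sibs  KID1-KID2:", A.loc("KID1", "KID2"), "(expect 0.5)")
print("half sibs  KID1-KID3:", A.loc("KID1", "KID3"), "(expect 0.25)")
print("pairwise-recursion oracle agrees:",
      relationship_oracle(ped, "KID1", "KID3") == A.loc("KID1", "KID3"))
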