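"""Hemiplasy risk factors: short internal branches put traits at risk.

HRF compares, per internal branch, the probability that an incongruent trait
pattern arose through a discordant genealogy with one mutation (hemiplasy)
against two convergent mutations (homoplasy).  It falls roughly
exponentially with the internal branch length, because discordant
genealogies require lineages to survive the branch uncoalesced.
"""

from xenorisk import (BinaryTraitModel, hrf, hrf_all_branches, major_tree,
                      parse_extended_newick)
from xenorisk.experiments import six_taxon_network

model = BinaryTraitModel.from_ratio(1.0, theta=0.01)

print("internal branch length   HRF")
for ib in (0.1, 0.5, 1.0, 2.0, 5.0, 10.0):
    tree = parse_extended_newick(f"((B:1,C:1):{ib},A:{1 + ib});")
    res = hrf(tree, {"B", "C"}, model, n_genealogies=30_000, rng_seed=1)
    print(f"{ib:8.1f} {res.hrf:20.4f}")

print("\nper-branch HRF on the six-taxon benchmark's major tree:")
table = hrf_all_branches(major_tree(six_taxon_network()), model,
                         n_genealogies=20_000, rng_seed=2)
print(table[["branch", "p_hemiplasy", "p_homoplasy", "hrf"]]
      .to_string(index=False))
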