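"""Map a sheddase cleavage site from two semi-specific peptides.

Loads the bundled surrogate receptor ectodomain (the identifying peptides
sit at receptor-numbering coordinates 54-64 and 65-80), treats the two
peptides as a MaxQuant-style semi-specific identification table, and calls
the cleavage site supported by both cleavage products.
"""

import shedmap as sm
from shedmap.io import load_reference_protein

protein = load_reference_protein()
print(f"protein {protein.id}, {len(protein)} residues")

# the two identifying peptides: one ends where the sheddase cut (the
# N-terminal product's C-terminus), one starts right after it
table = [
    sm.PeptideMatch(protein.id, 54, 64, "EVLQRPASIME", "trypsinP"),
    sm.PeptideMatch(protein.id, 65, 80, "SDKGWTSASTSGKPRK", "trypsinP"),
]

evidence = sm.collect_terminus_evidence(
    table, {protein.id: protein}, sm.DEFAULT_PROTEASES
)
for e in evidence:
    print(f"  {e.peptide}: non-canonical terminus -> site {e.site} ({e.product_side.value})")

calls = sm.call_cleavage_sites(evidence, min_products=2)
for call in calls:
    print(
        f"concordant cleavage site: bond {call.site}|{call.site + 1} "
        f"(n-side {call.n_side_peptides}, c-side {call.c_side_peptides})"
    )
# Both products leave a terminus the digestion protease cannot explain at
# the same bond, so the scissile bond is pinned between residues 64 and 65.
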