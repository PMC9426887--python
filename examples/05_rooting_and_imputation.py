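"""Root an inferred tree at the sample closest to a reference genotype and
export the tree-based imputation of missing calls.

Rooting uses the same sequence cost as inference: the sample with minimal
cost to the (normal-cell) reference becomes the root, giving the unrooted
lineage tree an evolutionary direction.
"""

from scelestial import (
    root_by_reference,
    run_scelestial,
    sequences_from_strings,
    serialize_genotype_table,
    to_newick,
)
from scelestial.genotype import GenotypeMatrix

cells = sequences_from_strings(
    ["AAAA", "AACA", "ACCX", "CCCC", "XCCC"],
    ["normal1", "normal2", "early", "late1", "late2"],
)
(reference,) = sequences_from_strings(["AAAA"], ["reference"])

tree = run_scelestial(cells, k=3)
rooted = root_by_reference(tree, reference)
print(f"root (sample closest to the reference): {rooted.root}")
print("rooted newick:", to_newick(rooted))

imputed = GenotypeMatrix.from_sequences(
    [tree.sequence(s.sample_id) for s in cells]
)
print("imputed matrix (missing X/X calls filled from tree neighbors):")
print(serialize_genotype_table(imputed, "tenstate"))
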