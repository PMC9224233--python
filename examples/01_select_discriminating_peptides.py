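"""Select isoform-discriminating tryptic peptides for a paralog family.

Builds a 9-member synthetic family in which two members share every
tryptic peptide (like a pair of gene duplicates), digests everything,
merges indistinguishable members, and applies the evidence and
minimum-two-peptides filters.
"""

from isomrm.digest import (build_peptide_index, digest_peptide_set,
                           merge_indistinguishable, select_discriminating)
from isomrm.io import EvidenceSet
from isomrm.simulate import generate_family

family, _ = generate_family(9, include_indistinguishable_pair=True, seed=1)
index = build_peptide_index(family)

# discovery evidence: pretend every tryptic peptide was observed except
# those of the last distinct isoform, which therefore cannot be assayed
unseen = digest_peptide_set(family[6].sequence)
evidence = EvidenceSet(frozenset(
    pep for rec in family for pep in digest_peptide_set(rec.sequence)
    if pep not in unseen))

groups = merge_indistinguishable(family, index, length_bounds=(6, 30))
groups, drop_log = select_discriminating(groups, index, evidence,
                                         min_peptides=2)

print(f"{len(family)} isoforms -> {len(groups)} distinguishable groups\n")
print(f"{'group':<14}{'members':<8}{'n_disc':<8}{'n_sel':<7}quantifiable")
for g in groups:
    print(f"{g.label:<14}{len(g.members):<8}"
          f"{len(g.discriminating_peptides):<8}"
          f"{len(g.selected_peptides):<7}{g.quantifiable}")
print("\ndropped (insufficient evidenced peptides):")
for line in drop_log:
    print("  " + line.replace("\t", " — "))
print("\nA group needs >= 2 evidenced peptides unique to it to be "
      "quantifiable; the merged pair is quantified as one polypeptide.")
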