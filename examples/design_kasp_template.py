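"""Design a KASP-style flanking consensus template for a target allele.

The template carries the target diagnostic allele verbatim, IUPAC-codes
every other SNP in the window so one sequence covers all haplotypes, and
flags flanking indels (the mechanism known to break allele-specific
primers when within 25 bp of the target).
"""

import numpy as np

from polybrix import Variant, design_consensus

rng = np.random.default_rng(3)
reference = "".join(rng.choice(list("ACGT"), size=300))

target_pos = 150
variants = [
    Variant(pos=150, ref=reference[149], alts=("T",)),   # the target site
    Variant(pos=140, ref=reference[139], alts=("A",)),   # flanking SNP
    Variant(pos=170, ref=reference[169],
            alts=(reference[169] + "ACGT",)),            # flanking insertion
]

template = design_consensus(reference, target_pos, "T", variants, flank=50)

print(f">consensus|target={template.target_allele}"
      f"|offset={template.target_offset}")
print(template.sequence)
iupac = [b for b in template.sequence if b not in "ACGT"]
print(f"\ntarget base at offset {template.target_offset}: "
      f"{template.sequence[template.target_offset]}")
print(f"ambiguity-coded flanking sites: {iupac}")
for flag in template.indel_flags:
    print(f"WARNING: flanking indel at {flag['pos']} "
          f"({flag['distance_bp']} bp from target; "
          f"{'within' if flag['near_target'] else 'beyond'} 25 bp)")
print("-> a near-target indel warns that the assay may fail to amplify the "
      "non-target haplotype and report spurious homozygous calls.")
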