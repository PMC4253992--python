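"""LD-based block detection, EM haplotype frequencies and pooling.

Simulates the default population, finds haplotype blocks (D' > 0.75
with >= 90% strong informative pairs), estimates block haplotype
frequencies by EM over phase configurations, and pools rare
(<= 5%) haplotypes into a single class.
"""

import numpy as np

from halfsib import build_block, find_blocks, simulate_population
from halfsib.refpanel import default_sim_config

d = simulate_population(default_sim_config(seed=1))
g, _ = d.genotypes.orient_to_minor()

blocks = find_blocks(g)
print(f"{len(blocks)} block(s) detected")
for i, members in enumerate(blocks, 1):
    print(f"block {i}: {len(members)} SNPs: {', '.join(members)}")
    block = build_block(g, members)
    for label, freq in zip(block.class_labels, block.class_frequencies):
        print(f"  {label:<10} {100 * freq:5.1f}%")
    print(f"  dosage design: {block.dosage.shape[0]} individuals x {block.k} classes,"
          f" rows sum to {block.dosage.sum(axis=1).mean():.1f}")
# Each dosage row holds the expected number of copies (0-2) of every
# haplotype class under the EM phase posteriors; rows sum to 2 because
# every individual carries two haplotypes.
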