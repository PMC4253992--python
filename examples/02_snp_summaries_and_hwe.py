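"""Per-SNP descriptive statistics and Hardy-Weinberg tests.

Reconstructs genotype counts for the published bovine HAL panel
(round(frequency x 638)) and prints MAF and the chi-square HWE p-value
per SNP — the same arithmetic the package applies to any genotype file.
"""

from halfsib import hwe_test, minor_allele_frequency
from halfsib.refpanel import PANEL, reconstructed_counts

print(f"{'snp':<14}{'region':<10}{'counts':<16}{'MAF':>6}{'HWE p':>10}")
for snp in PANEL:
    counts = reconstructed_counts(snp)
    maf = minor_allele_frequency(counts)
    _, p = hwe_test(counts)
    print(f"{snp.id:<14}{snp.region:<10}{str(counts):<16}{maf:>6.3f}{p:>10.4f}")
# A small HWE p (e.g. the intron-2 SNP, p ~ 4e-4) flags genotype
# proportions departing from p^2 : 2pq : q^2 at the sample allele
# frequencies; MAF is the rarer allele's frequency.
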