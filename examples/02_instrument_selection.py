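"""Select and harmonise instruments from a variant-weight table.

Filters a toy exposure GWAS at genome-wide significance (P < 5e-8),
prunes it by greedy LD clumping (r² < 0.01 within ±250 kb), harmonises
against outcome summary statistics (including a strand-flipped and a
palindromic record), and subsets to ion-channel genes.
"""

import ecgmr

variants = [
    ecgmr.VariantRecord("rs1", "3", 38_600_000, "A", "G", 0.30, 2.5, 0.2, 1e-30, "SCN5A"),
    ecgmr.VariantRecord("rs2", "3", 38_700_000, "C", "T", 0.45, 1.8, 0.2, 1e-15, "SCN5A"),
    ecgmr.VariantRecord("rs3", "3", 40_000_000, "G", "A", 0.20, -1.1, 0.2, 1e-10, "TTN"),
    ecgmr.VariantRecord("rs4", "11", 2_500_000, "A", "T", 0.50, 0.9, 0.2, 1e-9, "KCNQ1"),
    ecgmr.VariantRecord("rs5", "1", 1_000_000, "T", "C", 0.60, 0.4, 0.2, 3e-7, None),
]

significant = ecgmr.gw_significance_filter(variants)
print(f"significance filter: {len(variants)} -> {len(significant)} variants")

# rs1 and rs2 are 100 kb apart and correlated; the smaller p wins
ld = lambda a, b: 0.6 if {a.id, b.id} == {"rs1", "rs2"} else 0.0
independent = ecgmr.ld_clump(significant, ld)
print(f"LD clumping: retained {[v.id for v in independent]}")

outcome_stats = {
    "rs1": ("A", "G", -0.030, 0.01),   # direct match
    "rs3": ("C", "T", 0.012, 0.01),    # opposite strand of G/A
    "rs4": ("A", "T", -0.011, 0.01),   # palindromic at eaf 0.50: dropped
}
pairs = ecgmr.harmonise(independent, outcome_stats)
for p in pairs:
    print(f"  {p.variant.id}: beta_exposure {p.beta_exposure:+.2f} ms, "
          f"beta_outcome {p.beta_outcome:+.4f} log-OR (coded to lengthening allele)")

channel = ecgmr.ion_channel_subset(independent, {"SCN5A", "SCN10A", "KCNQ1", "KCNJ2"})
print(f"ion-channel subset: {[v.id for v in channel]}")
# rs3's exposure beta was negative, so both betas were flipped jointly;
# the ambiguous palindrome rs4 was removed rather than guessed.
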