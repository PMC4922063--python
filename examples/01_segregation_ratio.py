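"""Which Mendelian ratio fits the observed litter counts?

74 piglets from 11 heterozygote x heterozygote litters: 49 with normal
hearing, 25 hearing-impaired.  The chi-square goodness of fit is run
against the classical candidate ratios, and carrier penetrance is
estimated from the 4 affected among 51 haplotype heterozygotes.
"""

from recmap import estimate_penetrance, gof_chisq, select_mendelian_ratio

observed = (49, 25)  # (normal, affected)
selected, results = select_mendelian_ratio(observed)

print(f"observed {observed[0]} normal : {observed[1]} affected")
for ratio, res in sorted(results.items()):
    mark = "  <- selected" if ratio == selected else ""
    print(f"  {ratio[0]:>2}:{ratio[1]} chi2={res.chi2:6.3f}  p={res.p:.4f}{mark}")

# a 3:1 fit means one parental allele pair segregating recessively
pen = estimate_penetrance({"het": (4, 51), "hom_risk": (24, 24)})
het = pen["het"]
print(f"\ncarrier (heterozygote) penetrance: {het.estimate:.4f} "
      f"(95% Wilson CI {het.ci_low:.3f}-{het.ci_high:.3f})")
print("homozygote penetrance:", pen["hom_risk"].estimate)
print("\nA selected 3:1 ratio with low but non-zero carrier penetrance is")
print("the signature of a semi-recessive autosomal locus.")
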