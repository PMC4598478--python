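"""Run the QC cascade on a simulated study and read the report.

Stages: mask calls with confidence < 0.25; drop subjects missing > 10% of
calls; merge heterozygote/minor-homozygote groups smaller than 10 (exclude
the locus if the merged group is still < 10); flag Hardy-Weinberg deviation
at p < 0.01 (df = 1, females only on X); greedily prune loci in LD
(r^2 > 0.8) with an earlier retained locus; estimate PI_HAT relatedness on
the pruned autosomal panel.
"""

import snpset as ss

truth = ss.default_truth(target_planted_r2=0.08, seed=42)
gm, pheno, _ = ss.simulate_study(truth)

clean, groupings, report = ss.run_qc(gm)

print(f"input: {report.input_subjects} subjects x {report.input_loci} loci")
print(f"masked calls: {report.masked_calls} "
      f"({100 * report.masked_fraction:.2f}%)")
print(f"excluded subjects: {len(report.excluded_subjects)}")
print(f"loci excluded (small groups/monomorphic): {len(report.excluded_loci)}")
print(f"loci merged (het+minor-hom combined): {len(report.merged_loci)}")
print(f"loci pruned for LD: {len(report.ld_dropped)}")
for locus, partner, r2 in report.ld_dropped[:3]:
    print(f"  {locus} dropped against {partner} (r^2 = {r2:.2f})")
print(f"HWE-deviating (flagged, retained): "
      f"{(report.hwe['flag'] == 'deviating').sum()}")
print(f"relatedness pairs flagged at PI_HAT >= 0.5: "
      f"{len(report.relatedness_flags)}")
print(f"retained: {report.retained_subjects} subjects x "
      f"{report.retained_loci} loci")
# With a ~90-locus panel the method-of-moments PI_HAT is noisy (the flag
# count above is tail noise, not true relatives); panels of hundreds of
# independent SNPs give sharp estimates -- see the relatedness tests.
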