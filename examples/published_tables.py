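"""Work through the packaged reference tables.

Loads the 40-sample sequencing cohort summary, totals its CCS reads,
audits the 13-sample sequencing-vs-KASP concordance panel, and computes
the assay attrition arithmetic.
"""

from polybrix import assay_attrition_report, concordance, datasets, summarize_ccs

meta = datasets.sequenced_samples()
summary = summarize_ccs(meta)
print(f"cohort: {len(meta)} samples, "
      f"{meta['program'].value_counts().to_dict()} per breeding program")
print(f"high/low SSC split at 11.5 °Brix: "
      f"{meta['ssc_class'].value_counts().to_dict()}")
print(f"CCS reads: {summary['total_reads']:,} total, "
      f"per program {summary['per_program']}")

seq, kasp, targets = datasets.kasp_concordance()
rep = concordance(seq, kasp, targets=targets)
print(f"\nKASP vs sequencing: {rep.n_concordant}/{rep.n_total} samples "
      f"fully concordant; discordant: {rep.discordant_samples}")
print("-> the two discordant samples returned homozygous target-allele "
      "calls where sequencing saw both alleles.")

attrition = assay_attrition_report(n_designed=111, n_failed=27)
print(f"\nassay attrition: {attrition['n_usable']} usable markers, "
      f"{attrition['pct_failed']}% failed or monomorphic")
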