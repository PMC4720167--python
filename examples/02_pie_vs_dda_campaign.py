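"""Compare a precursor-ion-exclusion campaign against DDA replicates.

Generates a synthetic two-channel TMT mixture, runs 3 PIE iterations
(each excluding everything previously identified) and 3 plain DDA
replicates on the same sample, then prints the comparison report:
identification counts, percent increase, and the log2-ratio regression
between strategies over their common proteins.
"""

from pieacq import (
    AcquisitionConfig,
    MixtureConfig,
    compare_strategies,
    generate_mixture,
    reporter_ratios,
    run_dda_replicates,
    run_pie_campaign,
)

mixture = generate_mixture(MixtureConfig(seed=7))
print(f"mixture: {len(mixture.proteins)} proteins, {len(mixture.peptides)} peptides")

cfg = AcquisitionConfig()
pie_runs, final_list = run_pie_campaign(mixture, cfg, 3, seed=7)
dda_runs = run_dda_replicates(mixture, cfg, 3, seed=7)

for r in pie_runs:
    in_force = len(r.exclusion) if r.exclusion else 0
    print(
        f"  {r.run_id}: {len(r.events)} selections, "
        f"{len(r.accepted_peptides)} accepted peptides (exclusion in force: {in_force})"
    )
for r in dda_runs:
    print(f"  {r.run_id}: {len(r.events)} selections, {len(r.accepted_peptides)} accepted peptides")

quant_pie = reporter_ratios(pie_runs, mixture, noise_sd=0.2, seed=(7, 0))
quant_dda = reporter_ratios(dda_runs, mixture, noise_sd=0.2, seed=(7, 1))
pep_pie = set().union(*(r.accepted_peptides for r in pie_runs))
pep_dda = set().union(*(r.accepted_peptides for r in dda_runs))

report = compare_strategies(quant_pie, quant_dda, pep_pie, pep_dda)
print()
print(report.to_markdown())
# Each PIE iteration samples precursors the previous runs already
# identified-and-excluded, so the cumulative unique peptide count outgrows
# the DDA replicates, while the common-protein ratio regression stays close
# to the identity line (quantification quality is preserved).
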