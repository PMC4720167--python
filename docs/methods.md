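# Methods

This note documents the models behind `pieacq`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic studies can
and cannot say about real data.

## Scope and design stance

The toolkit has two halves. The exclusion-list engine is deterministic
list algebra: parsing, ppm/RT clustering, cross-run merging, capacity
capping and instrument-format export. The acquisition simulator is a
ground-truth-aware statistical model of a DDA instrument: it never
synthesizes spectra. Peptides are known objects with known elution
profiles; selection is an intensity competition under exclusion rules, and
identification is a stochastic process whose success probability depends
on precursor intensity. This makes every downstream claim (yield,
coverage, ratio recovery) checkable against ground truth, at the price of
abstracting away everything spectral (isotope envelopes, fragmentation,
co-isolation).

## Synthetic mixture

The generator emulates a two-channel TMT-labeled tryptic digest of a
moderately complex proteome.

- **Proteins.** `n_proteins` random sequences (default 55, lengths
  uniform 120–600 residues, vertebrate residue frequencies). Default
  abundance law is log-uniform over `dynamic_range_orders` (default 4)
  above `abundance_floor` (10 units), with the extremes pinned so the
  configured span is realized exactly; a log-normal law is available by
  config switch. Four orders is a deliberate desk-scale compression of the
  far wider range of real biofluids: wide enough that low-abundance
  species are genuinely hard to reach, small enough that a single run can
  cover a meaningful part of the mixture.
- **Digestion.** Cleavage C-terminal to K/R (Lys-C + trypsin collapse to
  this single rule; the no-cleavage-before-proline refinement is a config
  option, off by default), up to 2 missed cleavages, length ≥ 6. The
  defaults give ≈ 5,000 peptide species from 55 proteins.
- **Peptide observables.** One charge state per species (weights
  1+: 5%, 2+: 55%, 3+: 30%, 4+: 10%); monoisotopic mass = residue masses
  + water + 229.162932 Da per TMT label (N-terminus + each lysine);
  elution apex uniform over the central 96% of a 90-min gradient; Gaussian
  peak width σ uniform in 0.15–0.45 min; amplitude = protein abundance ×
  lognormal ionization factor (sd 1.0 in natural log) × 0.3 per missed
  cleavage (missed-cleavage forms are real but less abundant).
- **Channels.** A `differential_fraction` (default 0.2) of proteins get a
  true log2(126/127) ratio of ±`effect_size_log2` (default 1.0); the rest
  are exactly 1:1. This gives an exact ground truth for ratio-recovery
  tests.
- **Fractions.** Six HILIC and six SCX labels from quantile bins of two
  pure sequence functions: hydrophilicity (negated mean Kyte–Doolittle
  hydropathy) and basicity (K/R/H count + 1). A tiny CRC-based,
  sequence-pure jitter breaks ties in the discrete basicity descriptor so
  bins stay non-degenerate; identical sequences always share fractions.
  Real step-elution fractionation bleeds across fractions; this partition
  is idealized and serves only to split workloads.

## Acquisition model

- **Duty cycle.** `survey_time` (1.0 s) + 2 × `top_n` × `ms2_event_time`
  (0.4 s) = 3.4 s for the default top-3×2 method, in which each selected
  precursor costs an HCD event (reporter quantification) plus a CID event
  (sequencing). The two MS2 events are counted for time accounting only.
- **Selection.** At each cycle the candidates are peptides whose Gaussian
  profile at the cycle time exceeds `detection_threshold` (30 units) and
  whose m/z lies in 350–2000; the `top_n` most intense are selected, ties
  broken by lower m/z for deterministic replay.
- **Dynamic exclusion.** A peptide selected `dyn_excl_repeat` (2) times
  within `dyn_excl_duration` (60 s) is excluded for that duration — i.e.
  a precursor picked more than once within a minute goes quiet for a
  minute. Both numbers are config-exposed because the natural-language
  rule ("more than once within 60 s") does not pin down the exact state
  machine.
- **PIE exclusion.** A precursor is blocked when some list entry matches
  within `ppm_window` (10 ppm, computed against the entry m/z) and the
  cycle time falls inside the entry's RT window. The simulator enforces
  exactly the same predicate the compliance check re-applies.
- **Run-to-run variation.** Each run shifts every peptide's apex by a
  Gaussian jitter (sd 0.3 min). Per-run random streams are derived as
  `(master seed, run index, stage)` tuples, so any run can be reproduced
  in isolation.

Under these defaults the mixture demands roughly three times more MS2
selections than a 90-min run can supply (≈ 4,800 selections per run
against ≈ 5,000 detectable species, each visible for tens of cycles and
re-selectable after dynamic exclusion lapses). That oversubscription —
chosen a priori to mirror the undersampling regime that motivates PIE in
practice — is what makes replicate DDA redundant and exclusion effective;
with a small or dilute mixture the two strategies converge, which the
simulator reproduces.

## Identification and FDR

Each selection yields one target PSM. With probability
`expit(id_steepness · (log10 I − id_midpoint))` (defaults 1.0 and 2.5) the
match is "correct" and its score is drawn from N(3.5, 1); otherwise from
the null N(0, 1). Injected decoys (0.5 per target) also score from the
null. The FDR walk ranks PSMs by descending score (ties: decoys first,
conservative), and accepts from the top until the running decoy/target
ratio first exceeds α = 0.01; decoys are never accepted. The walk stops at
the first violation rather than seeking a later, longer valid prefix —
that is the "accept until the FDR rate is reached" semantics, and it is
what makes a top-scoring decoy empty the acceptance set.

The logistic-in-log-intensity success model is the simplest mechanism
that reproduces the key empirical behaviour: intense precursors identify
reliably, faint ones mostly fail, and re-sampling a faint precursor in a
later run gives it another chance.

## Exclusion-list algebra

Two entries are mergeable when their m/z difference, in ppm of the lower
member, is ≤ the tolerance AND their closed RT intervals overlap (or lie
within `rt_gap`, default 0). `cluster_merge` collapses the transitive
closure of this relation in whole-closure passes until a fixpoint; the
merged m/z is the arithmetic mean over the *original* members (tracked by
leaf counts, so the result is independent of merge order), the RT window
is the union, intensity is the member maximum. The output is canonical:
sorted by (m/z, RT start) with no mergeable pair remaining — idempotent
and permutation-invariant by construction.

Matching is on m/z, not neutral mass: the instrument's exclusion criterion
is a ppm window on m/z, and charge is deliberately ignored (an entry
blocks any charge state landing in its window). Cross-run merging takes
the stricter ppm of the two lists so a merge never loosens exclusion.
Point RTs from raw exports are padded by `rt_pad` (default 2.0 min) to a
window; capacity capping (default 2000 entries, a typical instrument
reject-table size) keeps the highest-intensity entries, entries without
intensity ranking last. The instrument CSV rounds m/z to 4 decimals and RT
to 2; the round-trip contract holds exactly at that precision, and a
richer TSV format preserves charge/intensity/provenance losslessly.

## Campaigns and reporting

A PIE campaign starts with plain DDA; after each run, entries built from
its accepted PSMs (event m/z, time ± `excl_rt_pad`) are clustered and
merged into the cumulative list used by the next run. DDA replicates use
the same per-run seed streams, so campaign and replicates of the same seed
are paired comparisons. Fraction mode analyzes each HILIC (or SCX)
fraction as an independent sub-mixture with its own per-fraction exclusion
list.

Reporter quantification adds N(0, `noise_sd` = 0.2) noise to the true
log2 ratio per accepted PSM, averages per distinct peptide and takes the
protein median (robust to the occasional wild peptide). Comparison
statistics: Venn partition, percent increase (raw and rounded), OLS
regression of common-protein log2 ratios (reference strategy on x, so a
slope < 1 reads as compressed ratios in the test strategy), and the
fraction of common proteins with *strictly* more peptides — the
strict inequality is a documented choice where "increased coverage" is
ambiguous.

## Numerical conventions and degenerate inputs

- ppm differences are always computed against the lower m/z of a pair
  (symmetric in arguments, marginally conservative).
- RT intervals are closed; exclusion boundaries are inclusive.
- Selection ties → lower m/z; FDR score ties → decoys first.
- Cycle count is `floor(run_length / cycle_time)`; an empty mixture still
  reports it.
- Constant-x regression, zero reference counts, and empty strategy
  intersections raise typed degenerate-input errors instead of returning
  NaN.
- All randomness flows through `numpy.random.default_rng` seeded from
  explicit integers or tuples; identical config + seed reproduce outputs
  bit for bit, including serialized experiment directories.

## Problem sizes used in the checks

The bundled verification suites run at the default conditions: ~5,000
peptides per mixture, 90-min runs, 3-iteration campaigns, 20 seeds for the
paired PIE-vs-DDA yield comparison; clustering and FDR behaviour are
checked against brute-force oracles on hundreds of random instances.
`scripts/acceptance.py` reruns the full default comparison from scratch
from a single seed.

## Limitations

- No spectra: co-isolation interference, reporter-ion compression of TMT
  ratios, and search-engine score structure are not modeled. The reporter
  noise model is symmetric in log2 space and channel-independent.
- Retention time is sampled, not predicted from sequence, so exclusion
  windows are exactly as transferable across runs as the jitter model
  makes them — real gradient drift is nonlinear.
- Fraction assignment is an exact partition; real fractionation overlaps.
- Ion suppression, charge-state coupling and peak-shape asymmetry are
  absent; intensity is the only driver of selection and identification.
- Synthetic-study outcomes (yield gains, coverage fractions, regression
  slopes) are functions of the configured conditions, chiefly the
  oversubscription ratio; they demonstrate mechanism, not magnitudes to
  expect from any particular real sample.
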