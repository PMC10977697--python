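"""ELISA hit calling and campaign tabulation.

Calls positivity on the packaged primary-hit table, reproduces the
published campaign statistics from the unique-clone count matrix, and
computes the SPR confirmation rate of the synthesized peptides.
"""

from dcphage import (
    call_positive,
    confirmation_rate,
    load_primary_hits,
    load_unique_clone_counts,
    signal_to_noise,
    summarize_counts,
)

records = load_primary_hits()
positives = 0
for rec in records:
    ok, reasons = call_positive(rec)
    positives += ok
print(f"positivity: {positives}/{len(records)} packaged hits pass "
      "(signal >= 0.3, S/N > 2, intact cysteine framework)")
print(f"example S/N: {records[0].clone} = {signal_to_noise(records[0]):.1f}")

summary = summarize_counts(load_unique_clone_counts())
print("\nunique clones per scaffold:")
for sc in summary.counts.columns:
    hits, screened = summary.hit_rate(sc)
    print(f"  {sc:16s} total {summary.scaffold_totals[sc]:4d}   targets {hits}/{screened}")
h, n = summary.overall_success
print(f"overall success: {h}/{n} targets ({100 * summary.overall_success_fraction:.1f}%)")

confirmed, total, pct = confirmation_rate(records)
print(f"\nSPR confirmation of synthesized hits: {confirmed}/{total} ({pct}%)")
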