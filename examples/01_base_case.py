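"""Deterministic base case: totals per arm, ICER, regional verdicts.

Builds the three-state cohort model from the bundled CARES-310 input set
(log-logistic OS/PFS curves, 120 monthly cycles, 3% annual discounting) and
compares camrelizumab plus rivoceranib against sorafenib.
"""

from hcc_cea import compare, default_bundle, run_base_case

bundle = default_bundle()
outcomes = run_base_case(bundle)  # partitioned-survival occupancies

for arm, out in outcomes.items():
    print(f"{arm:12s}  cost ${out.total_cost:>9,.2f}   QALYs {out.total_qalys:.3f}")
    for part, usd in out.cost_breakdown.items():
        print(f"    {part:20s} ${usd:>9,.2f}")

result = compare(outcomes["sorafenib"], outcomes["combination"],
                 bundle.settings.wtp_thresholds)
print(f"\nincremental cost  ${result.delta_cost:,.2f}")
print(f"incremental QALYs {result.delta_qalys:.3f}")
print(f"ICER              ${result.icer:,.2f} per QALY")
for region, ok in result.verdicts.items():
    wtp = bundle.settings.wtp_thresholds[region]
    print(f"  {region:7s} (WTP ${wtp:>9,.2f}): "
          f"{'cost-effective' if ok else 'not cost-effective'}")

# The ICER is the extra spend per quality-adjusted life year gained by the
# combination; it is cost-effective in a region when below that region's WTP.
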