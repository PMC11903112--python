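"""Per-case and pooled nuclear size summaries with reference-cell ratios.

Simulates a small cohort of pleomorphic ILC, classic score-1 ILC and
reference lymphocytes (each calibrated to its published area law),
measures every nucleus, and prints pooled median/IQR per variant plus the
lesion-to-lymphocyte median-area ratio — the "times larger than a
lymphocyte" figure pathologists use as an internal size standard.
"""

from lobmorph import (
    measure_all,
    reference_ratio,
    reference_spec,
    simulate_cohort,
    spec_for_variant,
    summarize_cases,
)

specs = [
    spec_for_variant("pILC"),
    spec_for_variant("cILC_score1"),
    reference_spec("lymphocyte"),
]
shapes, manifest, _ = simulate_cohort(specs, n_cases_per_variant=6, seed=11,
                                      nuclei_per_case=150)
records = measure_all(shapes)
pooled = {s.key: s for s in summarize_cases(records, manifest, "pooled_by_variant")}

print(f"{'variant':>14} {'n':>5} {'area median':>12} {'area IQR':>9}")
for key, s in pooled.items():
    a = s.stats["area"]
    print(f"{key:>14} {s.n_nuclei:>5} {a.median:>12.1f} {a.iqr:>9.1f}")

rr_p = reference_ratio(pooled["pILC"], pooled["lymphocyte"])
rr_c = reference_ratio(pooled["cILC_score1"], pooled["lymphocyte"])
print(f"\npILC area vs lymphocyte:        {rr_p.displayed['area']} times")
print(f"cILC score1 area vs lymphocyte: {rr_c.displayed['area']} times")
print("\nPleomorphic nuclei are both larger (median) and more variable "
      "(IQR) than classic ones; ratios near 3.8x/2.0x echo the published "
      "lesion-to-lymphocyte relations.")
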