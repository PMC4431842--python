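"""Detect interspecific introgression, mask it, and re-mine the panel.

Injects pummelo-heterozygous fragments into four of the eleven mandarin
references (20% of fragments each) — the situation that depresses the
mandarin diagnostic count in real germplasm — then runs the
heterozygosity + differential-SNP screen, masks the flagged
accession × fragment calls, re-estimates taxon frequencies and compares
the diagnostic counts before and after.
"""

import diagsnp as dg

intro = tuple(
    dg.IntrogressionSpec(f"mandarin_{i:02d}", "pummelo", 0.2) for i in (1, 2, 3, 4)
)
ds = dg.build_scenario(dg.ScenarioConfig(rng_seed=3, introgressions=intro))

res = dg.remine_with_mask(ds.genotypes, ds.taxon_map, ds.markers, ds.fragments)

truth = set(map(tuple, ds.truth.introgressions[["accession", "fragment"]]
                .itertuples(index=False)))
flagged = set(map(tuple, res.flags[["accession", "fragment"]].itertuples(index=False)))
tp = len(truth & flagged)
print(f"injected introgressed fragments: {len(truth)}; flagged: {len(flagged)}; "
      f"precision = {tp / max(len(flagged), 1):.3f}, recall = {tp / len(truth):.3f}")

print("\nDiagnostic counts per taxon before/after masking:")
print(res.delta_report[["taxon", "n_diagnostic_pre", "n_diagnostic_post"]]
      .to_string(index=False))
print("\nMasking removes only the donor-heterozygous calls, so the focal "
      "taxon's allele frequencies return to fixation and its diagnostic "
      "count increases; the other taxa are untouched.")
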