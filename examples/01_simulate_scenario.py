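"""Generate a synthetic four-taxon genotype dataset and inspect its truth.

Builds the default reference design — four ancestral citrus taxa sampled
11/9/5/1, 57 gene fragments of ~500 bp over nine chromosomes, ~18 SNPs
per fragment — and prints the planted marker-class composition plus the
basic diversity report the real analysis would start from.
"""

import diagsnp as dg

ds = dg.build_scenario(dg.ScenarioConfig(rng_seed=1))

print(f"accessions: {ds.genotypes.n_accessions}, markers: {ds.genotypes.n_markers}, "
      f"fragments: {len(ds.fragments)}")
print("\nPlanted marker classes (truth table):")
print(ds.truth.markers["true_class"].value_counts().to_string())

rep = dg.group_report(ds.genotypes, ds.taxon_map.reference_groups())
print("\nPer-taxon report (Na = sample size, MD = % missing, PL = polymorphic "
      "loci, NSG = distinct multilocus genotypes):")
print(rep.round(3).to_string(index=False))

_, fst = dg.wc_fst(ds.genotypes, ds.taxon_map.reference_groups())
print(f"\nMultilocus Weir–Cockerham F_ST across the four taxa: {fst:.3f}")
print("High F_ST (≫0.25) reflects the strong allopatric differentiation the "
      "diagnostic-marker strategy relies on.")
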