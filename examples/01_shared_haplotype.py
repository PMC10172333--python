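"""Delimit the haplotype shared by carriers of a rare founder variant.

Simulates the packaged isolate scenario (20 carriers descending from one
founder couple among ~2000 unrelated samples), then runs the stepwise
variant-by-variant sharing search over all carrier pairs.
"""

import founderhap as fh

ped, cfg = fh.westray_demo(seed=11)
res = fh.simulate(ped, cfg)
panel = res.phased["all"]

haps = fh.identify_carrier_haplotypes(panel, res.focal, res.carriers)
sharing = fh.all_pairs_sharing(panel, res.focal, haps, gmap=cfg.resolved_map())

print(f"carriers: {len(res.carriers)} of {panel.n_samples} samples")
print(f"pairwise segments: {len(sharing.segments)}")
print(f"shortest shared haplotype: {sharing.shortest.length_bp / 1e6:.2f} Mb "
      f"({sharing.shortest.n_variants} variants)")
print(f"core shared by every pair: {sharing.core.length_bp / 1e6:.2f} Mb, "
      f"{sharing.core.length_cm:.2f} cM")

# The core interval is the region every carrier pair still matches over —
# the footprint of the founder haplotype that all carriers co-inherited.
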