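"""Simulate a ZP-module gene family with planted truth.

Builds the default synthetic bundle: six ancient paralogous subfamilies
sampled across five species, ten replicate alignments of the same
sequences, two subfamilies with the ZP-N domain deleted, and Type 1/2/3
cysteine layouts assigned per subfamily.
"""

from zpevol import SyntheticSpec, make_fixture_bundle

spec = SyntheticSpec(seed=1)
bundle = make_fixture_bundle(spec, out_dir="scratch_bundle")

truth = bundle.truth
a0 = bundle.replicates[0]
print(f"tips: {len(truth.tip_types)}  replicates: {len(bundle.replicates)}")
print(f"alignment columns (replicate 0): {a0.n_cols}")
print(f"planted ZP-N-loss tips: {len(truth.loss_tips)}")
print(f"planted type-switch branches: {truth.type_switches}")

nm = sorted(truth.loss_tips)[0]
zpn_gap = a0.sequence(nm)[:80].count("-") / 80
print(f"example loss tip {nm}: ZP-N gap fraction {zpn_gap:.2f}")
# A loss tip's ZP-N interval is mostly gaps (planted in [0.80, 0.99]),
# while its ZP-C region stays intact -- the signature the scanner detects.
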