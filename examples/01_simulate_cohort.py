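"""Generate a synthetic control-SNc cohort and inspect its ground truth.

The generator draws each neuron's tonic baseline rate from 8-12 Hz, assigns
response types by exact quota from the condition's published mixture, and
derives the tetanization / post-event rates from the type's fold changes.
"""

from collections import Counter

from peristim import generate_cohort, preset_spec

spec = preset_spec("control-SNc", seed=20250528)
trains, truths, manifest = generate_cohort(spec)

print(f"cohort: {spec.group}/{spec.region}, {spec.n_neurons} neurons")
print(f"type counts (exact quota): {dict(Counter(gt.true_type for gt in truths))}")
gt = truths[0]
print(
    f"neuron 0: type {gt.true_type}, r_be={gt.r_be:.2f} Hz, "
    f"r_tt={gt.r_tt:.2f} Hz, r_pe={gt.r_pe:.2f} Hz"
)
print(f"spike table checksum: {manifest['spike_table_sha256'][:16]}...")
# The counts reproduce the published 9/36/27/28% mixture exactly; each
# neuron's r_tt and r_pe are its baseline divided or multiplied by the
# type's published fold change.
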