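"""Simulate a qPCR miRNA array experiment and apply detection calling.

Generates a 754-assay x 18-sample Cq matrix (3 cell types x 2 compartments
x 3 donors), flags each reaction as detected (15 <= Cq <= 30) and reports
the per-compartment detection rate and the consistently detected core used
for global-mean normalization.
"""

from evmir import SimConfig, generate_cq_dataset, detection_call, group_complete
from evmir.detection import detection_fraction
from evmir.normalization import normalizer_set

cq, sheet, truth = generate_cq_dataset(SimConfig(seed=1))
det = group_complete(detection_call(cq), sheet)

in_samples = [s for s in cq.sample_ids if "_IN_" in s]
ev_samples = [s for s in cq.sample_ids if "_EV_" in s]
core = normalizer_set(det)

print(f"matrix: {cq.shape[0]} assays x {cq.shape[1]} samples")
print(f"intracellular detection: {100 * detection_fraction(det, in_samples):.1f}%")
print(f"EV detection:            {100 * detection_fraction(det, ev_samples):.1f}%")
print(f"detected in all 18 samples: {len(core)} assays "
      f"({100 * len(core) / cq.shape[0]:.1f}% of the array)")
print()
print("Roughly a quarter of the array amplifies reliably per compartment;")
print("the ~11% core detected everywhere anchors the global-mean normalizer.")
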