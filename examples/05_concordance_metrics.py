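"""Agreement metrics between two modalities' hypoperfusion masks.

Shows the voxel-level overlap partition (overlapping / adjacent /
isolated, as percentages of the test mask), the Jaccard index, ROI-level
sensitivity/specificity, and the summary of the built-in nine-patient
reference table of published overlap values.
"""

import numpy as np

import perfconc as pc

# two overlapping cuboid "clusters": the test mask is the reference
# shifted by two voxels, so a slab of it is adjacent rather than overlapping
ref = np.zeros((20, 20, 10), dtype=bool)
ref[4:12, 4:12, 3:7] = True
test = np.zeros_like(ref)
test[6:14, 4:12, 3:7] = True

ov, adj, iso = pc.overlap_partition(test, ref)
print(f"overlap partition: {ov:.1f}% overlapping, {adj:.1f}% adjacent, "
      f"{iso:.1f}% isolated (sums to 100)")
print(f"Jaccard index: {pc.jaccard(test, ref):.3f} — low even for nearby "
      "clusters, which is why adjacency matters")
print(f"cluster volume change: {pc.cluster_volume_change(ref, test):.1f}% "
      "(positive = test detects less)")

ref_table = pc.ftd_overlap_reference("sd", "absolute")
summary = pc.summarize_columns(ref_table, decimals={"overlap": 1, "adjacent": 1,
                                                    "isolated": 1, "jaccard": 2})
print("\nreference cohort (single-delay pCASL vs ¹⁵O-water, absolute CBF):")
print(summary.to_string())
print("\nnote how ~93% of ASL-detected voxels are overlapping or adjacent "
      "while the mean Jaccard is only 0.2.")
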