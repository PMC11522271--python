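"""Global longitudinal strain from a synthetic deforming mask sequence.

Generates one cardiac cycle of a U-shaped myocardial band with 20%
prescribed longitudinal shortening, runs the tracking-free DTW strain
pipeline, and compares the recovered strain curve with the analytic
ground truth.
"""

import numpy as np

from dtwstrain import PhantomSpec, analyze, generate_phantom_sequence

spec = PhantomSpec(shortening_amplitude=0.2, n_frames=32, seed=1)
masks, truth = generate_phantom_sequence(spec)
result = analyze(masks)

gc = result.global_curve
print(f"frames analysed        : {len(masks)}")
print(f"end-diastolic frame(s) : {gc.ed_frames.tolist()}")
print(f"end-systolic frame     : {result.es_frame}")
print(f"recovered peak strain  : {100 * gc.peak_strain_signed:+.2f}%")
print(f"prescribed peak strain : {100 * truth.strain_per_frame.min():+.2f}%")
err = 100 * np.abs(gc.strain - truth.strain_per_frame)
print(f"max curve error        : {err.max():.2f} percentage points")
print()
print("frame  measured  truth  (%)")
for f in range(0, len(masks), 4):
    print(f"{f:5d}  {100 * gc.strain[f]:+7.2f}  {100 * truth.strain_per_frame[f]:+6.2f}")
print()
print("The peak strain is the maximal |(L - L0)/L0| of the centerline")
print("length L against its end-diastolic value L0; negative values mean")
print("systolic shortening. Agreement within ~1 percentage point shows the")
print("block registration tracks the prescribed deformation.")
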