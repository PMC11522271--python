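"""Registration consistency: the hopscotch experiment.

50 analytically co-moving points on the mid-curve play the role of
speckle-tracking output. Each point is assigned the serial number
(1..60) of the DTW block containing it, frame by frame; if the
block registration is temporally consistent, the serials barely change
and the mean difference from the first frame stays near zero.
"""

from dtwstrain import (
    PhantomSpec,
    analyze,
    generate_comoving_points,
    generate_phantom_sequence,
    run_hopscotch,
)

spec = PhantomSpec(shortening_amplitude=0.2, n_frames=32, seed=3)
masks, _ = generate_phantom_sequence(spec)
result = analyze(masks)
points = generate_comoving_points(spec, n_points=50)
hs = run_hopscotch(points, result.partitions)

print(f"points x frames          : {hs.serials.shape[1]} x {hs.serials.shape[0]}")
print(f"mean serial difference   : {hs.mean_difference:+.4f}")
print(f"mean |serial difference| : {hs.mean_abs_difference:.4f}")
print(f"max |serial difference|  : {hs.max_abs_difference:.0f}")
print(f"points outside any block : {hs.outside_flags.sum()} assignments (snapped to nearest)")
print()
print("A signed mean within a few hundredths of zero means a material")
print("point almost never changes its block: the tracking-free block")
print("registration agrees with explicit point tracking.")
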