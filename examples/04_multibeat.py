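"""Multi-beat analysis: per-cycle end-diastole re-zeroing.

Tracking-based strain accumulates drift over beats; a segmentation-based
method can instead redefine end-diastole for every cycle from the
cavity-area series. On a two-beat phantom the pipeline must find both
end-diastolic frames and restart the strain reference at each.
"""

import numpy as np

from dtwstrain import PhantomSpec, analyze, generate_phantom_sequence

spec = PhantomSpec(shortening_amplitude=0.2, n_frames=32, n_cycles=2, seed=4)
masks, truth = generate_phantom_sequence(spec)
result = analyze(masks)

gc = result.global_curve
print(f"frames analysed        : {len(masks)} (2 cycles x 32)")
print(f"detected ED frames     : {gc.ed_frames.tolist()}")
print(f"true ED phase frames   : {truth.ed_phase_frames.tolist()}")
print(f"strain at detected EDs : {np.round(100 * gc.strain[gc.ed_frames], 3).tolist()} %")
print(f"peak strain per cycle  : {[f'{100 * p:+.2f}%' for p in gc.peak_per_cycle]}")
print()
print("Each cycle is referenced to its own end-diastolic centerline")
print("length, so the strain returns to exactly zero at every detected ED")
print("and per-beat peaks are directly comparable — no drift correction.")
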