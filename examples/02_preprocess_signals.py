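"""From raw signals to 256-sample movement vectors.

Locomotion: 50 N stance segmentation -> body-weight normalization ->
128+128 left/right concatenation.  Handwriting: Savitzky-Golay filter ->
first-letter extraction (cut at the W-to-'e' pressure minimum) ->
time normalization -> z-standardize -> [0, 1].
"""

import numpy as np

from crossmove import (detect_ground_contacts, make_domain_maps,
                       make_population, preprocess_writing,
                       simulate_walking_recording, simulate_writing_trial)
from crossmove.preprocess import locomotion_stride_vectors, scale_unit_interval

subjects = make_population(3, seed=21)
maps = make_domain_maps(21)

rec = simulate_walking_recording(subjects[0], maps["walking"], 1.0,
                                 n_strides=6, seed=2)
contacts = detect_ground_contacts(rec.left)
print(f"left-foot stances detected: {len(contacts)}; first at samples "
      f"[{contacts[0].start}, {contacts[0].end})")

vectors = locomotion_stride_vectors(rec)
print(f"stride vectors: {len(vectors)} x {vectors[0].shape[0]} values, "
      f"peak {max(v.max() for v in vectors):.2f} body weight before scaling")
scaled = scale_unit_interval(vectors[0])
print(f"after per-trial scaling: min={scaled.min():.1f}, max={scaled.max():.1f}")

pen = simulate_writing_trial(subjects[0], maps["writing"], "bigger", seed=3,
                             attach_e=True)
mv = preprocess_writing(pen, subject_id=0, trial_id="demo")
print(f"writing vector: {mv.values.shape[0]} samples in "
      f"[{mv.values.min():.1f}, {mv.values.max():.1f}], "
      f"condition={mv.condition!r}")
print("first 8 values:", np.round(mv.values[:8], 3))
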