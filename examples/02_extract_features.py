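"""Extract the 43 per-block features from one synthetic subject.

The pipeline concatenates the subject's speech segments and cuts them into
10-s blocks advanced by 5 s; each block yields 7 spectral-moment features,
9 intensity and 9 intensity-delta statistics, and 9 F0 and 9 F0-delta
statistics.
"""

from advoice import CohortSpec, FrameGrid, extract_speech, simulate_subjects
from advoice.features import cohort_feature_table

spec = CohortSpec(n_patient=1, n_healthy=1, duration_s=40.0, seed=2)
recordings = [(rec.subject_id, rec.group, extract_speech(rec))
              for rec, _ in simulate_subjects(spec)]

table = cohort_feature_table(recordings, 44100, FrameGrid(sample_rate=44100))
print(f"{len(table)} blocks x {table.shape[1] - 3} features")
cols = ["subject_id", "block_index", "spectrum.cog_mean",
        "spectrum.kurtosis_sd", "intensity.mean", "f0.mean"]
print(table[cols].round(3).to_string(index=False))
print("\nspectrum.cog_mean is the power-weighted mean frequency (Hz) of each")
print("block; f0.mean the average voiced pitch (Hz); intensity.mean the")
print("average frame RMS amplitude on a linear scale.")
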