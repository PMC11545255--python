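"""Screen all 43 features for case-control differences with Welch t-tests.

Prints the comparison table rows for the spectrum family: group means +- SD
and the two-sided p-value at the 5% level. On this strong-contrast synthetic
cohort the spectral-envelope features separate the groups sharply.
"""

from advoice import CohortSpec, FrameGrid, compare_all, extract_speech, simulate_subjects
from advoice.compare import format_p
from advoice.features import cohort_feature_table

spec = CohortSpec(n_patient=6, n_healthy=6, duration_s=30.0, seed=3)
table = cohort_feature_table(
    [(r.subject_id, r.group, extract_speech(r))
     for r, _ in simulate_subjects(spec)], 44100, FrameGrid(sample_rate=44100))

comparison = compare_all(table)
spectrum = comparison[comparison["feature"].str.startswith("spectrum.")]
for r in spectrum.itertuples():
    print(f"{r.feature:28s} {r.patient_mean:9.3f} ± {r.patient_sd:7.3f}   "
          f"{r.healthy_mean:9.3f} ± {r.healthy_sd:7.3f}   p {format_p(r.p_value)}")
print(f"\n{int(comparison['significant'].sum())} of 43 features significant "
      "at the 5% level. The patient centroid sits below the healthy one")
print("because the gentle patient roll-off removes more mid-band energy.")
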