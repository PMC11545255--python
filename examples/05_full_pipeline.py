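"""Run every stage end-to-end and render the report.

simulate -> extract (speech concatenation, noise remix, blocks, features)
-> compare (Welch screening) -> evaluate (single-feature LR/SVM/RF, 5-fold)
-> report (tables + per-fold ROC panels). All artifacts land in one run
directory; re-running with the same config reuses cached features.
"""

import tempfile
from pathlib import Path

from advoice import RunConfig, report, run

out = Path(tempfile.mkdtemp(prefix="advoice_run_"))
cfg = RunConfig(mode="synthetic", out_dir=str(out), seed=5,
                n_patient=3, n_healthy=3, duration_s=30.0)
run(cfg)
report_path = report(out, max_roc_features=2)

print("artifacts:")
for p in sorted(out.iterdir()):
    print("  ", p.name)
print(f"\nreport: {report_path}")
print("features.csv holds one row per 10-s block (43 features); table2.csv")
print("the screening; summary.csv the fold-mean classifier metrics.")
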