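"""Run the full scaled study end to end and summarize its headline results.

Generates the bundled three-condition cohort (tracking CF moving from the
syllable rate toward the modulation rate while overall coupling gain drops),
runs coherence -> parametrization -> inference, and prints the numbers the
study design is built to recover. Writes all tables plus a markdown report
under ``study_results/``.
"""

import json
from pathlib import Path

import pandas as pd

import trackshift as ts

cfg = ts.demo_config(seed=1, n_subjects=8)  # 12 in the full design; 8 runs faster
out = ts.run_study(cfg, "study_results")

tracking = pd.read_csv(out / "tracking_table.tsv", sep="\t")
print(tracking.groupby("condition")[["band_coh", "cf", "height", "offset"]]
      .mean().round(3))

stats = pd.read_csv(out / "stats_absdiff.tsv", sep="\t")
inter = stats[stats.effect == "tracking x vocoding"].iloc[0]
print(f"\ntracking x vocoding interaction: F = {inter['stat']:.1f}, "
      f"p_gg = {inter['p_gg']:.2g}")

dom = json.loads((out / "dominance.json").read_text())
if "dominance" in dom:
    print("dominance of task performance:",
          {k: round(v, 3) for k, v in dom["dominance"].items()})
print(f"\nfull report: {out / 'report.md'}")
print("Band coherence and offset fall with vocoding while peak height holds;")
print("the rising CF drives the interaction — tracking shifts from the syllable")
print("rate toward the acoustic modulation rate as intelligibility drops.")
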