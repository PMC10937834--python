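"""Simulate a bed-rest-style cohort and inspect its ground truth.

Generates 12 participants × 6 sessions × 6 clock times with ~25% rhythmic
transcripts, then summarizes the planted rhythms per session.
"""
import numpy as np

from rhythmix import SimConfig, generate_cohort, truth_summary

cfg = SimConfig(n_participants=12, n_transcripts=400, seed=1)
gem, meta, melatonin, truth = generate_cohort(cfg)

print(f"expression matrix: {gem.shape[0]} transcripts x {gem.shape[1]} samples")
print(f"samples retained after dropout: {gem.shape[1]} "
      f"of {12 * 6 * 6} scheduled")

counts, hist = truth_summary(truth)
print("\ntrue rhythmic transcripts per session (amplitude scaling shrinks the")
print("detectable set mid-bed-rest even though the planted set is fixed):")
print(counts.to_string())
night = hist.loc["BDC1", [f"h{h:02d}" for h in (0, 1, 2, 3, 4, 5)]].sum()
print(f"\nof the BDC1 rhythmic transcripts, {night} peak between 00:00-06:00 —")
print("the night mode of the bimodal day/night acrophase distribution.")
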