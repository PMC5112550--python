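"""Simulate the two study-sized cohorts (55 patients-like, 149 controls-like).

Writes per-subject pulse and respiration waveforms (two-column CSV), true
IBI files and the cohort manifest under scratch/study_run/simulated/ (bulky
signal files stay out of version control; later stages read them from
there).

Run from the repository root:  python analysis/01_simulate_cohort.py [--seed 1]
"""

import argparse
import time

from cardioresp.pipeline import RunConfig, run_simulate

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out-dir", default="scratch/study_run")
args = parser.parse_args()

config = RunConfig(out_dir=args.out_dir, seed=args.seed)
t0 = time.time()
manifest = run_simulate(config)
by_group = manifest.groupby("group").size()
print(f"simulated {len(manifest)} subjects in {time.time() - t0:.0f} s:")
print(by_group.to_string())
print(f"manifest: {config.manifest_path}")
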