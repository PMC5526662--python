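#!/usr/bin/env python
"""Stage 4 — STN-cortex phase coupling around the stop cue.

Computes windowed intersite phase clustering between the contralateral STN
bipolar and the contralateral motor channel (C3/C4) in the gamma bands,
normalized by the -350:0 ms pre-cue baseline, and tests the post-cue
change against zero with the 1-sample cluster permutation.

Run after 01_simulate.py:  python analysis/04_connectivity.py [--seed 1]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import stopgamma as sg
from stopgamma.pipeline import AnalysisConfig, run_pipeline
from stopgamma.stats import cluster_permutation

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--trials", type=int, default=16)
parser.add_argument("--rate", type=float, default=400.0)
args = parser.parse_args()

out = Path("results/ispc")
out.mkdir(parents=True, exist_ok=True)

cfg = AnalysisConfig(
    sim=sg.SimConfig(n_subjects=9, n_stop_trials=args.trials,
                     sample_rate=args.rate, seed=args.seed,
                     gamma_coupling_amp=0.5),
    contrasts=("ispc_change",),
    n_perm=500,
    stats_seed=args.seed + 4000,
)
bundle = run_pipeline(cfg)

inv = bundle["summary"].get("ispc_change")
if inv is None:
    raise SystemExit("no ISPC maps produced (missing target channel?)")
freqs, times = bundle["ispc_axes"]
res = bundle["ispc_change"]

# group-mean ISPC change per band, post-cue window
maps = np.stack([s["ispc_norm"].values for s in bundle["subjects"]
                 if s.get("ispc_norm") is not None])
post = (times >= 0.0) & (times <= 0.16)
tbl = pd.DataFrame({
    "freq_hz": freqs,
    "mean_ispc_change_post": np.nanmean(maps[:, :, post], axis=(0, 2)),
})
tbl.to_csv(out / "ispc_change_by_band.tsv", sep="\t", index=False,
           float_format="%.5f")

print(f"ISPC (STN seed -> contralateral motor cortex), "
      f"{maps.shape[0]} subjects, bands {freqs.min():.0f}-{freqs.max():.0f} Hz")
print(f"significant clusters: {inv['n_significant']}")
for c in inv["clusters"][:4]:
    tag = "+" if c["sign"] > 0 else "-"
    print(f"  {tag} mass={c['mass']:8.1f}  p={c['p_perm']:.4f}  "
          f"f={c.get('freq_hz')} Hz  t={c['time_s']} s")
band = (freqs >= 60) & (freqs <= 80)
print(f"mean post-cue 60-80 Hz ISPC change: "
      f"{np.nanmean(maps[:, band][:, :, post]):+.4f} "
      "(the cohort carries a shared STN-M1 gamma carrier that collapses "
      "after the cue, so this should be clearly negative)")
print("wrote", out / "ispc_change_by_band.tsv")
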