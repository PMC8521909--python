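"""Generate the default synthetic study cohort and summarize its signals.

25 JIA + 18 healthy baseline subjects and 10 attenuated follow-ups, four
accelerometer channels each, 10 flexion/extension cycles of ~4 s at a
desk-scale 25 kHz.  Healthy sessions are noise-like; JIA sessions carry
high-energy clicks whose peak factor this script tabulates per class.

Writes results/cohort_summary.csv and prints the per-class signal stats.
"""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from jae.config import load_config
from jae.synthetic import generate_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = load_config(overrides={"seed": args.seed})
    sessions = generate_cohort(cfg.cohort_spec())
    rows = []
    for s in sessions:
        x = s.recordings[0].samples.astype(float)
        rows.append({
            "subject_id": s.subject_id, "visit": s.visit,
            "group_label": s.group_label,
            "n_channels": len(s.recordings),
            "duration_s": round(s.recordings[0].duration, 3),
            "rms": round(float(np.sqrt(np.mean(x ** 2))), 4),
            "peak_over_rms": round(float(np.max(np.abs(x))
                                         / np.sqrt(np.mean(x ** 2))), 2),
        })
    df = pd.DataFrame(rows)
    args.out.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out / "cohort_summary.csv", index=False)

    print(f"{len(sessions)} sessions "
          f"({(df.visit == 'baseline').sum()} baseline, "
          f"{(df.visit == 'followup').sum()} follow-up)")
    print(df.groupby(["visit", "group_label"])[["rms", "peak_over_rms"]]
          .mean().round(2))
    print("\nJIA baselines show a markedly higher peak/RMS ratio than "
          "healthy controls (the clicks); after the 5-fold click "
          "attenuation, follow-ups return to near-healthy peak factors.")


if __name__ == "__main__":
    main()
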