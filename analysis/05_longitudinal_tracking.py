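"""Longitudinal joint-health-score tracking over paired visits.

Scores each follow-up subject's baseline and post-treatment sessions with
a model trained on the other subjects' baselines, and tests the score drop
with a one-tailed paired t-test.

Writes results/paired.json and prints the per-subject score trajectories.
"""

import argparse
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from jae.config import load_config
from jae.features import FeatureMatrix
from jae.longitudinal import paired_one_tailed_ttest, score_pairs


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--features", type=Path, default=Path("results/features.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = load_config()
    X = FeatureMatrix.from_csv(args.features)
    pairs = score_pairs(X, ridge=cfg.ridge, threshold=cfg.threshold)
    tt = paired_one_tailed_ttest(pairs.deltas)

    for _, row in pairs.table.iterrows():
        print(f"  {row.subject_id}: {row.baseline_score:.3f} -> "
              f"{row.followup_score:.3f}  (drop {row.delta:+.3f})")
    print(f"mean drop {tt.mean_delta:.3f} +/- {tt.sd_delta:.3f}; "
          f"t = {tt.t_statistic:.1f}, dof = {tt.dof}, "
          f"one-tailed p = {tt.p_value:.2e}")

    args.out.mkdir(parents=True, exist_ok=True)
    with open(args.out / "paired.json", "w") as fh:
        json.dump({"pairs": pairs.table.to_dict(orient="records"),
                   "t_statistic": tt.t_statistic, "dof": tt.dof,
                   "p_value": tt.p_value, "mean_delta": tt.mean_delta,
                   "sd_delta": tt.sd_delta}, fh, indent=2)
    print(f"wrote {args.out / 'paired.json'}")


if __name__ == "__main__":
    main()
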