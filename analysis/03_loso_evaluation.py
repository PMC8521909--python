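"""Leave-one-subject-out evaluation of the joint health score.

Reads results/features.csv (from 02), runs LOSO logistic regression with
per-fold standardization, and reports cycle-level and subject-level
accuracy, the confusion-derived metrics, and the ROC AUC.

Writes results/report.json and results/roc.csv.
"""

import argparse
import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from jae.config import load_config
from jae.features import FeatureMatrix
from jae.model import loso_evaluate


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--features", type=Path, default=Path("results/features.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = load_config()
    X = FeatureMatrix.from_csv(args.features)
    result, reports = loso_evaluate(X, ridge=cfg.ridge, threshold=cfg.threshold)

    cyc = reports["cycle"]
    print(f"cycle accuracy   {100 * cyc.accuracy:5.1f}%   "
          f"(sens {100 * cyc.sensitivity:.1f}%, spec {100 * cyc.specificity:.1f}%, "
          f"AUC {cyc.auc:.3f})")
    print(f"subject accuracy {100 * reports['subject_mean'].accuracy:5.1f}%  "
          f"(mean-probability rule)")
    print(f"subject accuracy {100 * reports['subject_majority'].accuracy:5.1f}%  "
          f"(majority-of-cycles rule)")

    args.out.mkdir(parents=True, exist_ok=True)
    payload = {
        "cycle_metrics": cyc.to_dict(),
        "subject_metrics_mean_rule": reports["subject_mean"].to_dict(),
        "subject_metrics_majority_rule": reports["subject_majority"].to_dict(),
        "subject_scores": result.subject_scores,
        "subject_truth": result.subject_truth,
    }
    with open(args.out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    pd.DataFrame({"fpr": cyc.roc_fpr, "tpr": cyc.roc_tpr}).to_csv(
        args.out / "roc.csv", index=False)
    print(f"wrote {args.out / 'report.json'}")


if __name__ == "__main__":
    main()
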