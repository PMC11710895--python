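#!/usr/bin/env python
"""Predict low/high behavioral change from baseline dynamic networks.

For each measure (sitting time st, step count ns): median-split labels, 100
balanced 28/8 train-test subsamplings (the same scheme for both measures),
per-split HOSVD reduction fitted on training subjects only, linear SVM (C=1),
and aggregation of accuracy / sensitivity / specificity / cross-entropy.
Writes per-measure metrics JSON and the averaged weight matrix TSV.
"""

import argparse
from pathlib import Path

import numpy as np

from sednet import (
    PipelineConfig,
    cohort_labels,
    load_tensor,
    make_split_scheme,
    read_cohort_manifest,
    run_repeated_cv,
    write_metrics_json,
)


def load_tensors(tensor_dir: Path, subject_ids: list[str]) -> dict:
    return {sid: load_tensor(tensor_dir / f"{sid}.npz") for sid in subject_ids}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--tensors", type=Path, default=Path("scratch/tensors"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-splits", type=int, default=100)
    ap.add_argument("--variance", type=float, default=0.85)
    ap.add_argument("--rank", type=int, default=None,
                    help="fix the reduced rank (default: minimal rank capturing --variance)")
    ap.add_argument("--seed", type=int, default=42)
    args = ap.parse_args()

    manifest = read_cohort_manifest(args.cohort / "manifest.csv")
    tensors = load_tensors(args.tensors, manifest.subject_ids)
    config = PipelineConfig(variance_threshold=args.variance, rank=args.rank)

    scheme = None
    for measure in ("st", "ns"):
        labels = cohort_labels(manifest, measure)
        if scheme is None:  # one scheme, reused verbatim for both measures
            n = len(labels.labels)
            n_test = max(2, int(round(n * 8 / 36 / 2)) * 2)
            scheme = make_split_scheme(
                labels, n_splits=args.n_splits, n_train=n - n_test,
                n_test=n_test, seed=args.seed,
            )
        result = run_repeated_cv(tensors, labels, scheme, config)
        m, s = result.metrics.mean, result.metrics.std
        print(f"{measure}: rank {result.rank}, accuracy {m['accuracy']:.2f}+-{s['accuracy']:.2f}, "
              f"sensitivity {m['sensitivity']:.2f}+-{s['sensitivity']:.2f}, "
              f"specificity {m['specificity']:.2f}+-{s['specificity']:.2f}, "
              f"cross-entropy {m['cross_entropy']:.4f}+-{s['cross_entropy']:.4f}")
        write_metrics_json(
            {
                "measure": measure,
                "n_splits": result.metrics.n_splits,
                "rank": result.rank,
                "mean": m,
                "std": s,
                "per_split": [vars(sm) for sm in result.metrics.per_split],
                "config": {"variance_threshold": args.variance, "rank": args.rank,
                           "svm_cost": config.svm_cost, "seed": args.seed},
            },
            args.out / f"predict_{measure}.json",
        )
        np.savetxt(args.out / f"weights_{measure}.tsv",
                   result.weight_summary.matrix, fmt="%.6g", delimiter="\t")
    print(f"wrote metrics and weight matrices to {args.out}")


if __name__ == "__main__":
    main()
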