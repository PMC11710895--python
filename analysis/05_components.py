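#!/usr/bin/env python
"""Reconstruct and rank the network components behind the prediction.

Refits the per-split connectivity bases (same scheme as the prediction run),
sign-aligns and averages each leading component's singular vector across the
splits, reports normalized variances, and writes each component's top-1%
edge list and node-degree table (region, subnetwork, degree).
"""

import argparse
from pathlib import Path

from sednet import (
    PipelineConfig,
    average_components_across_splits,
    cohort_labels,
    load_tensor,
    make_split_scheme,
    normalized_variances,
    read_atlas_info,
    read_cohort_manifest,
    run_repeated_cv,
    threshold_component_edges,
    write_edge_list,
    write_node_table,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--tensors", type=Path, default=Path("scratch/tensors"))
    ap.add_argument("--out", type=Path, default=Path("results/components"))
    ap.add_argument("--n-components", type=int, default=4)
    ap.add_argument("--top-fraction", type=float, default=0.01)
    ap.add_argument("--n-splits", type=int, default=100)
    ap.add_argument("--seed", type=int, default=42)
    args = ap.parse_args()

    manifest = read_cohort_manifest(args.cohort / "manifest.csv")
    tensors = {
        sid: load_tensor(args.tensors / f"{sid}.npz") for sid in manifest.subject_ids
    }
    n_regions = next(iter(tensors.values())).n_regions
    atlas = read_atlas_info(args.cohort / "atlas.csv", n_regions)

    labels = cohort_labels(manifest, "st")
    n = len(labels.labels)
    n_test = max(2, int(round(n * 8 / 36 / 2)) * 2)
    scheme = make_split_scheme(
        labels, n_splits=args.n_splits, n_train=n - n_test, n_test=n_test, seed=args.seed
    )
    result = run_repeated_cv(tensors, labels, scheme, PipelineConfig())

    nv = normalized_variances(result.bases[0])
    below = next((i + 1 for i, v in enumerate(nv) if v < 0.25), None)
    print(f"rank {result.rank}; normalized variance drops below 0.25 at component {below}")

    n_show = min(args.n_components, result.rank)
    for idx in range(1, n_show + 1):
        comp = average_components_across_splits(result.bases, idx)
        comp = threshold_component_edges(comp, args.top_fraction)
        write_edge_list(comp.top_edges, args.out / f"component_{idx}_edges.tsv")
        write_node_table(comp.node_degrees, atlas, args.out / f"component_{idx}_nodes.tsv")
        top_region = int(comp.node_degrees.argmax()) + 1
        print(f"component {idx}: normalized variance {comp.normalized_variance:.3f}, "
              f"{len(comp.top_edges)} edges kept, highest-degree region {top_region} "
              f"({atlas.loc[top_region, 'subnetwork']})")
    print(f"wrote edge/node tables to {args.out}")


if __name__ == "__main__":
    main()
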