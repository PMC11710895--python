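#!/usr/bin/env python
"""Build every subject's dynamic connectivity tensor and cache it.

Sliding-window Pearson correlation (61-TR window, 1-TR shift), diagonal
zeroed, each window proportionally thresholded to the top 10% strongest
connections. Tensors are cached per subject (npz) for the downstream drivers.
"""

import argparse
import time
from pathlib import Path

from sednet import (
    WindowSpec,
    build_dynamic_networks,
    read_cohort_manifest,
    read_subject_timeseries,
    save_tensor,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--out", type=Path, default=Path("scratch/tensors"))
    ap.add_argument("--window", type=int, default=61)
    ap.add_argument("--shift", type=int, default=1)
    ap.add_argument("--shape", choices=["rectangular", "tapered"], default="rectangular")
    ap.add_argument("--density", type=float, default=0.10)
    args = ap.parse_args()

    manifest = read_cohort_manifest(args.cohort / "manifest.csv")
    spec = WindowSpec(length_trs=args.window, shift_trs=args.shift, shape=args.shape)
    t0 = time.time()
    for _, row in manifest.records.iterrows():
        ts = read_subject_timeseries(
            row["timeseries_path"], subject_id=str(row["subject_id"])
        )
        tensor = build_dynamic_networks(ts, spec, density=args.density)
        save_tensor(tensor, args.out / f"{tensor.subject_id}.npz")
    print(f"built {len(manifest)} tensors "
          f"({tensor.data.shape[0]}x{tensor.data.shape[1]}x{tensor.data.shape[2]}, "
          f"{tensor.n_retained_edges} edges/slice) in {time.time() - t0:.1f}s -> {args.out}")


if __name__ == "__main__":
    main()
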