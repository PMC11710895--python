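"""Reading and writing of ROI time series, atlas metadata and cohort manifests.

File conventions
----------------
* **Time series**: UTF-8 TSV, rows = time points (TRs), columns = regions in
  atlas order. An optional single header row is auto-detected (any non-numeric
  token in the first row). Values are written in decimal notation with 12
  significant digits so a write/read round trip is bit-faithful at that
  precision.
* **Atlas**: CSV with header ``region_id,label,x,y,z,subnetwork`` where
  ``subnetwork`` is one of the eight canonical resting-state subnetworks.
* **Manifest**: CSV with header
  ``subject_id,timeseries_path,st_baseline,st_6mo,ns_baseline,ns_6mo`` —
  daily sitting time in min/day and daily step counts, at baseline and after
  the six-month intervention.

Atlas rows and time-series columns are joined strictly by ``region_id``
position, never by label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DimensionError, ParseError, ValidationError

SUBNETWORKS = ("DMN", "CEN", "DAN", "SMN", "SAL", "BGN", "VIS", "FTN")
"""The eight canonical subnetworks regions are assigned to."""

MANIFEST_COLUMNS = (
    "subject_id",
    "timeseries_path",
    "st_baseline",
    "st_6mo",
    "ns_baseline",
    "ns_6mo",
)


@dataclass
class SubjectTimeSeries:
    """One subject's preprocessed ROI signal matrix, time points x regions."""

    subject_id: str
    data: np.ndarray  # (T', N) float64
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DimensionError(
                f"time series must be 2-D (time x regions), got shape {self.data.shape}"
            )
        t, n = self.data.shape
        if t < 2 or n < 2:
            raise DimensionError(
                f"time series needs >=2 time points and >=2 regions, got {t}x{n}"
            )
        if self.tr_seconds <= 0:
            raise ValidationError(f"tr_seconds must be positive, got {self.tr_seconds}")
        bad = ~np.isfinite(self.data)
        if bad.any():
            t_i, r_i = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite value at time point {t_i + 1}, region {r_i + 1} "
                f"of subject {self.subject_id!r}"
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class CohortManifest:
    """Subject roster with time-series paths and behavioral measurements."""

    records: pd.DataFrame  # columns = MANIFEST_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        ids = self.records["subject_id"].astype(str)
        dup = ids[ids.duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate subject_id(s) in manifest: {sorted(set(dup))}")
        behav = self.records[list(MANIFEST_COLUMNS[2:])].to_numpy(dtype=float)
        if not np.isfinite(behav).all():
            raise ValidationError("manifest contains non-finite behavioral values")
        if (behav < 0).any():
            raise ValidationError("manifest contains negative behavioral values")

    @property
    def subject_ids(self) -> list[str]:
        return [str(s) for s in self.records["subject_id"]]

    def __len__(self) -> int:
        return len(self.records)


def _first_row_is_header(path: Path) -> bool:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    for tok in first.rstrip("\n").split("\t"):
        try:
            float(tok)
        except ValueError:
            return True
    return False


def read_subject_timeseries(
    path: str | Path,
    expected_regions: int | None = None,
    subject_id: str | None = None,
    tr_seconds: float = 2.0,
) -> SubjectTimeSeries:
    """Read one subject's TSV time-series matrix (rows = TRs, columns = ROIs).

    Parameters
    ----------
    path:
        TSV file, optionally with a single header row.
    expected_regions:
        If given, the column count must match exactly.
    subject_id:
        Defaults to the file stem.
    """
    path = Path(path)
    header = 0 if _first_row_is_header(path) else None
    try:
        frame = pd.read_csv(path, sep="\t", header=header, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas-level I/O failure
        raise ParseError(f"could not read {path}: {exc}") from exc
    raw = frame.to_numpy()
    data = np.empty(raw.shape, dtype=float)
    for (i, j), cell in np.ndenumerate(raw):
        try:
            data[i, j] = float(cell)
        except (TypeError, ValueError):
            offset = 2 if header == 0 else 1
            raise ParseError(
                f"{path}: non-numeric cell {cell!r} at row {i + offset}, column {j + 1}"
            ) from None
    if expected_regions is not None and data.shape[1] != expected_regions:
        raise DimensionError(
            f"{path}: expected {expected_regions} region columns, found {data.shape[1]}"
        )
    sid = subject_id if subject_id is not None else path.stem
    return SubjectTimeSeries(subject_id=sid, data=data, tr_seconds=tr_seconds)


def write_subject_timeseries(ts: SubjectTimeSeries, path: str | Path) -> None:
    """Write a time-series matrix as TSV with 12 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, ts.data, fmt="%.12g", delimiter="\t")


def read_atlas_info(path: str | Path, n_regions: int) -> pd.DataFrame:
    """Read atlas metadata covering exactly regions ``1..n_regions``.

    Returns a DataFrame indexed by ``region_id`` with columns
    ``label, x, y, z, subnetwork``, sorted by region_id.
    """
    atlas = pd.read_csv(path)
    required = ["region_id", "label", "x", "y", "z", "subnetwork"]
    missing = [c for c in required if c not in atlas.columns]
    if missing:
        raise ValidationError(f"atlas missing columns: {missing}")
    bad_codes = sorted(set(atlas["subnetwork"]) - set(SUBNETWORKS))
    if bad_codes:
        raise ValidationError(
            f"unknown subnetwork code(s) {bad_codes}; expected one of {SUBNETWORKS}"
        )
    ids = sorted(int(r) for r in atlas["region_id"])
    if ids != list(range(1, n_regions + 1)):
        expected = set(range(1, n_regions + 1))
        found = set(ids)
        raise ValidationError(
            f"atlas region_ids must be exactly 1..{n_regions}; "
            f"missing {sorted(expected - found)}, unexpected {sorted(found - expected)}"
        )
    atlas = atlas.astype({"region_id": int}).set_index("region_id").sort_index()
    return atlas[["label", "x", "y", "z", "subnetwork"]]


def read_cohort_manifest(path: str | Path, check_paths: bool = True) -> CohortManifest:
    """Read the cohort manifest CSV; time-series paths resolve relative to it."""
    path = Path(path)
    records = pd.read_csv(path, dtype={"subject_id": str})
    manifest = CohortManifest(records=records)
    resolved = [
        p if Path(p).is_absolute() else str(path.parent / p)
        for p in manifest.records["timeseries_path"]
    ]
    manifest.records = manifest.records.assign(timeseries_path=resolved)
    if check_paths:
        missing = [p for p in resolved if not Path(p).exists()]
        if missing:
            raise ValidationError(f"manifest time-series paths do not exist: {missing[:3]}")
    return manifest


def write_cohort_manifest(manifest: CohortManifest, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.records.to_csv(path, index=False)


def write_metrics_json(metrics: dict, path: str | Path) -> None:
    """Write a result dictionary as indented JSON (numpy scalars coerced)."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(metrics, fh, indent=2, default=_default)
        fh.write("\n")


def write_edge_list(edges: list[tuple[int, int, float]], path: str | Path) -> None:
    """Write component edges as TSV: region_i, region_j, weight (1-based ids)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("region_i\tregion_j\tweight\n")
        for i, j, w in edges:
            fh.write(f"{i}\t{j}\t{w:.12g}\n")


def write_node_table(
    node_degrees: np.ndarray, atlas: pd.DataFrame | None, path: str | Path
) -> None:
    """Write per-region degree table: region_id, label, subnetwork, degree."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("region_id\tlabel\tsubnetwork\tdegree\n")
        for idx, deg in enumerate(node_degrees, start=1):
            if atlas is not None and idx in atlas.index:
                label = atlas.loc[idx, "label"]
                subnet = atlas.loc[idx, "subnetwork"]
            else:
                label, subnet = f"region_{idx}", "NA"
            fh.write(f"{idx}\t{label}\t{subnet}\t{int(deg)}\n")
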