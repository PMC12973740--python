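"""Study orchestration: images + tables in, comparison tables out.

``run_study`` replays the whole analysis on a directory of inputs:

* a metadata CSV (``patient_id,group,age,sex[,cholesterol]``),
* an ROI table (``image,patient_id,region,side,row,col,size``) pointing
  into 8-bit greyscale TIFF/PNG radiographs,
* a landmark CSV (``patient_id,side,role,point_index,row,col``) with
  roles inferior_border / foramen_lower_edge / cortical_inner_margin.

Each ROI is preprocessed and measured (fractal dimension, lacunarity);
each landmark set yields MCW and PMI; the per-patient long-format
metric table is assembled and compared across cholesterol groups.
Missing or degenerate entries are recorded in the run log and excluded
from the affected variable only. A config snapshot is written next to
the outputs so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import group_stats
from .errors import SchemaError
from .fractal import DEFAULT_BOX_SIZES, analyze_patch
from .morphometry import LandmarkSet, pmi
from .preprocess import GreyPatch, RoiSpec, crop_roi, preprocess

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_study",
    "read_cohort",
    "write_results",
    "read_landmark_table",
]

logger = logging.getLogger("mandifrac")

COHORT_COLUMNS = (
    "patient_id",
    "group",
    "age",
    "sex",
    "region",
    "fd",
    "lacunarity",
    "mcw",
    "pmi",
)
LANDMARK_ROLES = (
    "inferior_border",
    "foramen_lower_edge",
    "cortical_inner_margin",
)


@dataclass
class StudyConfig:
    """Serializable parameters of one study run."""

    images_dir: str = "."
    roi_table: str = "rois.csv"
    landmark_table: str = "landmarks.csv"
    metadata_table: str = "metadata.csv"
    output_dir: str = "out"
    sigma: float = 35.0
    offset: int = 128
    threshold: int = 128
    box_sizes: tuple[int, ...] = DEFAULT_BOX_SIZES
    n_offsets: int = 4
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "box_sizes" in data:
            data["box_sizes"] = tuple(int(x) for x in data["box_sizes"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["box_sizes"] = list(self.box_sizes)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class StudyReport:
    metrics: pd.DataFrame
    comparisons: pd.DataFrame
    log: list[str] = field(default_factory=list)


def _read_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        table = pd.read_csv(path)
    except FileNotFoundError:
        raise SchemaError(f"table not found: {path}") from None
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return table


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format cohort table.

    Metric columns may be empty (metric absent for that row), but group
    labels must be valid and every row needs a patient id and region;
    errors name the column and CSV line.
    """
    table = _read_csv(path, ("patient_id", "group", "region"))
    for idx, label in table["group"].items():
        if label not in group_stats.GROUPS:
            raise SchemaError(
                f"{path}: line {idx + 2}, column 'group': "
                f"invalid label {label!r} (expected one of {group_stats.GROUPS})"
            )
    for col in ("fd", "lacunarity", "mcw", "pmi"):
        if col not in table.columns:
            table[col] = np.nan
        else:
            table[col] = pd.to_numeric(table[col], errors="coerce")
    return table


def write_results(
    out_dir: str | Path, metrics: pd.DataFrame, comparisons: pd.DataFrame
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "metrics": out / "patient_metrics.csv",
        "comparisons": out / "group_comparisons.csv",
    }
    metrics.to_csv(paths["metrics"], index=False, float_format="%.6g")
    comparisons.to_csv(paths["comparisons"], index=False, float_format="%.6g")
    return paths


def _load_image(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse an RGB export of a greyscale radiograph
        arr = arr[..., :3].mean(axis=2).round().astype(np.uint8)
    return arr


def read_landmark_table(path: str | Path) -> dict[tuple[str, str], LandmarkSet]:
    """Landmark CSV -> {(patient_id, side): LandmarkSet}."""
    table = _read_csv(
        path, ("patient_id", "side", "role", "point_index", "row", "col")
    )
    bad = ~table["role"].isin(LANDMARK_ROLES)
    if bad.any():
        line = int(table.index[bad][0]) + 2
        raise SchemaError(
            f"{path}: line {line}, column 'role': invalid role "
            f"{table.loc[bad, 'role'].iloc[0]!r}"
        )
    out: dict[tuple[str, str], LandmarkSet] = {}
    for (pid, side), grp in table.groupby(["patient_id", "side"]):
        pieces = {}
        for role, sub in grp.groupby("role"):
            sub = sub.sort_values("point_index")
            pieces[role] = sub[["row", "col"]].to_numpy(dtype=float)
        if set(pieces) != set(LANDMARK_ROLES):
            missing = set(LANDMARK_ROLES) - set(pieces)
            raise SchemaError(
                f"{path}: patient {pid!r} side {side!r} missing role(s) "
                f"{sorted(missing)}"
            )
        out[(str(pid), str(side))] = LandmarkSet(
            inferior_border=pieces["inferior_border"],
            foramen_lower_edge=pieces["foramen_lower_edge"][0],
            cortical_inner_margin=pieces["cortical_inner_margin"],
            side=str(side),
        )
    return out


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full pipeline described by ``config``.

    Deterministic: identical config and inputs produce byte-identical
    output CSVs.
    """
    log: list[str] = []
    images_dir = Path(config.images_dir)
    meta = _read_csv(config.metadata_table, ("patient_id", "group", "age", "sex"))
    meta["patient_id"] = meta["patient_id"].astype(str)
    for idx, label in meta["group"].items():
        if label not in group_stats.GROUPS:
            raise SchemaError(
                f"{config.metadata_table}: line {idx + 2}, column 'group': "
                f"invalid label {label!r}"
            )
    rois = _read_csv(
        config.roi_table,
        ("image", "patient_id", "region", "side", "row", "col", "size"),
    )
    rows = []
    image_cache: dict[str, np.ndarray] = {}
    for _, r in rois.iterrows():
        pid = str(r["patient_id"])
        name = str(r["image"])
        if name not in image_cache:
            image_cache[name] = _load_image(images_dir / name)
        spec = RoiSpec(
            region=str(r["region"]),
            side=str(r["side"]),
            origin=(int(r["row"]), int(r["col"])),
            size=int(r["size"]),
        )
        patch = crop_roi(GreyPatch(image_cache[name], provenance=name), spec)
        prep = preprocess(
            patch,
            sigma=config.sigma,
            offset=config.offset,
            threshold=config.threshold,
        )
        result = analyze_patch(
            prep, box_sizes=config.box_sizes, n_offsets=config.n_offsets
        )
        if result.degenerate:
            log.append(
                f"degenerate patch: patient {pid} region {spec.region} "
                f"({name}); excluded from fd/lacunarity"
            )
            continue
        if result.clamped:
            log.append(
                f"clamped fd for patient {pid} region {spec.region} ({name})"
            )
        rows.append(
            {
                "patient_id": pid,
                "region": spec.region,
                "fd": result.fd,
                "lacunarity": result.lacunarity,
                "mcw": np.nan,
                "pmi": np.nan,
            }
        )
    landmarks = read_landmark_table(config.landmark_table)
    for (pid, side), lset in sorted(landmarks.items()):
        try:
            res = pmi(lset)
        except Exception as exc:  # geometry failures are per-patient data gaps
            log.append(f"morphometry failed: patient {pid} side {side}: {exc}")
            continue
        rows.append(
            {
                "patient_id": pid,
                "region": side,
                "fd": np.nan,
                "lacunarity": np.nan,
                "mcw": res.mcw,
                "pmi": res.pmi,
            }
        )
    metrics = pd.DataFrame(rows)
    known = set(meta["patient_id"])
    orphan = sorted(set(metrics["patient_id"]) - known) if len(metrics) else []
    for pid in orphan:
        log.append(f"no metadata for patient {pid}; rows dropped")
    if len(metrics):
        metrics = metrics[metrics["patient_id"].isin(known)]
        metrics = metrics.merge(
            meta[["patient_id", "group", "age", "sex"]], on="patient_id"
        )
        metrics = metrics.sort_values(["patient_id", "region"]).reset_index(
            drop=True
        )
        metrics = metrics[
            ["patient_id", "group", "age", "sex", "region", "fd",
             "lacunarity", "mcw", "pmi"]
        ]
    comparisons = group_stats.comparisons_to_frame(
        group_stats.compare_all(metrics, alpha=config.alpha)
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_results(out, metrics, comparisons)
    config.to_yaml(out / "config_snapshot.yaml")
    (out / "run.log").write_text("".join(line + "\n" for line in log))
    for line in log:
        logger.warning(line)
    return StudyReport(metrics=metrics, comparisons=comparisons, log=log)
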