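"""Reading and writing the on-disk formats of the pipeline.

Fixel fields travel as NIfTI-1 volumes: a *peaks* image whose last dimension
concatenates the xyz unit vectors of each voxel's fixels (an all-zero triplet
marks an absent fixel), a *fractions* image and one image per metric, each
with the fixel index as last dimension. Streamlines travel as TRK or TCK;
points are always returned in world RAS mm regardless of the on-disk
convention. Summaries and profiles are CSV; run manifests are JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import FixelField
from .geometry import Tract, VoxelGrid
from .maps import MicrostructureMap, TractSummary, WeightMaps

__all__ = [
    "RunConfig",
    "read_fixel_field",
    "write_fixel_field",
    "read_tractogram",
    "write_tractogram",
    "write_outputs",
]

logger = logging.getLogger(__name__)

_AFFINE_TOL = 1e-4


@dataclass
class RunConfig:
    """Configuration of one pipeline run; round-trips losslessly via YAML."""

    peaks: str = ""
    fractions: str = ""
    metrics: Dict[str, str] = dc_field(default_factory=dict)
    tract: str = ""
    strategy: str = "ang"
    weighting: str = "tsl"
    min_length: float = 0.0
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.strategy not in ("vol", "cfo", "ang"):
            raise ValueError(f"strategy must be vol, cfo or ang, got {self.strategy!r}")
        if self.weighting not in ("tsl", "roi"):
            raise ValueError(f"weighting must be tsl or roi, got {self.weighting!r}")

    def to_file(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _check_affines(affines: Mapping[str, np.ndarray]) -> np.ndarray:
    items = list(affines.items())
    ref_name, ref = items[0]
    for name, aff in items[1:]:
        if np.max(np.abs(aff - ref)) > _AFFINE_TOL:
            raise ValueError(
                f"affine mismatch between {ref_name} and {name}:\n{ref}\nvs\n{aff}"
            )
    return ref


def read_fixel_field(
    peaks_path: Union[str, Path],
    fractions_path: Union[str, Path],
    metric_paths: Optional[Mapping[str, Union[str, Path]]] = None,
) -> FixelField:
    """Load a fixel field from peaks / fractions / metric NIfTI volumes.

    The peaks image must be 4D with last dimension ``3 * K_max``; fractions
    and metrics 4D with last dimension ``K_max``. Present peak vectors with
    norm in [0.9, 1.1] are re-normalized; norms outside that band are
    rejected as a layout error.
    """
    metric_paths = metric_paths or {}
    peaks_img = nib.load(str(peaks_path))
    frac_img = nib.load(str(fractions_path))
    peaks = np.asarray(peaks_img.dataobj, dtype=float)
    fractions = np.asarray(frac_img.dataobj, dtype=float)
    if peaks.ndim != 4 or peaks.shape[3] % 3:
        raise ValueError(
            f"peaks image must be 4D with last dimension a multiple of 3 "
            f"(xyz triplets per fixel), got shape {peaks.shape}"
        )
    k_max = peaks.shape[3] // 3
    if fractions.ndim != 4 or fractions.shape != peaks.shape[:3] + (k_max,):
        raise ValueError(
            f"fractions shape {fractions.shape} incompatible with peaks "
            f"{peaks.shape} (expected {peaks.shape[:3] + (k_max,)})"
        )
    affines = {"peaks": peaks_img.affine, "fractions": frac_img.affine}
    metrics = {}
    for name, path in metric_paths.items():
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj, dtype=float)
        if arr.shape != fractions.shape:
            raise ValueError(f"metric {name!r} shape {arr.shape} != {fractions.shape}")
        metrics[name] = arr
        affines[f"metric:{name}"] = img.affine
    affine = _check_affines(affines)

    orientations = peaks.reshape(peaks.shape[:3] + (k_max, 3))
    norms = np.linalg.norm(orientations, axis=-1)
    present = norms >= 1e-8
    bad = present & ((norms < 0.9) | (norms > 1.1))
    if np.any(bad):
        raise ValueError(
            f"{int(bad.sum())} peak vectors have norms outside [0.9, 1.1]; "
            "the peaks image does not look like unit orientation vectors"
        )
    safe = np.where(present, norms, 1.0)
    orientations = orientations / safe[..., None]
    orientations[~present] = 0.0
    return FixelField(
        affine=affine, orientations=orientations, fractions=fractions, metrics=metrics
    )


def write_fixel_field(
    field: FixelField,
    peaks_path: Union[str, Path],
    fractions_path: Union[str, Path],
    metric_paths: Optional[Mapping[str, Union[str, Path]]] = None,
) -> None:
    """Write a fixel field to peaks / fractions / metric NIfTI volumes."""
    metric_paths = metric_paths or {}
    shape = field.shape
    peaks = field.orientations.reshape(shape + (field.k_max * 3,))
    nib.save(nib.Nifti1Image(peaks.astype(np.float32), field.affine), str(peaks_path))
    nib.save(
        nib.Nifti1Image(field.fractions.astype(np.float32), field.affine), str(fractions_path)
    )
    for name, path in metric_paths.items():
        nib.save(
            nib.Nifti1Image(field.metrics[name].astype(np.float32), field.affine), str(path)
        )


def read_tractogram(path: Union[str, Path]) -> Tract:
    """Load a TRK or TCK tractogram; points come back in world RAS mm."""
    path = Path(path)
    try:
        tfile = nib.streamlines.load(str(path))
    except Exception as exc:
        raise ValueError(f"could not parse tractogram {path} ({path.suffix}): {exc}") from exc
    sls = [np.asarray(s, dtype=float) for s in tfile.streamlines]
    if not sls:
        logger.warning("tractogram %s contains no streamlines", path)
    return Tract(streamlines=sls)


def write_tractogram(
    tract: Tract,
    path: Union[str, Path],
    grid: Optional[VoxelGrid] = None,
) -> None:
    """Write a tract to TRK or TCK (chosen by extension), points in RAS mm.

    TRK stores voxel-grid metadata in its header; supply ``grid`` when
    writing TRK so downstream tools see the correct dimensions.
    """
    path = Path(path)
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in tract.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    if path.suffix == ".trk":
        header = {}
        if grid is not None:
            header["voxel_to_rasmm"] = grid.affine.astype(np.float32)
            header["voxel_sizes"] = np.linalg.norm(grid.affine[:3, :3], axis=0).astype(np.float32)
            header["dimensions"] = np.asarray(grid.shape, dtype=np.int16)
        nib.streamlines.save(tractogram, str(path), header=header)
    elif path.suffix == ".tck":
        nib.streamlines.save(tractogram, str(path))
    else:
        raise ValueError(f"unsupported tractogram extension {path.suffix!r} (use .trk or .tck)")


def write_outputs(
    maps: Mapping[str, Union[MicrostructureMap, WeightMaps, np.ndarray]],
    affine: np.ndarray,
    summaries: Sequence[Mapping],
    profiles: Mapping[str, pd.DataFrame],
    out_dir: Union[str, Path],
    config: Optional[RunConfig] = None,
    version: Optional[str] = None,
) -> Dict:
    """Write maps (NIfTI), summaries and profiles (CSV) and a JSON manifest.

    NaN is the undefined-voxel sentinel in float volumes and renders as an
    empty field in CSVs. Returns the manifest (also saved as
    ``manifest.json``), which records the written files, the config and the
    software version so a rerun can be reproduced exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise PermissionError(f"output directory {out_dir} is not writable")
    written: Dict[str, str] = {}
    for name, obj in maps.items():
        if isinstance(obj, MicrostructureMap):
            data = obj.values
        elif isinstance(obj, WeightMaps):
            data = obj.fixel_weights
        else:
            data = np.asarray(obj)
        p = out_dir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(data.astype(np.float32), np.asarray(affine, float)), str(p))
        written[name] = p.name
    if summaries:
        rows = []
        for s in summaries:
            row = dict(s)
            if isinstance(row.get("summary"), TractSummary):
                ts = row.pop("summary")
                row.update(
                    mean=ts.mean,
                    weighting=ts.weighting,
                    n_voxels=ts.n_voxels,
                    total_length_mm=ts.total_length_mm,
                )
            rows.append(row)
        p = out_dir / "tract_means.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written["tract_means"] = p.name
    for name, df in profiles.items():
        p = out_dir / f"profile_{name}.csv"
        df.to_csv(p, index=False)
        written[f"profile_{name}"] = p.name
    manifest = {
        "files": written,
        "config": dataclasses.asdict(config) if config else None,
        "seed": config.seed if config else None,
        "version": version,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
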