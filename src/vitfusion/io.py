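"""File formats and run configuration.

Volumes and statistical maps travel as NIfTI-1; connectivity matrices and
block masks as CSV; cohort indexes as a TSV manifest (id, label,
volume_path, fnc_path); the full run configuration as YAML that round-trips
exactly. One root seed is split deterministically into per-stage seeds so
every artifact a run writes is reproducible from its config file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .model import ModelConfig
from .synthetic import CohortConfig, GroundTruth, SubjectRecord
from .training import AugmentConfig, TrainConfig

__all__ = ["VolumeImage", "read_volume", "write_volume", "write_cohort",
           "load_cohort", "InterpretConfig", "RunConfig", "derive_seed"]

_STAGES = ("simulate", "split", "init", "augment", "interpret")


@dataclass
class VolumeImage:
    """A 3D voxel array with its spatial affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


def read_volume(path) -> VolumeImage:
    """Load a 3D NIfTI-1 volume; array and affine survive round-trips bit-exact."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    try:
        img = nib.load(path)
    except nib.filebasedimages.ImageFileError as err:
        raise ValueError(f"{path} is not a readable NIfTI file: {err}") from err
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    elif data.ndim != 3:
        raise ValueError(
            f"{path} is {data.ndim}D; extract individual 3D volumes first")
    return VolumeImage(data=np.asarray(data, dtype=np.float64),
                       affine=np.asarray(img.affine))


def write_volume(image: VolumeImage | np.ndarray, path,
                 affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    if isinstance(image, VolumeImage):
        data, aff = image.data, image.affine
    else:
        data, aff = np.asarray(image), None
    if affine is not None:
        aff = affine
    if aff is None:
        aff = np.eye(4)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), aff), path)
    return path


# -- cohort persistence -------------------------------------------------------

def write_cohort(records: list[SubjectRecord], truth: GroundTruth | None,
                 out_dir) -> Path:
    """Write one NIfTI + one FNC CSV per subject, a TSV manifest, and truth."""
    out_dir = Path(out_dir)
    (out_dir / "volumes").mkdir(parents=True, exist_ok=True)
    (out_dir / "fnc").mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        vpath = out_dir / "volumes" / f"{rec.id}.nii.gz"
        fpath = out_dir / "fnc" / f"{rec.id}.csv"
        write_volume(rec.volume, vpath)
        np.savetxt(fpath, rec.fnc, delimiter=",")
        rows.append({"id": rec.id, "label": rec.label,
                     "volume_path": str(vpath.relative_to(out_dir)),
                     "fnc_path": str(fpath.relative_to(out_dir))})
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    if truth is not None:
        write_volume(truth.voxel_mask.astype(np.float64),
                     out_dir / "truth_voxel_mask.nii.gz")
        pd.DataFrame(truth.block_mask.astype(int),
                     index=truth.partition, columns=truth.partition
                     ).to_csv(out_dir / "truth_block_mask.csv")
    return manifest


def load_cohort(manifest_path) -> tuple[list[SubjectRecord], GroundTruth | None]:
    """Read a cohort back from its manifest; inverse of :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path, sep="\t")
    records = []
    for row in df.itertuples():
        records.append(SubjectRecord(
            id=str(row.id), label=str(row.label),
            volume=read_volume(base / row.volume_path).data,
            fnc=np.loadtxt(base / row.fnc_path, delimiter=","),
        ))
    truth = None
    mask_path = base / "truth_voxel_mask.nii.gz"
    block_path = base / "truth_block_mask.csv"
    if mask_path.exists() and block_path.exists():
        block_df = pd.read_csv(block_path, index_col=0)
        truth = GroundTruth(
            voxel_mask=read_volume(mask_path).data > 0.5,
            block_mask=block_df.to_numpy().astype(bool),
            partition=block_df.index.to_numpy().astype(str),
            effect_blocks=(),
        )
    return records, truth


# -- run configuration --------------------------------------------------------

@dataclass
class InterpretConfig:
    alpha: float = 0.5
    beta: float = 0.5
    aggregation: str = "average"  # or 'rollout'
    threshold_p: float = 0.02
    normalize: str | None = "sum"
    weight_by_fnc: bool = True


@dataclass
class RunConfig:
    """Everything one run needs, serialized alongside its outputs."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    interpret: InterpretConfig = field(default_factory=InterpretConfig)
    out_dir: str = "runs/run"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        ev = d["cohort"]["effect_voxels"]
        if isinstance(ev, np.ndarray):
            d["cohort"]["effect_voxels"] = (
                np.argwhere(ev).tolist() if ev.dtype == bool else ev.tolist())
        d["cohort"]["effect_blocks"] = [list(b)
                                        for b in d["cohort"]["effect_blocks"]]
        return _plain(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cohort = dict(d.get("cohort", {}))
        if cohort.get("effect_voxels") is not None:
            cohort["effect_voxels"] = np.asarray(cohort["effect_voxels"])
        if "effect_blocks" in cohort:
            cohort["effect_blocks"] = tuple(
                tuple(b) for b in cohort["effect_blocks"])
        train = dict(d.get("train", {}))
        if isinstance(train.get("augmentation"), dict):
            train["augmentation"] = AugmentConfig(**train["augmentation"])
        return cls(
            cohort=CohortConfig(**cohort),
            model=ModelConfig(**d.get("model", {})),
            train=TrainConfig(**train),
            interpret=InterpretConfig(**d.get("interpret", {})),
            out_dir=str(d.get("out_dir", "runs/run")),
            seed=int(d.get("seed", 0)),
        )

    def save(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)


def _plain(obj):
    """Recursively convert numpy scalars/sequences to YAML-safe builtins."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def derive_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31) from one root seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {_STAGES}")
    ss = np.random.SeedSequence([int(root_seed), _STAGES.index(stage)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
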