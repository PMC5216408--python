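"""Readers, writers and run configuration.

NIfTI-1 volumes are handled through nibabel; the repetition time is stored
in the header ``pixdim[4]`` with time units set to seconds.  Motion files
are whitespace-delimited text with six columns (translations mm, rotations
radians), one row per volume.  Phenotype tables are UTF-8 TSV with empty
cells for missing values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .datatypes import MotionTrace, Volume4D
from .synthetic import cohort_from_age

__all__ = [
    "read_volume",
    "write_volume",
    "read_motion",
    "write_motion",
    "read_phenotypes",
    "write_phenotypes",
    "RunConfig",
]

PHENOTYPE_COLUMNS = [
    "subject_id", "diagnosis", "age_years", "cohort", "gender", "fiq",
    "ados_comm", "ados_social", "ados_stereo",
]


def write_volume(path, vol: Volume4D) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data), vol.affine)
    zooms = list(vol.voxel_size_mm) + ([vol.tr_s] if vol.data.ndim == 4 else [])
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_volume(path) -> Volume4D:
    """Read a NIfTI-1 file; 3D images (masks) are promoted to t=1 volumes."""
    try:
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # pragma: no cover - malformed input path
        raise ValueError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: expected 3D or 4D image, got ndim={data.ndim}")
    tr = float(zooms[3]) if data.ndim == 4 and len(zooms) > 3 and zooms[3] > 0 else 2.0
    return Volume4D(data, tuple(float(z) for z in zooms[:3]), tr, np.asarray(img.affine))


def write_motion(path, motion: MotionTrace) -> None:
    np.savetxt(str(path), motion.params, fmt="%.8f")


def read_motion(path, tr_s: float = 2.0) -> MotionTrace:
    return MotionTrace(np.loadtxt(str(path), ndmin=2), tr_s)


def write_phenotypes(path, phen: pd.DataFrame) -> None:
    phen.to_csv(str(path), sep="\t", index=False, na_rep="")


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype TSV, deriving the age cohort when absent.

    Cut points: child < 11, adolescent 11-18, adult >= 18.  TC rows may have
    empty ADOS cells; duplicated subject ids are an error.
    """
    phen = pd.read_csv(str(path), sep="\t")
    required = {"subject_id", "diagnosis", "age_years"}
    missing = required - set(phen.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    if not np.issubdtype(phen["age_years"].dtype, np.number):
        raise ValueError("age_years column is not numeric")
    if phen["subject_id"].duplicated().any():
        dup = phen.loc[phen["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicated subject_id: {dup}")
    if "cohort" not in phen.columns:
        phen["cohort"] = phen["age_years"].map(cohort_from_age)
    for col in ("ados_comm", "ados_social", "ados_stereo"):
        if col not in phen.columns:
            phen[col] = np.nan
    return phen


@dataclass
class RunConfig:
    """Every constant of the end-to-end run, serializable to YAML."""

    input_dir: str | None = None
    output_dir: str = "alffdev_out"
    band_hz: tuple[float, float] = (0.01, 0.08)
    discard: int = 10
    fwhm_mm: float = 8.0
    voxel_p: float = 0.01
    cluster_alpha: float = 0.05
    posthoc_family: int = 3
    n_perm: int = 1000
    svr_c: float = 1.0
    svr_epsilon: float = 0.1
    connectivity: int = 6
    seed: int = 0
    exclude_trans_mm: float = 3.0
    exclude_rot_deg: float = 3.0
    write_volumes: bool = False

    def validate(self) -> None:
        if not (0 < self.band_hz[0] < self.band_hz[1]):
            raise ValueError("invalid band")
        if not (0 < self.voxel_p < 1 and 0 < self.cluster_alpha < 1):
            raise ValueError("thresholds must be probabilities")
        if self.n_perm < 1 or self.discard < 0 or self.fwhm_mm < 0:
            raise ValueError("invalid run configuration")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "band_hz" in raw:
            raw["band_hz"] = tuple(raw["band_hz"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg
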