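"""File-format plumbing: cohort CSV, signal-curve CSV, NIfTI volumes, YAML config.

The cohort CSV dialect is fixed (comma separator, dot decimal, header row)
with columns exactly ``subject_id, lvi, reader, mk, md, suvmax, mtv, tlg,
adc, d, dstar, f_pct``.  Signal curves travel as a CSV whose first column
is ``b`` and whose remaining columns are one signal curve each.  Volumes
and parameter maps are NIfTI-1 with the voxel spacing carried in the
affine.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .synthetic import (
    BValueScheme,
    CohortConfig,
    COHORT_COLUMNS,
    PETVolume,
    SignalCurve,
    make_bvalue_scheme,
)

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_curves",
    "read_curves",
    "write_volume",
    "read_volume",
    "read_dwi_stack",
    "write_maps",
    "load_config",
    "dump_config",
]


# ---------------------------------------------------------------- cohort CSV


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    cohort[list(COHORT_COLUMNS)].to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    return df[list(COHORT_COLUMNS)]


# ---------------------------------------------------------- signal-curve CSV


def write_curves(curves: Sequence[SignalCurve], path: str | Path) -> None:
    """Write curves sharing one scheme as columns b, curve_1, curve_2, ..."""
    if not curves:
        raise ValueError("no curves to write")
    scheme = curves[0].scheme
    for c in curves:
        if c.scheme.bvalues != scheme.bvalues:
            raise ValueError("all curves must share one b-value scheme")
    out = pd.DataFrame({"b": scheme.array})
    for i, c in enumerate(curves, start=1):
        out[f"curve_{i}"] = c.array
    out.to_csv(path, index=False)


def read_curves(path: str | Path) -> list[SignalCurve]:
    df = pd.read_csv(path)
    if "b" not in df.columns or df.shape[1] < 2:
        raise ValueError(f"{path}: expected a 'b' column plus >= 1 signal column")
    scheme = make_bvalue_scheme(df["b"].to_list())
    curves = []
    for col in df.columns[1:]:
        sig = df[col].to_numpy(dtype=float)
        curves.append(SignalCurve(scheme, tuple(sig), float(sig[0])))
    return curves


# ------------------------------------------------------------------- NIfTI


def _affine(spacing: Sequence[float]) -> np.ndarray:
    return np.diag([*spacing, 1.0])


def write_volume(volume: PETVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(volume.data, _affine(volume.spacing)), str(path))


def read_volume(path: str | Path) -> PETVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return PETVolume(np.asarray(img.dataobj, dtype=float), spacing)


def read_dwi_stack(
    nifti_path: str | Path, bval_path: str | Path
) -> tuple[np.ndarray, tuple[float, float, float], BValueScheme]:
    """Read a 4-D (x, y, z, b) diffusion stack plus its b-value text file."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{nifti_path}: expected a 4-D stack, got {data.ndim}-D")
    bvals = np.loadtxt(str(bval_path)).ravel()
    if bvals.size != data.shape[-1]:
        raise ValueError(
            f"{bval_path}: {bvals.size} b-values but stack has "
            f"{data.shape[-1]} frames"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, make_bvalue_scheme(bvals.tolist())


def write_maps(
    maps: dict[str, np.ndarray],
    spacing: Sequence[float],
    out_dir: str | Path,
    prefix: str = "",
) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, arr in maps.items():
        p = out_dir / f"{prefix}{name}.nii.gz"
        nib.save(nib.Nifti1Image(arr, _affine(spacing)), str(p))
        paths.append(p)
    return paths


# ------------------------------------------------------------------ config


def load_config(path: str | Path) -> CohortConfig:
    """Parse a YAML cohort config; YAML errors surface with line numbers."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ValueError(f"{path}: malformed config{where}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a key-value mapping")
    kwargs = {}
    for key in ("n_pos", "n_neg", "reader_icc", "quantile_convention", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "calibration" in raw:
        calib = {
            marker: {grp: tuple(vals) for grp, vals in groups.items()}
            for marker, groups in raw["calibration"].items()
        }
        kwargs["calibration"] = calib
    return CohortConfig(**kwargs)


def dump_config(config: CohortConfig, path: str | Path) -> None:
    payload = {
        "n_pos": config.n_pos,
        "n_neg": config.n_neg,
        "reader_icc": config.reader_icc,
        "quantile_convention": config.quantile_convention,
        "seed": config.seed,
        "calibration": {
            marker: {grp: list(vals) for grp, vals in groups.items()}
            for marker, groups in config.calibration.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
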