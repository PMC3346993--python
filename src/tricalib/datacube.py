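"""Data model and I/O for three-way HPLC-DAD arrays.

A :class:`DataCube` holds the I x J x K intensity array (elution time x
wavelength x sample) together with its physical axes; a
:class:`CalibrationDesign` records which samples are calibration
standards, unknowns, or blanks, and the known analyte concentrations.

On disk a cube is a directory with one headerless CSV matrix per sample
(rows = time points, columns = wavelengths) plus a YAML metadata file
carrying the axes, sample roles and known concentrations.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

ROLES = ("calibration", "prediction", "blank")

__all__ = [
    "DataCube",
    "CalibrationDesign",
    "load_cube",
    "save_cube",
    "subtract_blank",
    "select_region",
]


@dataclass(frozen=True)
class DataCube:
    """Three-way absorbance array with axis metadata.

    Parameters
    ----------
    values
        Array of shape ``(I, J, K)``: time x wavelength x sample,
        arbitrary absorbance units. Must be finite.
    time_axis
        Retention times in minutes, strictly increasing, length I.
    wavelength_axis
        Wavelengths in nm, strictly increasing, length J.
    sample_ids
        Unique sample labels, length K.
    """

    values: np.ndarray
    time_axis: np.ndarray
    wavelength_axis: np.ndarray
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        t = np.asarray(self.time_axis, dtype=float)
        w = np.asarray(self.wavelength_axis, dtype=float)
        ids = tuple(str(s) for s in self.sample_ids)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "time_axis", t)
        object.__setattr__(self, "wavelength_axis", w)
        object.__setattr__(self, "sample_ids", ids)
        if values.ndim != 3:
            raise ValueError(f"values must be 3-dimensional, got {values.ndim}")
        if values.shape != (t.size, w.size, len(ids)):
            raise ValueError(
                f"values shape {values.shape} does not match axes "
                f"({t.size}, {w.size}, {len(ids)})"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("values contain non-finite entries")
        for name, axis in (("time_axis", t), ("wavelength_axis", w)):
            if axis.size == 0:
                raise ValueError(f"{name} is empty")
            if axis.size > 1 and not np.all(np.diff(axis) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids contain duplicates")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def slab(self, sample_id: str) -> np.ndarray:
        """Return the I x J measurement matrix of one sample."""
        return self.values[:, :, self.sample_ids.index(str(sample_id))]

    def subset(self, sample_ids: Sequence[str]) -> "DataCube":
        """Cube restricted to the given samples, in the given order."""
        idx = [self.sample_ids.index(str(s)) for s in sample_ids]
        return replace(
            self,
            values=self.values[:, :, idx],
            sample_ids=tuple(str(s) for s in sample_ids),
        )


@dataclass(frozen=True)
class CalibrationDesign:
    """Sample roles and known analyte concentrations.

    ``known_conc`` is indexed by sample id with one column per analyte
    (units carried as the opaque ``conc_unit`` label; the source data
    print mg/mL). Calibration samples must have every analyte
    concentration defined and nonnegative; for prediction samples the
    added concentrations are optional (NaN when unknown) and used only
    for recovery/RMSEP scoring.
    """

    analyte_names: tuple[str, ...]
    known_conc: pd.DataFrame
    roles: pd.Series
    conc_unit: str = "mg/mL"

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.analyte_names)
        object.__setattr__(self, "analyte_names", names)
        roles = self.roles.astype(str)
        roles.index = roles.index.astype(str)
        object.__setattr__(self, "roles", roles)
        bad = set(roles.unique()) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles {sorted(bad)}; allowed: {ROLES}")
        conc = self.known_conc.copy()
        conc.index = conc.index.astype(str)
        missing_cols = set(names) - set(conc.columns)
        if missing_cols:
            raise ValueError(f"known_conc missing analyte columns {sorted(missing_cols)}")
        conc = conc.loc[:, list(names)].astype(float)
        object.__setattr__(self, "known_conc", conc)
        cal = self.sample_ids_with_role("calibration")
        if not set(cal) <= set(conc.index):
            raise ValueError("known_conc must cover every calibration sample")
        cal_block = conc.loc[cal]
        if cal_block.isna().any().any():
            raise ValueError("calibration samples must have all concentrations defined")
        if (cal_block.values < 0).any():
            raise ValueError("known concentrations must be nonnegative")

    def role_of(self, sample_id: str) -> str:
        return str(self.roles.loc[str(sample_id)])

    def sample_ids_with_role(self, role: str) -> list[str]:
        return [str(s) for s in self.roles.index[self.roles == role]]

    def subset(self, sample_ids: Sequence[str]) -> "CalibrationDesign":
        ids = [str(s) for s in sample_ids]
        return replace(
            self,
            roles=self.roles.loc[ids],
            known_conc=self.known_conc.loc[self.known_conc.index.intersection(ids)],
        )

    def validate_against(self, cube: DataCube) -> None:
        """Check that every cube sample has exactly one role."""
        missing = set(cube.sample_ids) - set(self.roles.index)
        if missing:
            raise ValueError(f"samples without a role: {sorted(missing)}")


# ---------------------------------------------------------------------------
# I/O

_METADATA_NAME = "metadata.yaml"


def save_cube(
    cube: DataCube,
    design: CalibrationDesign,
    directory_path: str | os.PathLike,
    fmt: str = "%.12g",
) -> list[Path]:
    """Write one CSV matrix per sample plus a YAML metadata file.

    Returns the list of written paths (metadata first). The default
    float format round-trips through :func:`load_cube` to better than
    1e-8 absolute for order-unity absorbances.
    """
    if cube.shape[2] == 0:
        raise ValueError("cannot save a cube with no samples")
    design.validate_against(cube)
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    if not os.access(directory, os.W_OK):
        raise PermissionError(f"destination {directory} is not writable")

    samples_meta = []
    paths: list[Path] = []
    for k, sid in enumerate(cube.sample_ids):
        fname = f"sample_{sid}.csv"
        np.savetxt(directory / fname, cube.values[:, :, k], fmt=fmt, delimiter=",")
        paths.append(directory / fname)
        entry: dict = {"id": sid, "role": design.role_of(sid), "file": fname}
        if sid in design.known_conc.index:
            row = design.known_conc.loc[sid]
            conc = {a: float(v) for a, v in row.items() if np.isfinite(v)}
            if conc:
                entry["known_conc"] = conc
        samples_meta.append(entry)

    meta = {
        "time_axis": [float(t) for t in cube.time_axis],
        "wavelength_axis": [float(w) for w in cube.wavelength_axis],
        "analytes": list(design.analyte_names),
        "conc_unit": design.conc_unit,
        "samples": samples_meta,
    }
    meta_path = directory / _METADATA_NAME
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return [meta_path] + paths


def load_cube(
    directory_path: str | os.PathLike,
    metadata_path: str | os.PathLike | None = None,
) -> tuple[DataCube, CalibrationDesign]:
    """Read a cube directory written by :func:`save_cube`.

    Fails atomically: any missing file, shape mismatch, duplicate id or
    non-numeric cell raises before anything is returned.
    """
    directory = Path(directory_path)
    meta_path = Path(metadata_path) if metadata_path else directory / _METADATA_NAME
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)

    t = np.asarray(meta["time_axis"], dtype=float)
    w = np.asarray(meta["wavelength_axis"], dtype=float)
    analytes = [str(a) for a in meta.get("analytes", [])]

    ids: list[str] = []
    roles: dict[str, str] = {}
    conc_rows: dict[str, dict[str, float]] = {}
    slabs: list[np.ndarray] = []
    for entry in meta["samples"]:
        sid = str(entry["id"])
        if sid in roles:
            raise ValueError(f"duplicate sample id {sid!r} in metadata")
        path = directory / entry["file"]
        if not path.exists():
            raise FileNotFoundError(f"missing sample file {path}")
        try:
            slab = np.loadtxt(path, delimiter=",", ndmin=2, dtype=float)
        except ValueError as exc:
            raise ValueError(f"non-numeric or ragged data in {path}: {exc}") from exc
        if slab.shape != (t.size, w.size):
            raise ValueError(
                f"{path}: shape {slab.shape} does not match axes ({t.size}, {w.size})"
            )
        ids.append(sid)
        roles[sid] = str(entry["role"])
        if "known_conc" in entry:
            conc_rows[sid] = {str(a): float(v) for a, v in entry["known_conc"].items()}
        slabs.append(slab)

    cube = DataCube(
        values=np.stack(slabs, axis=2),
        time_axis=t,
        wavelength_axis=w,
        sample_ids=tuple(ids),
    )
    known = pd.DataFrame.from_dict(conc_rows, orient="index").reindex(columns=analytes)
    design = CalibrationDesign(
        analyte_names=tuple(analytes),
        known_conc=known,
        roles=pd.Series(roles),
        conc_unit=str(meta.get("conc_unit", "mg/mL")),
    )
    design.validate_against(cube)
    return cube, design


# ---------------------------------------------------------------------------
# Preprocessing


def subtract_blank(
    cube: DataCube,
    blank_ids: Sequence[str],
    keep_blanks: bool = False,
) -> DataCube:
    """Subtract the element-wise mean of the blank slabs from every sample.

    Compensates a constant instrumental baseline, mirroring the standard
    practice of subtracting the measurement matrix of an average blank.
    By default the blank samples are dropped from the returned cube; with
    ``keep_blanks=True`` the mean-subtracted blank slabs are retained
    (useful when blanks must be decomposed jointly, e.g. for detection
    limits).
    """
    blank_ids = [str(b) for b in blank_ids]
    if not blank_ids:
        raise ValueError("blank_ids is empty")
    unknown = set(blank_ids) - set(cube.sample_ids)
    if unknown:
        raise ValueError(f"unknown blank ids: {sorted(unknown)}")
    rest = [s for s in cube.sample_ids if s not in blank_ids]
    if not rest:
        raise ValueError("all samples are blanks; nothing left to correct")
    blank_idx = [cube.sample_ids.index(b) for b in blank_ids]
    mean_blank = cube.values[:, :, blank_idx].mean(axis=2)

    keep = cube.sample_ids if keep_blanks else tuple(rest)
    keep_idx = [cube.sample_ids.index(s) for s in keep]
    corrected = cube.values[:, :, keep_idx] - mean_blank[:, :, None]
    return replace(cube, values=corrected, sample_ids=keep)


def select_region(
    cube: DataCube,
    time_window: tuple[float, float] | None = None,
    wavelength_window: tuple[float, float] | None = None,
) -> DataCube:
    """Crop the cube to closed windows on the physical axes.

    Used to discard uninformative elution-time and wavelength regions
    before modelling. ``None`` leaves an axis untouched.
    """

    def _mask(axis: np.ndarray, window, name: str) -> np.ndarray:
        if window is None:
            return np.ones(axis.size, dtype=bool)
        lo, hi = float(window[0]), float(window[1])
        if hi < lo:
            raise ValueError(f"{name} window has hi < lo: {window}")
        mask = (axis >= lo) & (axis <= hi)
        if not mask.any():
            raise ValueError(f"{name} window {window} does not intersect the axis")
        return mask

    tmask = _mask(cube.time_axis, time_window, "time")
    wmask = _mask(cube.wavelength_axis, wavelength_window, "wavelength")
    return replace(
        cube,
        values=cube.values[np.ix_(tmask, wmask, np.ones(cube.shape[2], dtype=bool))],
        time_axis=cube.time_axis[tmask],
        wavelength_axis=cube.wavelength_axis[wmask],
    )
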