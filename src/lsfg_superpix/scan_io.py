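"""Reading and writing LSFG composite maps and cohort tables.

A laser speckle flowgraphy (LSFG) device emits, per acquisition, a single
composite image: the per-pixel mean blur rate (MBR) averaged over a short
video recording, in arbitrary units (AU) proportional to relative blood-flow
velocity.  The native vendor format is proprietary, so this package defines
two open dialects:

``csv``
    Headerless matrix of 64-bit floats, one image row per line.  Lossless
    round-trip for finite values.
``tiff``
    Single-channel 32-bit float TIFF (compact, lossy at float32 epsilon).

Undefined pixels (no stable speckle signal) are encoded as NaN in both
dialects and surface as ``valid == False`` on the in-memory scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "LSFGScan",
    "CohortPatient",
    "ScanFormatError",
    "CohortTableError",
    "read_scan",
    "write_scan",
    "read_cohort",
    "write_cohort",
    "COHORT_COLUMNS",
]

logger = logging.getLogger("lsfg_superpix")


class ScanFormatError(ValueError):
    """Raised when a scan file violates the documented dialects."""


class CohortTableError(ValueError):
    """Raised when a cohort metadata table is malformed."""


@dataclass
class LSFGScan:
    """One composite MBR map with its validity mask and provenance.

    Parameters
    ----------
    mbr : ndarray of float
        2-D per-pixel mean blur rate in AU.  Invalid pixels may hold NaN.
    valid : ndarray of bool
        Same shape as ``mbr``; False where the device reported no value.
    patient_id : str
        Identifier of the patient the scan belongs to.
    eye : str
        Laterality, ``"OD"`` (right) or ``"OS"`` (left).
    irradiated : bool
        Whether this is the plaque-treated eye.
    scan_index : int
        Which of the three successive scans this is (1..3).
    """

    mbr: np.ndarray
    valid: np.ndarray
    patient_id: str = "anonymous"
    eye: str = "OD"
    irradiated: bool = False
    scan_index: int = 1

    def __post_init__(self) -> None:
        self.mbr = np.asarray(self.mbr, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.mbr.ndim != 2:
            raise ScanFormatError(f"MBR map must be 2-D, got ndim={self.mbr.ndim}")
        if self.mbr.shape != self.valid.shape:
            raise ScanFormatError(
                f"mbr shape {self.mbr.shape} != valid shape {self.valid.shape}"
            )
        if self.eye not in ("OD", "OS"):
            raise ValueError(f"eye must be 'OD' or 'OS', got {self.eye!r}")
        if self.scan_index not in (1, 2, 3):
            raise ValueError(f"scan_index must be in 1..3, got {self.scan_index}")
        vals = self.mbr[self.valid]
        if vals.size and not np.all(np.isfinite(vals)):
            raise ScanFormatError("valid pixels must hold finite MBR values")
        if vals.size and np.any(vals < 0):
            raise ScanFormatError("MBR is non-negative; found negative valid values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mbr.shape

    def valid_values(self) -> np.ndarray:
        """Finite MBR values at valid pixels, flattened."""
        return self.mbr[self.valid]


def _as_scan_array(data: np.ndarray, path: Path) -> tuple[np.ndarray, np.ndarray]:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ScanFormatError(f"{path}: scan data must be 2-D, got ndim={data.ndim}")
    valid = np.isfinite(data)
    if np.any(data[valid] < 0):
        raise ScanFormatError(f"{path}: negative MBR values are not permitted")
    mbr = data.copy()
    mbr[~valid] = np.nan
    return mbr, valid


def read_scan(path: str | Path, **metadata) -> LSFGScan:
    """Read a composite MBR map from either supported dialect.

    The dialect is inferred from the file suffix (``.csv`` or
    ``.tif``/``.tiff``).  Non-finite stored values become invalid pixels.
    Keyword arguments (``patient_id``, ``eye``, ``irradiated``,
    ``scan_index``) populate the scan's provenance fields.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        try:
            data = np.loadtxt(path, delimiter=",", ndmin=2)
        except Exception as exc:  # pragma: no cover - message wrapping
            raise ScanFormatError(f"{path}: unreadable CSV matrix ({exc})") from exc
    elif suffix in (".tif", ".tiff"):
        try:
            data = tifffile.imread(path)
        except Exception as exc:
            raise ScanFormatError(f"{path}: unreadable TIFF ({exc})") from exc
    else:
        raise ScanFormatError(f"{path}: unknown scan dialect {suffix!r}")
    mbr, valid = _as_scan_array(data, path)
    return LSFGScan(mbr=mbr, valid=valid, **metadata)


def write_scan(scan: LSFGScan, path: str | Path, dialect: str | None = None) -> Path:
    """Write a scan to disk; invalid pixels are encoded as NaN.

    ``dialect`` defaults to the one implied by the path suffix.
    """
    path = Path(path)
    if dialect is None:
        dialect = {"csv": "csv", "tif": "tiff", "tiff": "tiff"}.get(
            path.suffix.lower().lstrip("."), ""
        )
    out = scan.mbr.astype(float).copy()
    out[~scan.valid] = np.nan
    if dialect == "csv":
        np.savetxt(path, out, delimiter=",", fmt="%.17g")
    elif dialect == "tiff":
        tifffile.imwrite(path, out.astype(np.float32))
    else:
        raise ScanFormatError(f"unknown scan dialect {dialect!r}")
    return path


# One row per eye; scans are referenced by path relative to the scan directory.
COHORT_COLUMNS = [
    "patient_id",
    "eye",
    "irradiated",
    "scan_path_1",
    "scan_path_2",
    "scan_path_3",
    "time_from_treatment",
    "sbp",
    "dbp",
    "iop",
    "dose_to_disc",
    "distance_to_disc",
    "disc_cy",
    "disc_cx",
    "disc_r",
]

#: Covariates that may legitimately be missing (treatment-planning records).
_OPTIONAL = ("dose_to_disc", "distance_to_disc")


@dataclass
class CohortPatient:
    """All per-patient inputs: covariates plus 3 scans per eye."""

    patient_id: str
    irradiated_eye: str
    time_from_treatment: float
    sbp: float
    dbp: float
    iop: dict[str, float]
    dose_to_disc: float
    distance_to_disc: float
    scans: dict[str, list[LSFGScan]] = field(default_factory=dict)
    disc_center: tuple[float, float] = (0.0, 0.0)
    disc_radius: float = 0.0

    def eye_scans(self, eye: str) -> list[LSFGScan]:
        return self.scans[eye]


def read_cohort(table_path: str | Path, scan_dir: str | Path) -> list[CohortPatient]:
    """Load a cohort metadata CSV and the scan files it references.

    The table has one row per eye (two per patient) with the columns in
    :data:`COHORT_COLUMNS`.  Validation enforces the paired-eye design:
    every patient contributes exactly two eyes, three scans per eye, and
    exactly one irradiated eye.
    """
    table_path = Path(table_path)
    scan_dir = Path(scan_dir)
    table = pd.read_csv(table_path)
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise CohortTableError(f"{table_path}: missing columns {missing}")

    patients: list[CohortPatient] = []
    for pid, rows in table.groupby("patient_id", sort=False):
        eyes = list(rows["eye"])
        if sorted(eyes) != ["OD", "OS"]:
            raise CohortTableError(f"patient {pid}: needs exactly eyes OD and OS, got {eyes}")
        irr_flags = rows.set_index("eye")["irradiated"].astype(bool)
        if int(irr_flags.sum()) != 1:
            raise CohortTableError(
                f"patient {pid}: exactly one eye must be flagged irradiated"
            )
        irr_eye = irr_flags.idxmax()
        for col in ("time_from_treatment", "sbp", "dbp", "iop"):
            if rows[col].isna().any():
                raise CohortTableError(f"patient {pid}: missing required covariate {col}")
        first = rows.iloc[0]
        scans: dict[str, list[LSFGScan]] = {}
        iop: dict[str, float] = {}
        for _, row in rows.iterrows():
            eye = row["eye"]
            iop[eye] = float(row["iop"])
            eye_scans = []
            for idx in (1, 2, 3):
                rel = row[f"scan_path_{idx}"]
                if not isinstance(rel, str) or not rel:
                    raise CohortTableError(
                        f"patient {pid} eye {eye}: expected 3 scan paths, scan {idx} missing"
                    )
                spath = scan_dir / rel
                if not spath.exists():
                    raise CohortTableError(f"patient {pid}: missing scan file {spath}")
                eye_scans.append(
                    read_scan(
                        spath,
                        patient_id=str(pid),
                        eye=eye,
                        irradiated=bool(row["irradiated"]),
                        scan_index=idx,
                    )
                )
            scans[eye] = eye_scans
        patients.append(
            CohortPatient(
                patient_id=str(pid),
                irradiated_eye=irr_eye,
                time_from_treatment=float(first["time_from_treatment"]),
                sbp=float(first["sbp"]),
                dbp=float(first["dbp"]),
                iop=iop,
                dose_to_disc=float(first["dose_to_disc"]),
                distance_to_disc=float(first["distance_to_disc"]),
                scans=scans,
                disc_center=(float(first["disc_cy"]), float(first["disc_cx"])),
                disc_radius=float(first["disc_r"]),
            )
        )
    logger.info("read_cohort: %d patients, %d scans", len(patients), 6 * len(patients))
    return patients


def write_cohort(
    patients: Iterable[CohortPatient],
    out_dir: str | Path,
    dialect: str = "tiff",
) -> Path:
    """Write scans plus the metadata CSV; returns the table path."""
    out_dir = Path(out_dir)
    scan_dir = out_dir / "scans"
    scan_dir.mkdir(parents=True, exist_ok=True)
    ext = {"tiff": "tif", "csv": "csv"}.get(dialect)
    if ext is None:
        raise ScanFormatError(f"unknown scan dialect {dialect!r}")
    rows = []
    for patient in patients:
        for eye, scans in sorted(patient.scans.items()):
            row = {
                "patient_id": patient.patient_id,
                "eye": eye,
                "irradiated": eye == patient.irradiated_eye,
                "time_from_treatment": patient.time_from_treatment,
                "sbp": patient.sbp,
                "dbp": patient.dbp,
                "iop": patient.iop[eye],
                "dose_to_disc": patient.dose_to_disc,
                "distance_to_disc": patient.distance_to_disc,
                "disc_cy": patient.disc_center[0],
                "disc_cx": patient.disc_center[1],
                "disc_r": patient.disc_radius,
            }
            for scan in scans:
                rel = f"scans/{patient.patient_id}_{eye}_{scan.scan_index}.{ext}"
                write_scan(scan, out_dir / rel, dialect=dialect)
                row[f"scan_path_{scan.scan_index}"] = rel
            rows.append(row)
    table = pd.DataFrame(rows)[COHORT_COLUMNS]
    table_path = out_dir / "cohort.csv"
    table.to_csv(table_path, index=False)
    return table_path
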