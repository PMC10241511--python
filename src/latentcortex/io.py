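"""Surface-fMRI containers, file IO, and minimal preprocessing.

The central container is :class:`CorticalTimeseries`, a vertex-by-time matrix
of BOLD activity on a two-hemisphere cortical mesh together with the subject
metadata the downstream analyses need (age at scan in postmenstrual weeks,
repetition time, per-frame head motion).  Readers and writers are provided for
CIFTI-2 dense timeseries, GIFTI functional files, and an internal HDF5
container used for synthetic cohorts.

Preprocessing here covers only the final, surface-level steps applied before
latent encoding: polynomial detrending, temporal bandpass filtering,
per-vertex standardization, edge trimming, and low-motion volume selection.
Everything upstream (motion correction, registration, surface projection) is
assumed done.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml
from scipy import signal

logger = logging.getLogger("latentcortex")

__all__ = [
    "CorticalTimeseries",
    "FormatError",
    "DimensionError",
    "read_surface_timeseries",
    "write_surface_timeseries",
    "normalize_timeseries",
    "detrend_poly",
    "bandpass_filter",
    "select_low_motion_volumes",
    "trim_edges",
    "make_subject_table",
    "load_config",
]

#: Vertex order convention used everywhere: left-hemisphere block first,
#: then right hemisphere; indices are 0-based.
HEMISPHERE_ORDER = ("L", "R")

_CONTAINER_SCHEMA_VERSION = 1


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class DimensionError(ValueError):
    """Array dimensions are inconsistent with the mesh or with each other."""


@dataclass
class CorticalTimeseries:
    """Vertex x time activity matrix on a two-hemisphere cortical mesh.

    Parameters
    ----------
    values
        ``(V, T)`` array, vertex-major, left hemisphere before right.
    mesh_id
        Identifier of the mesh the vertices live on.
    subject_id, session_id
        Scan identifiers.
    age_weeks
        Postmenstrual age at scan, weeks.
    dataset_tag
        One of ``"dhcp_like"``, ``"dbi_like"``, ``"synthetic"``.
    tr_seconds
        Sampling interval (repetition time), seconds.
    fd_series
        Optional per-frame framewise displacement, mm, length ``T``.
    """

    values: np.ndarray
    mesh_id: str = "unknown"
    subject_id: str = "sub-0"
    session_id: str = "ses-0"
    age_weeks: float = float("nan")
    dataset_tag: str = "synthetic"
    tr_seconds: float = 1.0
    fd_series: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise DimensionError(
                f"values must be 2-D (V, T), got shape {self.values.shape}"
            )
        if self.fd_series is not None:
            self.fd_series = np.asarray(self.fd_series, dtype=np.float64)
            if self.fd_series.shape != (self.n_frames,):
                raise DimensionError(
                    f"fd_series length {self.fd_series.shape} does not match "
                    f"T={self.n_frames}"
                )

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def replace(self, **kwargs) -> "CorticalTimeseries":
        """Return a copy with some fields replaced."""
        return dataclasses.replace(self, **kwargs)

    def metadata(self) -> dict:
        return {
            "mesh_id": self.mesh_id,
            "subject_id": self.subject_id,
            "session_id": self.session_id,
            "age_weeks": float(self.age_weeks),
            "dataset_tag": self.dataset_tag,
            "tr_seconds": float(self.tr_seconds),
        }


def _check_finite_frames(values: np.ndarray) -> None:
    bad = ~np.all(np.isfinite(values), axis=0)
    if bad.any():
        idx = np.flatnonzero(bad).tolist()
        raise FormatError(f"non-finite values in frames {idx}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def write_surface_timeseries(ts: CorticalTimeseries, path, format: str = "internal") -> None:
    """Write a :class:`CorticalTimeseries` to disk.

    ``internal`` is an HDF5 container (values + JSON metadata attribute),
    ``gifti_func`` a GIFTI .func.gii with one data array per frame over all
    vertices (left block then right), ``cifti_dtseries`` a CIFTI-2 dense
    timeseries with left/right cortex brain models.
    """
    path = str(path)
    if format == "internal":
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=ts.values)
            if ts.fd_series is not None:
                f.create_dataset("fd_series", data=ts.fd_series)
            f.attrs["metadata"] = json.dumps(ts.metadata())
            f.attrs["schema_version"] = _CONTAINER_SCHEMA_VERSION
    elif format == "gifti_func":
        import nibabel as nib

        darrays = [
            nib.gifti.GiftiDataArray(
                ts.values[:, t].astype(np.float32), intent="NIFTI_INTENT_TIME_SERIES"
            )
            for t in range(ts.n_frames)
        ]
        img = nib.gifti.GiftiImage(darrays=darrays)
        img.meta["latentcortex_metadata"] = json.dumps(ts.metadata())
        nib.save(img, path)
    elif format == "cifti_dtseries":
        import nibabel as nib

        v_half = ts.n_vertices // 2
        if 2 * v_half != ts.n_vertices:
            raise DimensionError("cifti writer requires equal hemisphere sizes")
        bm = nib.cifti2.BrainModelAxis.from_mask(
            np.ones(v_half, bool), name="CIFTI_STRUCTURE_CORTEX_LEFT"
        ) + nib.cifti2.BrainModelAxis.from_mask(
            np.ones(v_half, bool), name="CIFTI_STRUCTURE_CORTEX_RIGHT"
        )
        series = nib.cifti2.SeriesAxis(start=0.0, step=ts.tr_seconds, size=ts.n_frames)
        img = nib.cifti2.Cifti2Image(
            ts.values.T.astype(np.float32), header=(series, bm)
        )
        nib.save(img, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_surface_timeseries(
    path,
    format: str = "internal",
    mesh=None,
) -> CorticalTimeseries:
    """Read surface fMRI from ``path`` in the declared ``format``.

    Values are returned vertex-major (V, T), left hemisphere before right.
    If ``mesh`` is given, the vertex count is checked against it.

    Raises
    ------
    FormatError
        Malformed file, or non-finite values (the offending frame indices are
        listed in the message).
    DimensionError
        Vertex count inconsistent with the supplied mesh.
    """
    path = str(path)
    if format == "internal":
        try:
            with h5py.File(path, "r") as f:
                values = np.asarray(f["values"])
                fd = np.asarray(f["fd_series"]) if "fd_series" in f else None
                meta = json.loads(f.attrs["metadata"])
        except (OSError, KeyError) as exc:
            raise FormatError(f"not a valid internal container: {path} ({exc})")
        ts = CorticalTimeseries(values=values, fd_series=fd, **meta)
    elif format == "gifti_func":
        import nibabel as nib

        try:
            img = nib.load(path)
            darrays = img.darrays
        except Exception as exc:  # nibabel raises several load error types
            raise FormatError(f"not a valid GIFTI file: {path} ({exc})")
        if not darrays:
            raise FormatError(f"GIFTI file has no data arrays: {path}")
        values = np.stack([np.asarray(d.data, dtype=np.float64) for d in darrays], axis=1)
        meta = {}
        raw = img.meta.get("latentcortex_metadata")
        if raw:
            meta = json.loads(raw)
        ts = CorticalTimeseries(values=values, **meta)
    elif format == "cifti_dtseries":
        import nibabel as nib

        try:
            img = nib.load(path)
            data = np.asarray(img.get_fdata())  # (T, V)
            ax1 = img.header.get_axis(1)
        except Exception as exc:
            raise FormatError(f"not a valid CIFTI-2 file: {path} ({exc})")
        series = img.header.get_axis(0)
        order = {"CIFTI_STRUCTURE_CORTEX_LEFT": 0, "CIFTI_STRUCTURE_CORTEX_RIGHT": 1}
        blocks = sorted(
            (
                (order.get(name, 99), sl)
                for name, sl, _ in ax1.iter_structures()
            ),
        )
        values = np.concatenate([data[:, sl] for _, sl in blocks], axis=1).T
        ts = CorticalTimeseries(values=values, tr_seconds=float(series.step))
    else:
        raise ValueError(f"unknown format {format!r}")

    _check_finite_frames(ts.values)
    if mesh is not None and ts.n_vertices != mesh.n_vertices:
        raise DimensionError(
            f"file has {ts.n_vertices} vertices but mesh "
            f"{mesh.mesh_id!r} has {mesh.n_vertices}"
        )
    return ts


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def normalize_timeseries(ts: CorticalTimeseries) -> CorticalTimeseries:
    """Standardize each vertex series to zero mean, unit population variance.

    Constant series are mapped to all-zero rather than dividing by zero.
    Idempotent: applying twice equals applying once (within roundoff).
    """
    if ts.n_frames < 2:
        raise ValueError(f"need T >= 2 to standardize, got T={ts.n_frames}")
    x = ts.values
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # population convention (divide by T)
    out = np.zeros_like(x)
    ok = sd[:, 0] > 0
    out[ok] = (x[ok] - mean[ok]) / sd[ok]
    return ts.replace(values=out)


def detrend_poly(ts: CorticalTimeseries, order: int = 3) -> CorticalTimeseries:
    """Regress out a polynomial trend of the given order from each vertex.

    Returns the least-squares residual; ``order=0`` is mean removal.
    """
    if order < 0:
        raise ValueError("polynomial order must be >= 0")
    T = ts.n_frames
    if T <= order + 1:
        raise ValueError(f"need T > order+1 = {order + 1}, got T={T}")
    t = np.linspace(-1.0, 1.0, T)
    design = np.polynomial.polynomial.polyvander(t, order)  # (T, order+1)
    coef, *_ = np.linalg.lstsq(design, ts.values.T, rcond=None)
    resid = ts.values - (design @ coef).T
    return ts.replace(values=resid)


def bandpass_filter(
    ts: CorticalTimeseries, low_hz: float = 0.01, high_hz: float = 0.1
) -> CorticalTimeseries:
    """Zero-phase Butterworth (order 4) bandpass along the time axis."""
    nyquist = 0.5 / ts.tr_seconds
    if not (0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz invalid for Nyquist {nyquist:.4g} Hz"
        )
    sos = signal.butter(
        4, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr_seconds, output="sos"
    )
    out = signal.sosfiltfilt(sos, ts.values, axis=1)
    return ts.replace(values=out)


def select_low_motion_volumes(fd_series: Sequence[float], n_keep: int = 1400) -> np.ndarray:
    """Indices of the ``n_keep`` frames with the least framewise displacement.

    Returned in ascending temporal order; ties broken in favour of the
    earlier frame.  The default 1400 frames corresponds to roughly ten
    minutes at the multiband acquisition rate of the larger cohort.
    """
    fd = np.asarray(fd_series, dtype=np.float64)
    if n_keep > fd.size:
        raise ValueError(f"n_keep={n_keep} exceeds available frames {fd.size}")
    order = np.argsort(fd, kind="stable")[:n_keep]
    return np.sort(order)


def trim_edges(ts: CorticalTimeseries, n_trim: int = 150) -> CorticalTimeseries:
    """Drop the first and last ``n_trim`` frames (filter edge effects)."""
    if n_trim < 0:
        raise ValueError("n_trim must be >= 0")
    if n_trim == 0:
        return ts.replace()
    if ts.n_frames <= 2 * n_trim:
        raise ValueError(
            f"cannot trim {n_trim} frames from each end of T={ts.n_frames}"
        )
    values = ts.values[:, n_trim:-n_trim]
    fd = ts.fd_series[n_trim:-n_trim] if ts.fd_series is not None else None
    return ts.replace(values=values, fd_series=fd)


# ---------------------------------------------------------------------------
# metadata table / config
# ---------------------------------------------------------------------------


def make_subject_table(records: Sequence[dict]) -> pd.DataFrame:
    """Validated per-scan metadata table keyed by (subject_id, session_id).

    Required columns: subject_id, session_id, age_weeks, dataset_tag.
    Optional: brain_volume_cc, mean_fd.  Ages must be strictly positive and
    keys unique.
    """
    df = pd.DataFrame(list(records))
    required = ["subject_id", "session_id", "age_weeks", "dataset_tag"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"subject table missing columns {missing}")
    if (df["age_weeks"] <= 0).any():
        raise ValueError("ages must be strictly positive")
    dup = df.duplicated(subset=["subject_id", "session_id"])
    if dup.any():
        raise ValueError(
            f"duplicate (subject_id, session_id) keys: "
            f"{df.loc[dup, ['subject_id', 'session_id']].values.tolist()}"
        )
    return df.set_index(["subject_id", "session_id"], drop=False)


def load_config(path) -> dict:
    """Load a YAML analysis configuration."""
    with open(path) as f:
        cfg = yaml.safe_load(f)
    logger.info("loaded config %s: %s", path, cfg)
    return cfg
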