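"""Movies, localization tables, and patch sets: containers and file formats.

Coordinate convention (used by every module in this package): coordinates are
0-based and sub-pixel, with integer coordinate *i* at the centre of pixel *i*.
Any 0.5-offset dialect must be converted at the I/O boundary; nothing inside
the package ever carries a half-pixel shift.

Movies are multi-page TIFF stacks of integer camera counts with a YAML sidecar
(``<stem>.yaml``) holding the integration time and camera model. Localization
tables use the Picasso "locs" HDF5 dialect: a single structured dataset named
``locs`` with at least the fields ``frame, x, y, photons, sx, sy, bg, lpx,
lpy`` plus a YAML sidecar; unknown extra fields are passed through untouched.
Patch sets are exported as a patch TIFF stack plus a CSV of patch-local
coordinates (columns ``patch_index, x, y``), the layout the ZeroCost-style
training notebooks consume.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("paintdense")

#: Fallback acquisition metadata used when a movie has no YAML sidecar.
DEFAULT_INTEGRATION_TIME = 0.15  # seconds per frame
DEFAULT_PIXEL_SIZE = 107.0  # nm per camera pixel (150x objective, 16 µm EMCCD pixel)

LOCS_REQUIRED_FIELDS = ("frame", "x", "y", "photons", "sx", "sy", "bg", "lpx", "lpy")


class FormatError(ValueError):
    """A file exists but violates the expected on-disk format."""


class SchemaError(FormatError):
    """A localization file is missing a required field."""


# ---------------------------------------------------------------------------
# Camera and movie
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CameraModel:
    """EMCCD camera description.

    Parameters
    ----------
    offset : float
        Constant count baseline (ADU) added by the detector. Summing n raw
        frames accumulates it n times, hence the (n-1)-fold subtraction in
        the training-patch synthesis.
    gain : float
        Counts per detected photoelectron.
    read_noise : float
        RMS readout noise in counts.
    pixel_size : float
        Camera pixel size in nm; the µm² denominator of all emitter densities.
    qe : float
        Quantum efficiency in (0, 1].
    """

    offset: float = 100.0
    gain: float = 1.0
    read_noise: float = 1.0
    pixel_size: float = DEFAULT_PIXEL_SIZE
    qe: float = 1.0

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError(f"camera offset must be >= 0, got {self.offset}")
        if self.gain <= 0:
            raise ValueError(f"camera gain must be > 0, got {self.gain}")
        if self.read_noise < 0:
            raise ValueError(f"read noise must be >= 0, got {self.read_noise}")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel size must be > 0, got {self.pixel_size}")
        if not 0.0 < self.qe <= 1.0:
            raise ValueError(f"quantum efficiency must be in (0, 1], got {self.qe}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class Movie:
    """A stack of camera frames in counts.

    ``frames`` has shape (n_frames, H, W) and nonnegative values;
    ``integration_time`` is seconds per frame.
    """

    frames: np.ndarray
    integration_time: float = DEFAULT_INTEGRATION_TIME
    camera: CameraModel = field(default_factory=CameraModel)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise FormatError(
                f"movie frames must be a (n, H, W) stack, got shape {self.frames.shape}"
            )
        if self.integration_time <= 0:
            raise ValueError("integration_time must be > 0")
        if self.frames.size and self.frames.min() < 0:
            raise ValueError("movie counts must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


# ---------------------------------------------------------------------------
# Localization table
# ---------------------------------------------------------------------------


class LocalizationTable:
    """Per-emitter records, the lingua franca between all stages.

    Wraps a :class:`pandas.DataFrame` with the required columns
    ``frame, x, y, photons, sx, sy, bg, lpx, lpy`` (extra columns are kept).
    ``frame`` is the 0-based frame index; ``x``/``y`` are sub-pixel camera
    pixel coordinates (0-based pixel-centre convention); ``sx``/``sy`` are PSF
    sigmas and ``lpx``/``lpy`` localization precisions, all in pixels. Records
    are kept sorted by frame (stable sort, so within-frame order survives).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in LOCS_REQUIRED_FIELDS if c not in df.columns]
        if missing:
            raise SchemaError(f"localization table missing required field(s): {missing}")
        if len(df) and (df["frame"] < 0).any():
            raise ValueError("frame indices must be >= 0")
        if len(df) and (df["photons"] <= 0).any():
            raise ValueError("photons must be > 0")
        if not df["frame"].is_monotonic_increasing:
            df = df.sort_values("frame", kind="stable")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_arrays(cls, frame, x, y, photons, sx=None, sy=None, bg=None, lpx=None, lpy=None, **extra):
        n = len(np.atleast_1d(x))

        def col(v, default):
            return np.full(n, default, dtype=float) if v is None else np.asarray(v)

        df = pd.DataFrame(
            {
                "frame": np.asarray(frame, dtype=np.int64),
                "x": np.asarray(x, dtype=float),
                "y": np.asarray(y, dtype=float),
                "photons": np.asarray(photons, dtype=float),
                "sx": col(sx, 1.0),
                "sy": col(sy, 1.0),
                "bg": col(bg, 0.0),
                "lpx": col(lpx, 0.1),
                "lpy": col(lpy, 0.1),
            }
        )
        for k, v in extra.items():
            df[k] = v
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    def __getitem__(self, col: str) -> np.ndarray:
        return self.df[col].to_numpy()

    def in_frame(self, frame: int) -> pd.DataFrame:
        return self.df[self.df["frame"] == frame]

    @property
    def n_frames_spanned(self) -> int:
        if not len(self.df):
            return 0
        return int(self.df["frame"].max()) + 1


# ---------------------------------------------------------------------------
# Patch sets
# ---------------------------------------------------------------------------


@dataclass
class PatchSet:
    """Image patches with paired per-patch emitter coordinate lists.

    ``patches`` has shape (n, P, P) in camera counts; ``coords[i]`` is an
    (k_i, 2) float array of (x, y) patch-local pixel coordinates in [0, P).
    ``provenance`` records whether patches are raw sparse crops, synthetic
    sums, or direct simulator output.
    """

    patches: np.ndarray
    coords: list
    provenance: str = "sparse"
    camera: CameraModel = field(default_factory=CameraModel)

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches)
        if self.patches.ndim != 3 or self.patches.shape[1] != self.patches.shape[2]:
            raise ValueError(f"patches must be (n, P, P), got {self.patches.shape}")
        if len(self.coords) != len(self.patches):
            raise ValueError(
                f"coords list length {len(self.coords)} != number of patches {len(self.patches)}"
            )
        P = self.patch_size
        clean = []
        for i, c in enumerate(self.coords):
            c = np.asarray(c, dtype=float).reshape(-1, 2)
            if c.size and (c.min() < 0 or c.max() >= P):
                raise ValueError(f"patch {i}: coordinate outside [0, {P})")
            clean.append(c)
        self.coords = clean

    @property
    def patch_size(self) -> int:
        return int(self.patches.shape[1])

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def n_emitters(self) -> int:
        return int(sum(len(c) for c in self.coords))

    @property
    def mean_emitters_per_patch(self) -> float:
        return self.n_emitters / len(self) if len(self) else 0.0

    def density_per_um2(self) -> float:
        """Mean emitters per µm² of patch area."""
        area = (self.patch_size * self.camera.pixel_size / 1000.0) ** 2
        return self.mean_emitters_per_patch / area


# ---------------------------------------------------------------------------
# Movie I/O
# ---------------------------------------------------------------------------


def _sidecar(path: Path) -> Path:
    return Path(path).with_suffix(".yaml")


def write_movie(movie: Movie, path) -> None:
    """Write a movie as multi-page TIFF plus YAML sidecar metadata."""
    if movie.n_frames == 0:
        raise ValueError("refusing to write an empty movie (0 frames)")
    path = Path(path)
    frames = movie.frames
    if not np.issubdtype(frames.dtype, np.integer):
        rounded = np.rint(frames)
        if not np.allclose(frames, rounded):
            raise FormatError("movie counts must be integral to be written as TIFF")
        frames = rounded
    frames = frames.astype(np.uint16 if frames.max() < 2**16 else np.uint32)
    tifffile.imwrite(path, frames, photometric="minisblack")
    meta = {
        "integration_time": float(movie.integration_time),
        "camera": movie.camera.to_dict(),
        "n_frames": int(movie.n_frames),
        "shape": [int(s) for s in movie.frame_shape],
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_movie(path, default_camera: CameraModel | None = None) -> Movie:
    """Read a multi-page TIFF movie; sidecar YAML supplies metadata if present."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) > 1:
            raise FormatError(f"mixed frame shapes in {path.name}: {sorted(shapes)}")
        frames = tif.asarray()
    if frames.ndim == 2:
        frames = frames[None]
    if not np.issubdtype(frames.dtype, np.integer):
        raise FormatError(
            f"movie {path.name} has non-integer sample format {frames.dtype}"
        )
    integration_time = DEFAULT_INTEGRATION_TIME
    camera = default_camera or CameraModel()
    sc = _sidecar(path)
    if sc.exists():
        meta = yaml.safe_load(sc.read_text()) or {}
        integration_time = float(meta.get("integration_time", integration_time))
        if "camera" in meta:
            camera = CameraModel.from_dict(meta["camera"])
    else:
        logger.warning(
            "%s has no YAML sidecar; falling back to defaults "
            "(integration_time=%.3f s, pixel_size=%.1f nm)",
            path.name,
            integration_time,
            camera.pixel_size,
        )
    return Movie(frames=frames, integration_time=integration_time, camera=camera)


# ---------------------------------------------------------------------------
# Localization table I/O (Picasso "locs" dialect)
# ---------------------------------------------------------------------------


def write_locs(table: LocalizationTable, path, pixel_size: float | None = None,
               shape: tuple[int, int] | None = None) -> None:
    """Write a localization table as Picasso-dialect HDF5 plus YAML sidecar."""
    path = Path(path)
    df = table.df
    dtype = np.dtype([(c, df[c].to_numpy().dtype) for c in df.columns])
    rec = np.empty(len(df), dtype=dtype)
    for c in df.columns:
        rec[c] = df[c].to_numpy()
    with h5py.File(path, "w") as f:
        f.create_dataset("locs", data=rec)
    meta = {
        "Generated by": "paintdense",
        "Pixelsize": float(pixel_size) if pixel_size is not None else None,
        "Height": int(shape[0]) if shape else None,
        "Width": int(shape[1]) if shape else None,
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_locs(path) -> LocalizationTable:
    """Read a Picasso-dialect HDF5 localization table.

    Tolerates extra fields (kept as extra columns); raises :class:`SchemaError`
    naming the field if a required one is absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        if "locs" not in f:
            raise SchemaError(f"{path.name}: no 'locs' dataset")
        rec = f["locs"][()]
    names = rec.dtype.names or ()
    for req in LOCS_REQUIRED_FIELDS:
        if req not in names:
            raise SchemaError(f"{path.name}: missing required field '{req}'")
    df = pd.DataFrame({name: rec[name] for name in names})
    return LocalizationTable(df)


# ---------------------------------------------------------------------------
# Patch set I/O (TIFF stack + coordinate CSV)
# ---------------------------------------------------------------------------


def export_patchset(ps: PatchSet, path) -> None:
    """Export patches as a TIFF stack + CSV coordinate table + YAML sidecar.

    The CSV has columns ``patch_index, x, y`` with patch-local pixel
    coordinates, the layout ZeroCost-style training notebooks ingest.
    """
    path = Path(path)
    frames = np.rint(ps.patches)
    frames = np.clip(frames, 0, None).astype(
        np.uint16 if frames.max(initial=0) < 2**16 else np.uint32
    )
    tifffile.imwrite(path, frames, photometric="minisblack")
    rows = []
    for i, c in enumerate(ps.coords):
        for x, y in c:
            rows.append((i, x, y))
    df = pd.DataFrame(rows, columns=["patch_index", "x", "y"])
    df.to_csv(path.with_suffix(".csv"), index=False)
    meta = {
        "patch_size": ps.patch_size,
        "n_patches": len(ps),
        "provenance": ps.provenance,
        "camera": ps.camera.to_dict(),
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def import_patchset(path) -> PatchSet:
    """Inverse of :func:`export_patchset`."""
    path = Path(path)
    patches = tifffile.imread(path)
    if patches.ndim == 2:
        patches = patches[None]
    df = pd.read_csv(path.with_suffix(".csv"))
    coords = [np.empty((0, 2)) for _ in range(len(patches))]
    for idx, grp in df.groupby("patch_index"):
        idx = int(idx)
        if idx >= len(patches):
            raise ValueError(f"coordinate CSV references patch {idx} beyond stack")
        coords[idx] = grp[["x", "y"]].to_numpy(dtype=float)
    provenance, camera = "sparse", CameraModel()
    sc = _sidecar(path)
    if sc.exists():
        meta = yaml.safe_load(sc.read_text()) or {}
        provenance = meta.get("provenance", provenance)
        if "camera" in meta:
            camera = CameraModel.from_dict(meta["camera"])
    return PatchSet(patches=patches, coords=coords, provenance=provenance, camera=camera)
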