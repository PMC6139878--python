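"""Line-profile containers, image extraction, and HDF5/JSON persistence.

A :class:`LineProfile` is a 1-D intensity cross-section with a physical
position axis in nm; a :class:`ProfileEnsemble` groups profiles that will be
fit together (sharing one PSF).  Ensembles round-trip losslessly through HDF5
(append-friendly table layout) and JSON (single diffable document), so
profiles extracted from multiple images can be pooled for ensemble fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy import ndimage

__all__ = [
    "LineProfile",
    "ProfileEnsemble",
    "extract_line_profile",
    "save_ensemble",
    "load_ensemble",
    "UnknownFormatError",
    "MalformedFileError",
    "SchemaVersionError",
]

SCHEMA_VERSION = "nepfit-1"
MIN_PROFILE_SAMPLES = 16


class UnknownFormatError(ValueError):
    """File format is not one of {hdf5, json}."""


class MalformedFileError(ValueError):
    """File does not contain a well-formed profile ensemble."""


class SchemaVersionError(MalformedFileError):
    """File schema version does not match this package's schema."""


@dataclass
class LineProfile:
    """Sampled intensity cross-section perpendicular to a tubule.

    ``positions`` (nm) are uniform, increasing and centered near 0;
    ``intensities`` are detector counts (ADU).  ``ground_truth`` carries the
    generating parameters for simulated profiles (diameter, psf_fwhm, ...).
    """

    positions: np.ndarray
    intensities: np.ndarray
    pixel_size: float
    source: str = ""
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.shape != self.intensities.shape:
            raise ValueError("positions and intensities must have equal length")
        if self.positions.size < MIN_PROFILE_SAMPLES:
            raise ValueError(
                f"profile needs >= {MIN_PROFILE_SAMPLES} samples, "
                f"got {self.positions.size}"
            )
        steps = np.diff(self.positions)
        if not np.allclose(steps, self.pixel_size, rtol=1e-6, atol=0.0):
            raise ValueError("positions must be uniform with spacing pixel_size")

    def __len__(self) -> int:
        return self.positions.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, LineProfile):
            return NotImplemented
        return (
            np.array_equal(self.positions, other.positions)
            and np.array_equal(self.intensities, other.intensities)
            and self.pixel_size == other.pixel_size
            and self.source == other.source
            and self.ground_truth == other.ground_truth
        )


@dataclass
class ProfileEnsemble:
    """A set of line profiles fit together with one shared PSF width."""

    profiles: list[LineProfile]
    geometry_kind: str = "annulus_fixed_inner"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError("ensemble must contain at least one profile")
        px = self.profiles[0].pixel_size
        for p in self.profiles:
            if abs(p.pixel_size - px) > 1e-6 * px:
                raise ValueError("all profiles must share the same pixel_size")

    @property
    def pixel_size(self) -> float:
        return self.profiles[0].pixel_size

    def __len__(self) -> int:
        return len(self.profiles)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ProfileEnsemble):
            return NotImplemented
        return (
            self.profiles == other.profiles
            and self.geometry_kind == other.geometry_kind
            and self.metadata == other.metadata
        )


def extract_line_profile(
    image: np.ndarray,
    start: tuple[float, float],
    end: tuple[float, float],
    width: int = 1,
    pixel_size: float = 1.0,
) -> LineProfile:
    """Extract an averaged line profile from a 2-D image.

    Intensity is sampled by bilinear interpolation at 1-pixel steps along the
    segment from ``start`` to ``end`` (pixel (x, y) coordinates, 0-based,
    pixel centers at integers).  ``width`` parallel lines, spaced one pixel
    apart perpendicular to the segment and centered on it, are averaged to
    boost SNR — this also averages out sparse-labelling gaps along the tubule.
    The position axis is in nm with its origin at the segment midpoint.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if width < 1:
        raise ValueError("width must be >= 1 pixel")
    x0, y0 = float(start[0]), float(start[1])
    x1, y1 = float(end[0]), float(end[1])
    ny, nx = image.shape
    for name, (xp, yp) in (("start", (x0, y0)), ("end", (x1, y1))):
        if not (0 <= xp <= nx - 1 and 0 <= yp <= ny - 1):
            raise ValueError(f"{name} point {xp, yp} lies outside the image")
    length = float(np.hypot(x1 - x0, y1 - y0))
    n_samples = int(np.floor(length)) + 1
    if n_samples < MIN_PROFILE_SAMPLES:
        raise ValueError(
            f"segment yields {n_samples} samples; need >= {MIN_PROFILE_SAMPLES}"
        )
    ux, uy = (x1 - x0) / length, (y1 - y0) / length
    px, py = -uy, ux  # unit perpendicular
    s = np.arange(n_samples, dtype=float)
    offsets = np.arange(width, dtype=float) - (width - 1) / 2.0
    xs = x0 + ux * s[None, :] + px * offsets[:, None]
    ys = y0 + uy * s[None, :] + py * offsets[:, None]
    if xs.min() < 0 or xs.max() > nx - 1 or ys.min() < 0 or ys.max() > ny - 1:
        bad = "start" if min(xs[:, 0].min(), ys[:, 0].min()) < 0 or max(
            xs[:, 0].max() - (nx - 1), ys[:, 0].max() - (ny - 1)
        ) > 0 else "end"
        raise ValueError(
            f"averaging band of width {width} px exits the image near the "
            f"{bad} endpoint"
        )
    # map_coordinates indexes (row, col) = (y, x); order=1 is bilinear
    sampled = ndimage.map_coordinates(
        image, [ys.ravel(), xs.ravel()], order=1, mode="nearest"
    ).reshape(width, n_samples)
    intensities = sampled.mean(axis=0)
    positions = (s - (n_samples - 1) / 2.0) * pixel_size
    source = (
        f"segment ({x0:g},{y0:g})->({x1:g},{y1:g}) width={width}px "
        f"pixel_size={pixel_size:g}nm"
    )
    return LineProfile(positions, intensities, pixel_size, source=source)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def _profile_meta(p: LineProfile) -> str:
    return json.dumps({"source": p.source, "ground_truth": p.ground_truth})


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("hdf5", "json"):
            raise UnknownFormatError(f"unknown format {fmt!r}; use 'hdf5' or 'json'")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    if suffix == ".json":
        return "json"
    raise UnknownFormatError(
        f"cannot infer format from suffix {suffix!r}; pass format='hdf5'|'json'"
    )


def save_ensemble(
    ensemble: ProfileEnsemble,
    path: str | Path,
    format: str | None = None,
    append: bool = False,
) -> None:
    """Write an ensemble to HDF5 or JSON; ``append=True`` adds profiles.

    The HDF5 layout is one table of profiles (fixed-length numeric rows for
    positions and intensities, resizable along the profile axis) plus
    JSON-string metadata attributes and a schema-version attribute; appended
    profiles must match the existing pixel size and sample count.  The JSON
    mirror is a single document with the same keys.  Round-trips are lossless
    (bit-identical floats).
    """
    fmt = _infer_format(path, format)
    n_pix = {len(p) for p in ensemble.profiles}
    if fmt == "hdf5" and len(n_pix) != 1:
        raise ValueError("HDF5 table layout requires equal-length profiles")
    if fmt == "hdf5":
        _save_hdf5(ensemble, Path(path), append)
    else:
        _save_json(ensemble, Path(path), append)


def _save_hdf5(ensemble: ProfileEnsemble, path: Path, append: bool) -> None:
    pos = np.stack([p.positions for p in ensemble.profiles])
    inten = np.stack([p.intensities for p in ensemble.profiles])
    meta = np.array(
        [_profile_meta(p) for p in ensemble.profiles], dtype=h5py.string_dtype()
    )
    if append and path.exists():
        with h5py.File(path, "a") as f:
            _check_hdf5_schema(f)
            if f.attrs["geometry_kind"] != ensemble.geometry_kind:
                raise ValueError("appending with mismatched geometry_kind")
            if f["positions"].shape[1] != pos.shape[1]:
                raise ValueError("appending profiles of different length")
            if abs(f.attrs["pixel_size"] - ensemble.pixel_size) > 1e-6:
                raise ValueError("appending profiles with different pixel_size")
            for name, arr in (("positions", pos), ("intensities", inten),
                              ("profile_meta", meta)):
                ds = f[name]
                n0 = ds.shape[0]
                ds.resize(n0 + arr.shape[0], axis=0)
                ds[n0:] = arr
        return
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA_VERSION
        f.attrs["geometry_kind"] = str(ensemble.geometry_kind)
        f.attrs["pixel_size"] = ensemble.pixel_size
        f.attrs["metadata"] = json.dumps(ensemble.metadata)
        f.create_dataset("positions", data=pos, maxshape=(None, pos.shape[1]))
        f.create_dataset("intensities", data=inten,
                         maxshape=(None, inten.shape[1]))
        f.create_dataset("profile_meta", data=meta, maxshape=(None,))


def _save_json(ensemble: ProfileEnsemble, path: Path, append: bool) -> None:
    if append and path.exists():
        existing = load_ensemble(path, format="json")
        if existing.geometry_kind != ensemble.geometry_kind:
            raise ValueError("appending with mismatched geometry_kind")
        profiles = existing.profiles + ensemble.profiles
        metadata = existing.metadata
        ensemble = ProfileEnsemble(profiles, ensemble.geometry_kind, metadata)
    doc = {
        "schema": SCHEMA_VERSION,
        "geometry_kind": str(ensemble.geometry_kind),
        "pixel_size": ensemble.pixel_size,
        "metadata": ensemble.metadata,
        "profiles": [
            {
                "positions": p.positions.tolist(),
                "intensities": p.intensities.tolist(),
                "pixel_size": p.pixel_size,
                "source": p.source,
                "ground_truth": p.ground_truth,
            }
            for p in ensemble.profiles
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def _check_hdf5_schema(f: h5py.File) -> None:
    if "schema" not in f.attrs:
        raise MalformedFileError("file has no schema attribute")
    if f.attrs["schema"] != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"schema {f.attrs['schema']!r} != expected {SCHEMA_VERSION!r}"
        )
    for name in ("positions", "intensities", "profile_meta"):
        if name not in f:
            raise MalformedFileError(f"missing dataset {name!r}")


def load_ensemble(path: str | Path, format: str | None = None) -> ProfileEnsemble:
    """Load a profile ensemble saved by :func:`save_ensemble`."""
    fmt = _infer_format(path, format)
    path = Path(path)
    if fmt == "hdf5":
        try:
            f = h5py.File(path, "r")
        except OSError as exc:
            raise MalformedFileError(f"not a readable HDF5 file: {exc}") from exc
        with f:
            _check_hdf5_schema(f)
            pos = np.asarray(f["positions"])
            inten = np.asarray(f["intensities"])
            meta = [json.loads(m) for m in f["profile_meta"].asstr()]
            if not (pos.shape == inten.shape and pos.shape[0] == len(meta)):
                raise MalformedFileError("inconsistent table lengths")
            px = float(f.attrs["pixel_size"])
            profiles = [
                LineProfile(pos[i], inten[i], px, source=meta[i]["source"],
                            ground_truth=meta[i]["ground_truth"])
                for i in range(pos.shape[0])
            ]
            return ProfileEnsemble(
                profiles,
                geometry_kind=str(f.attrs["geometry_kind"]),
                metadata=json.loads(f.attrs["metadata"]),
            )
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise MalformedFileError(f"not a well-formed JSON document: {exc}") from exc
    if not isinstance(doc, dict) or "schema" not in doc:
        raise MalformedFileError("JSON document has no schema key")
    if doc["schema"] != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"schema {doc['schema']!r} != expected {SCHEMA_VERSION!r}"
        )
    try:
        profiles = [
            LineProfile(
                np.asarray(d["positions"], dtype=float),
                np.asarray(d["intensities"], dtype=float),
                float(d["pixel_size"]),
                source=d.get("source", ""),
                ground_truth=d.get("ground_truth"),
            )
            for d in doc["profiles"]
        ]
        return ProfileEnsemble(
            profiles,
            geometry_kind=doc["geometry_kind"],
            metadata=doc.get("metadata", {}),
        )
    except (KeyError, TypeError) as exc:
        raise MalformedFileError(f"missing or invalid field: {exc}") from exc
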