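"""Raster and sample-table I/O with fixed coordinate conventions.

All public coordinates are 0-based ``(row, col)``, row 0 at the top,
half-open bounds. Cubes are stored in memory as ``(H, W, B)`` float arrays;
integer digital numbers are rescaled to reflectance-like ``[0, 1]`` at load
time by dividing by the dtype maximum, because the edge-preserving filter
range parameters (sigma_r, epsilon) are only meaningful on normalized
intensities.

Supported on-disk formats: multi-band TIFF (via :mod:`tifffile`), ENVI
``.hdr`` + flat binary, and NumPy ``.npz`` containers for cubes and
probability stacks; TIFF/PNG for label maps and guidance images (legend and
nodata ride in a JSON sidecar); CSV for sample tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "HyperspectralCube",
    "GuidanceImage",
    "LabelMap",
    "SampleSet",
    "RasterIOError",
    "RasterFormatError",
    "DimensionMismatchError",
    "SampleError",
    "read_cube",
    "write_cube",
    "read_label_map",
    "write_label_map",
    "read_guidance",
    "write_guidance",
    "load_samples",
    "save_samples",
]


class RasterIOError(Exception):
    """Base class for raster/sample I/O failures."""


class RasterFormatError(RasterIOError):
    """File exists but its format or header is invalid."""


class DimensionMismatchError(RasterFormatError):
    """Header-declared dimensions disagree with the payload."""


class SampleError(RasterIOError):
    """Sample table violates its contract (bounds, duplicates, classes)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class HyperspectralCube:
    """An ``(H, W, B)`` reflectance raster with optional band wavelengths."""

    values: np.ndarray
    wavelengths_nm: np.ndarray | None = None
    pixel_size_m: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"cube must be 3-D (H, W, B), got shape {self.values.shape}")
        h, w, b = self.values.shape
        if h < 1 or w < 1 or b < 1:
            raise ValueError("cube dimensions must all be >= 1")
        if self.wavelengths_nm is not None:
            wl = np.asarray(self.wavelengths_nm, dtype=float)
            if wl.shape != (b,):
                raise ValueError(f"wavelengths length {wl.shape} != band count {b}")
            if not np.all(np.diff(wl) > 0):
                raise ValueError("wavelengths must be strictly increasing")
            self.wavelengths_nm = wl
        mask = ~np.isfinite(self.values)
        if mask.any():
            # NaN/Inf pixels are masked out by zero-filling; the mask is kept
            self.mask = mask
            self.values = np.where(mask, 0.0, self.values)
        else:
            self.mask = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]


@dataclass
class GuidanceImage:
    """Single- or 3-channel image in [0, 1] supplying edge structure."""

    values: np.ndarray
    provenance: str = "synthetic"  # rgb_resampled | pca_false_color | synthetic

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise ValueError("guidance must be H×W or H×W×C")
        if self.values.ndim == 3 and self.values.shape[2] != 3:
            raise ValueError("multi-channel guidance must have exactly 3 channels")
        lo, hi = float(self.values.min()), float(self.values.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"guidance values outside [0, 1]: range [{lo}, {hi}]")
        self.values = np.clip(self.values, 0.0, 1.0)

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.values.shape[:2]  # type: ignore[return-value]

    def luminance(self) -> np.ndarray:
        """Rec.601 luma; identity for single-channel guidance."""
        if self.values.ndim == 2:
            return self.values
        r, g, b = self.values[..., 0], self.values[..., 1], self.values[..., 2]
        return 0.299 * r + 0.587 * g + 0.114 * b


@dataclass
class LabelMap:
    """H×W categorical raster over an ordered class legend."""

    values: np.ndarray
    legend: Sequence[str]
    nodata: int = -1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("label map must be 2-D")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("label map must hold integers")
        self.legend = list(self.legend)
        if len(self.legend) < 2:
            raise ValueError("legend needs at least 2 classes")
        valid = self.values[self.values != self.nodata]
        if valid.size and (valid.min() < 0 or valid.max() >= len(self.legend)):
            raise ValueError("label values outside legend range")

    @property
    def n_classes(self) -> int:
        return len(self.legend)

    def class_id(self, name: str) -> int:
        try:
            return self.legend.index(name)
        except ValueError:
            raise KeyError(f"class {name!r} not in legend {self.legend}") from None


TRAINING = "training"
VERIFICATION = "verification"


@dataclass
class SampleSet:
    """Pixel samples ``(row, col, class_id)`` flagged training/verification."""

    rows: np.ndarray
    cols: np.ndarray
    class_ids: np.ndarray
    roles: np.ndarray  # strings, TRAINING or VERIFICATION
    raster_shape: tuple[int, int]
    legend: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        self.class_ids = np.asarray(self.class_ids, dtype=int)
        self.roles = np.asarray(self.roles, dtype=object)
        n = len(self.rows)
        if not (len(self.cols) == len(self.class_ids) == len(self.roles) == n):
            raise SampleError("sample columns have unequal lengths")
        h, w = self.raster_shape
        oob = (self.rows < 0) | (self.rows >= h) | (self.cols < 0) | (self.cols >= w)
        if oob.any():
            i = int(np.flatnonzero(oob)[0])
            raise SampleError(
                f"sample ({self.rows[i]}, {self.cols[i]}) outside raster {h}×{w}"
            )
        flat = self.rows * w + self.cols
        if len(np.unique(flat)) != n:
            raise SampleError("duplicate (row, col) sample coordinates")
        bad = ~np.isin(self.roles, [TRAINING, VERIFICATION])
        if bad.any():
            raise SampleError(f"unknown role {self.roles[bad][0]!r}")

    def __len__(self) -> int:
        return len(self.rows)

    def subset(self, role: str) -> "SampleSet":
        m = self.roles == role
        return SampleSet(
            self.rows[m], self.cols[m], self.class_ids[m], self.roles[m],
            self.raster_shape, self.legend,
        )

    @property
    def training(self) -> "SampleSet":
        return self.subset(TRAINING)

    @property
    def verification(self) -> "SampleSet":
        return self.subset(VERIFICATION)

    def features(self, cube: HyperspectralCube) -> np.ndarray:
        return cube.values[self.rows, self.cols, :]


# ---------------------------------------------------------------------------
# cube I/O
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {1: "u1", 2: "i2", 3: "i4", 4: "f4", 5: "f8", 12: "u2", 13: "u4"}


def _normalize_dn(values: np.ndarray) -> np.ndarray:
    """Integer digital numbers -> [0, 1] by the dtype-declared maximum."""
    if np.issubdtype(values.dtype, np.integer):
        return values.astype(float) / float(np.iinfo(values.dtype).max)
    return values.astype(float)


def _read_envi_header(hdr_path: Path) -> dict:
    text = hdr_path.read_text()
    if not text.lstrip().lower().startswith("envi"):
        raise RasterFormatError(f"{hdr_path}: missing ENVI magic")
    fields: dict[str, str] = {}
    # join brace-wrapped multi-line values before splitting on '='
    body = text.split("\n", 1)[1] if "\n" in text else ""
    buf = ""
    for line in body.splitlines():
        buf += line + " "
        if buf.count("{") == buf.count("}"):
            if "=" in buf:
                key, val = buf.split("=", 1)
                fields[key.strip().lower()] = val.strip().strip("{}").strip()
            buf = ""
    return fields


def _read_envi_cube(hdr_path: Path) -> HyperspectralCube:
    fields = _read_envi_header(hdr_path)
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
    except KeyError as exc:
        raise RasterFormatError(f"{hdr_path}: missing ENVI field {exc}") from None
    if bands < 1:
        raise RasterFormatError(f"{hdr_path}: band count {bands} < 1")
    if dtype_code not in _ENVI_DTYPES:
        raise RasterFormatError(f"{hdr_path}: unsupported ENVI data type {dtype_code}")
    interleave = fields.get("interleave", "bsq").lower()
    byteorder = ">" if fields.get("byte order", "0").strip() == "1" else "<"
    dtype = np.dtype(byteorder + _ENVI_DTYPES[dtype_code])

    dat_path = None
    for ext in (".dat", ".img", ".bin", ""):
        cand = hdr_path.with_suffix(ext)
        if cand.exists() and cand != hdr_path:
            dat_path = cand
            break
    if dat_path is None:
        raise FileNotFoundError(f"no binary payload next to {hdr_path}")
    raw = np.fromfile(dat_path, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise DimensionMismatchError(
            f"{dat_path}: header declares {expected} values "
            f"({lines}×{samples}×{bands}) but payload has {raw.size}"
        )
    if interleave == "bsq":
        values = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        values = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        values = raw.reshape(lines, samples, bands)
    else:
        raise RasterFormatError(f"{hdr_path}: unknown interleave {interleave!r}")
    wl = None
    if "wavelength" in fields:
        wl = np.array([float(x) for x in fields["wavelength"].split(",") if x.strip()])
        if wl.shape != (bands,):
            raise DimensionMismatchError(
                f"{hdr_path}: {wl.size} wavelengths for {bands} bands"
            )
    return HyperspectralCube(_normalize_dn(values), wavelengths_nm=wl)


def read_cube(path: str | Path) -> HyperspectralCube:
    """Read a hyperspectral cube from TIFF, ENVI (.hdr) or .npz.

    Values come back as float ``(H, W, B)`` with row 0 at the top and the
    band order of the file; integer data is rescaled to [0, 1].
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".hdr":
        return _read_envi_cube(path)
    if suffix == ".npz":
        with np.load(path, allow_pickle=False) as npz:
            values = npz["values"]
            wl = npz["wavelengths_nm"] if "wavelengths_nm" in npz else None
        if values.ndim != 3 or values.shape[2] < 1:
            raise RasterFormatError(f"{path}: expected (H, W, B) array")
        return HyperspectralCube(_normalize_dn(values), wavelengths_nm=wl)
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None, :, :]
        if arr.ndim != 3:
            raise RasterFormatError(f"{path}: expected 2-D or 3-D TIFF")
        # tifffile yields band-major pages (B, H, W) for multi-page rasters
        values = arr.transpose(1, 2, 0)
        wl = None
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            if meta.get("wavelengths_nm") is not None:
                wl = np.asarray(meta["wavelengths_nm"], dtype=float)
                if wl.size != values.shape[2]:
                    raise DimensionMismatchError(
                        f"{sidecar}: {wl.size} wavelengths for {values.shape[2]} bands"
                    )
        return HyperspectralCube(_normalize_dn(values), wavelengths_nm=wl)
    raise RasterFormatError(f"unsupported cube format: {path.suffix!r}")


def write_cube(cube: HyperspectralCube, path: str | Path) -> Path:
    """Write a cube to TIFF (band-major pages), ENVI (.hdr + .dat) or .npz."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npz":
        payload = {"values": cube.values}
        if cube.wavelengths_nm is not None:
            payload["wavelengths_nm"] = cube.wavelengths_nm
        np.savez_compressed(path, **payload)
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(
            path,
            cube.values.transpose(2, 0, 1).astype(np.float32),
            photometric="minisblack",
        )
        if cube.wavelengths_nm is not None:
            meta = {"wavelengths_nm": cube.wavelengths_nm.tolist()}
            path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))
    elif suffix == ".hdr":
        h, w, b = cube.shape
        dat = path.with_suffix(".dat")
        cube.values.transpose(2, 0, 1).astype("<f8").tofile(dat)
        lines = [
            "ENVI",
            f"samples = {w}",
            f"lines = {h}",
            f"bands = {b}",
            "data type = 5",
            "interleave = bsq",
            "byte order = 0",
        ]
        if cube.wavelengths_nm is not None:
            wl = ", ".join(f"{x:g}" for x in cube.wavelengths_nm)
            lines.append("wavelength = {" + wl + "}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise RasterFormatError(f"unsupported cube format: {path.suffix!r}")
    return path


# ---------------------------------------------------------------------------
# label map and guidance I/O
# ---------------------------------------------------------------------------


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".legend.json")


def write_label_map(label_map: LabelMap, path: str | Path) -> Path:
    """Write a label map (TIFF or PNG) plus a JSON legend sidecar.

    Round-trips bit-exactly through :func:`read_label_map`.
    """
    if len(label_map.legend) == 0:
        raise ValueError("empty legend")
    path = Path(path)
    suffix = path.suffix.lower()
    values = label_map.values.astype(np.int32)
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, values)
    elif suffix == ".png":
        import imageio.v3 as iio

        if values.min() < 0 or label_map.nodata < 0:
            # PNG is unsigned; shift so nodata fits
            raise RasterFormatError("PNG label maps require a non-negative nodata code")
        if values.max() > 65535:
            raise RasterFormatError("label values exceed 16-bit PNG range")
        iio.imwrite(path, values.astype(np.uint16))
    else:
        raise RasterFormatError(f"unsupported label-map format: {path.suffix!r}")
    _sidecar(path).write_text(
        json.dumps({"legend": list(label_map.legend), "nodata": int(label_map.nodata)})
    )
    return path


def read_label_map(path: str | Path) -> LabelMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        values = tifffile.imread(path)
    elif suffix == ".png":
        import imageio.v3 as iio

        values = iio.imread(path)
    else:
        raise RasterFormatError(f"unsupported label-map format: {path.suffix!r}")
    side = _sidecar(path)
    if not side.exists():
        raise RasterFormatError(f"missing legend sidecar {side}")
    meta = json.loads(side.read_text())
    return LabelMap(values.astype(np.int64), meta["legend"], nodata=meta["nodata"])


def write_guidance(guidance: GuidanceImage, path: str | Path) -> Path:
    """Write guidance as float TIFF (lossless) or 8-bit PNG (quantized)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        photometric = "rgb" if guidance.values.ndim == 3 else "minisblack"
        tifffile.imwrite(path, guidance.values.astype(np.float32),
                         photometric=photometric)
    elif suffix == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, np.round(guidance.values * 255).astype(np.uint8))
    else:
        raise RasterFormatError(f"unsupported guidance format: {path.suffix!r}")
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps({"provenance": guidance.provenance})
    )
    return path


def read_guidance(path: str | Path) -> GuidanceImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        values = tifffile.imread(path).astype(float)
    elif suffix == ".png":
        import imageio.v3 as iio

        values = iio.imread(path).astype(float) / 255.0
    else:
        raise RasterFormatError(f"unsupported guidance format: {path.suffix!r}")
    provenance = "synthetic"
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        provenance = json.loads(meta_path.read_text()).get("provenance", provenance)
    return GuidanceImage(np.clip(values, 0.0, 1.0), provenance=provenance)


# ---------------------------------------------------------------------------
# sample tables
# ---------------------------------------------------------------------------


def load_samples(
    path: str | Path,
    raster_shape: tuple[int, int],
    legend: Sequence[str] | None = None,
) -> SampleSet:
    """Load a CSV sample table with columns row, col, class, role.

    ``class`` may hold integer ids, or names when ``legend`` is given. A
    ``<name>.legend.json`` sidecar written by :func:`save_samples` supplies
    the legend when the argument is omitted. Coordinates are bounds-checked
    against ``raster_shape`` (half-open) and duplicates rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if legend is None and _sidecar(path).exists():
        legend = json.loads(_sidecar(path).read_text())["legend"]
    df = pd.read_csv(path)
    required = {"row", "col", "class", "role"}
    missing = required - set(df.columns)
    if missing:
        raise SampleError(f"{path}: missing columns {sorted(missing)}")
    cls = df["class"]
    if legend is not None and cls.dtype == object:
        lut = {name: i for i, name in enumerate(legend)}
        unknown = set(cls) - set(lut)
        if unknown:
            raise SampleError(f"unknown class name(s) {sorted(unknown)}")
        class_ids = cls.map(lut).to_numpy()
    else:
        try:
            class_ids = cls.astype(int).to_numpy()
        except (TypeError, ValueError):
            raise SampleError(
                f"{path}: class column is non-integer and no legend was given"
            ) from None
    return SampleSet(
        df["row"].to_numpy(), df["col"].to_numpy(), class_ids,
        df["role"].to_numpy(), raster_shape, legend=legend,
    )


def save_samples(samples: SampleSet, path: str | Path) -> Path:
    """Write the sample table as CSV (+ legend sidecar when known)."""
    path = Path(path)
    pd.DataFrame(
        {
            "row": samples.rows,
            "col": samples.cols,
            "class": samples.class_ids,
            "role": samples.roles,
        }
    ).to_csv(path, index=False)
    if samples.legend is not None:
        _sidecar(path).write_text(json.dumps({"legend": list(samples.legend)}))
    return path
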