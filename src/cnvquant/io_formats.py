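"""Image and study-manifest I/O plus tidy measurement tables.

En-face angiograms are held as :class:`ImageFrame` objects: a 2-D float
raster min-max normalized to [0, 1] with study metadata (animal, eye,
modality, week, treatment arm, administration route, same-session
replicate index).  Longitudinal studies are described by a
:class:`StudyManifest` (CSV or JSON on disk) and measurement results are
collected in a :class:`MeasurementTable` written as CSV with
three-decimal percentages.

Conventions fixed once for the whole package:

* intensities are floats in [0, 1] (min-max normalized at load time);
* pixel coordinates are row-major, origin top-left, 0-based;
* densities are pixel-fraction percentages — physical pixel size is
  never modeled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import DegenerateImageError, SchemaError, ValidationError

MODALITIES = ("OCTA", "ICGA")
EYES = ("OD", "OS")
ARMS = ("saline", "aflibercept", "ranibizumab")
ROUTES = ("subconjunctival", "topical")

MANIFEST_COLUMNS = (
    "animal_id",
    "eye",
    "modality",
    "week",
    "arm",
    "route",
    "replicate",
    "file_path",
)

MEASUREMENT_COLUMNS = (
    "animal_id",
    "modality",
    "week",
    "arm",
    "route",
    "vessel_density_pct",
    "growth_density_pct",
    "interval",
)

MIN_IMAGE_SIDE = 64


@dataclass
class ImageFrame:
    """One 2-D grayscale en-face angiogram with study metadata."""

    pixels: np.ndarray
    modality: str
    animal_id: str = ""
    eye: str = "OD"
    week: int = 1
    arm: str = "saline"
    route: str = "subconjunctival"
    replicate: int = 1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"ImageFrame requires a 2-D raster, got shape {self.pixels.shape}"
            )
        h, w = self.pixels.shape
        if h < MIN_IMAGE_SIDE or w < MIN_IMAGE_SIDE:
            raise ValidationError(
                f"image too small: {h}x{w}, minimum side is {MIN_IMAGE_SIDE}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("image contains non-finite intensities")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0.0 or hi > 1.0:
            raise ValidationError(
                f"intensities outside [0, 1]: range [{lo:.4g}, {hi:.4g}]"
            )
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if self.eye not in EYES:
            raise ValidationError(f"unknown eye {self.eye!r}")
        if self.arm not in ARMS:
            raise ValidationError(f"unknown arm {self.arm!r}")
        if self.route not in ROUTES:
            raise ValidationError(f"unknown route {self.route!r}")
        if int(self.week) < 1 or int(self.replicate) < 1:
            raise ValidationError("week and replicate are 1-based positive integers")
        self.week = int(self.week)
        self.replicate = int(self.replicate)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "ImageFrame":
        """Return a copy of this frame carrying new pixel data."""
        return replace(self, pixels=pixels)


@dataclass(frozen=True)
class ManifestRecord:
    animal_id: str
    eye: str
    modality: str
    week: int
    arm: str
    route: str
    replicate: int
    file_path: str

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.animal_id, self.modality, self.week, self.replicate)


@dataclass
class StudyManifest:
    """Ordered list of image records describing one longitudinal study."""

    records: list[ManifestRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = sorted(
            self.records,
            key=lambda r: (r.animal_id, r.modality, r.week, r.replicate),
        )
        self._validate()

    def _validate(self) -> None:
        seen: set[tuple] = set()
        for r in self.records:
            if r.modality not in MODALITIES:
                raise ValidationError(f"unknown modality {r.modality!r} in manifest")
            if r.eye not in EYES or r.arm not in ARMS or r.route not in ROUTES:
                raise ValidationError(f"invalid enum value in record {r}")
            if r.week < 1 or r.replicate < 1:
                raise ValidationError(f"week/replicate must be >= 1 in record {r}")
            if r.key in seen:
                raise ValidationError(
                    f"duplicate manifest key (animal_id, modality, week, replicate) "
                    f"= {r.key}"
                )
            seen.add(r.key)
        # weeks per animal must form a contiguous ascending sequence
        by_animal: dict[str, set[int]] = {}
        for r in self.records:
            by_animal.setdefault(r.animal_id, set()).add(r.week)
        for animal, weeks in by_animal.items():
            lo, hi = min(weeks), max(weeks)
            if weeks != set(range(lo, hi + 1)):
                raise ValidationError(
                    f"weeks for animal {animal!r} are not contiguous: {sorted(weeks)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def animals(self) -> list[str]:
        return sorted({r.animal_id for r in self.records})

    def select(self, **criteria) -> list[ManifestRecord]:
        """Records matching all the given field values."""
        out = []
        for r in self.records:
            if all(getattr(r, k) == v for k, v in criteria.items()):
                out.append(r)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {c: getattr(r, c) for c in MANIFEST_COLUMNS}
                for r in self.records
            ],
            columns=list(MANIFEST_COLUMNS),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(
                json.dumps(
                    [{c: getattr(r, c) for c in MANIFEST_COLUMNS} for r in self.records],
                    indent=2,
                )
            )
        else:
            self.to_dataframe().to_csv(path, index=False)


def read_image(path: str | Path, meta: ManifestRecord | None = None) -> ImageFrame:
    """Read a TIFF/PNG angiogram, min-max normalize, attach metadata.

    RGB rasters are tolerated and converted by channel-mean luminance.
    A constant (zero-variance) image carries no vascular signal and is
    rejected.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by plugin
        raise OSError(f"could not decode image file {path}") from exc
    arr = np.asarray(raw, dtype=np.float64)
    if arr.ndim == 3:
        if arr.shape[2] in (3, 4):
            arr = arr[:, :, :3].mean(axis=2)
        else:
            raise ValidationError(
                f"{path}: expected single-channel or RGB image, got shape {arr.shape}"
            )
    if arr.ndim != 2:
        raise ValidationError(f"{path}: expected 2-D raster, got shape {arr.shape}")
    lo, hi = float(arr.min()), float(arr.max())
    if hi - lo <= 0.0:
        raise DegenerateImageError(f"{path}: zero-variance (constant) image")
    arr = (arr - lo) / (hi - lo)
    kwargs = {}
    if meta is not None:
        kwargs = dict(
            animal_id=meta.animal_id,
            eye=meta.eye,
            week=meta.week,
            arm=meta.arm,
            route=meta.route,
            replicate=meta.replicate,
        )
        modality = meta.modality
    else:
        modality = "OCTA"
    return ImageFrame(pixels=arr, modality=modality, **kwargs)


def write_image(pixels: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] float raster (or boolean mask) as an 8-bit PNG/TIFF."""
    arr = np.asarray(pixels)
    if arr.dtype == bool:
        out = arr.astype(np.uint8) * 255
    else:
        out = np.clip(np.round(np.asarray(arr, dtype=np.float64) * 255.0), 0, 255)
        out = out.astype(np.uint8)
    iio.imwrite(Path(path), out)


def load_manifest(path: str | Path) -> StudyManifest:
    """Load a study manifest from CSV (header row) or JSON (array of objects)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        if not isinstance(rows, list):
            raise SchemaError(f"{path}: JSON manifest must be an array of objects")
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, dtype={"animal_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: manifest missing required columns {missing}")
    records = [
        ManifestRecord(
            animal_id=str(row["animal_id"]),
            eye=str(row["eye"]),
            modality=str(row["modality"]),
            week=int(row["week"]),
            arm=str(row["arm"]),
            route=str(row["route"]),
            replicate=int(row["replicate"]),
            file_path=str(row["file_path"]),
        )
        for _, row in df.iterrows()
    ]
    return StudyManifest(records=records)


@dataclass
class MeasurementTable:
    """Tidy per-visit vessel density and per-interval growth results.

    One row per (animal, modality, week).  ``growth_density_pct`` and
    ``interval`` refer to the consecutive-week interval *ending* at the
    row's week and are empty (NaN / "") for the first visit.
    """

    data: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(MEASUREMENT_COLUMNS))
    )

    def __post_init__(self) -> None:
        missing = [c for c in MEASUREMENT_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"measurement table missing columns {missing}")
        self.data = self.data[list(MEASUREMENT_COLUMNS)].reset_index(drop=True)

    def validate(self) -> None:
        df = self.data
        vd = df["vessel_density_pct"].astype(float)
        if ((vd < 0) | (vd > 100)).any():
            raise ValidationError("vessel_density_pct outside [0, 100]")
        gd = df["growth_density_pct"].astype(float)
        finite = gd[np.isfinite(gd)]
        if ((finite < -100) | (finite > 100)).any():
            raise ValidationError("growth_density_pct outside [-100, 100]")
        for iv, wk in zip(df["interval"], df["week"]):
            if iv in ("", None) or (isinstance(iv, float) and np.isnan(iv)):
                continue
            try:
                a, b = (int(p) for p in str(iv).split("-"))
            except ValueError:
                raise ValidationError(f"malformed interval {iv!r}")
            if b != a + 1 or int(wk) != b:
                raise ValidationError(
                    f"interval {iv!r} does not name the consecutive weeks ending "
                    f"at week {wk}"
                )

    def __len__(self) -> int:
        return len(self.data)


def write_measurements(table: MeasurementTable, path: str | Path) -> None:
    """Write the measurement table as CSV with 3-decimal percentages."""
    table.validate()
    df = table.data.copy()
    for col in ("vessel_density_pct", "growth_density_pct"):
        df[col] = df[col].map(
            lambda v: "" if (v is None or not np.isfinite(float(v))) else f"{float(v):.3f}"
        )
    df.to_csv(Path(path), index=False)


def read_measurements(path: str | Path) -> MeasurementTable:
    df = pd.read_csv(
        Path(path),
        dtype={"animal_id": str, "interval": str},
        keep_default_na=False,
        na_values=[""],
    )
    df["interval"] = df["interval"].fillna("")
    return MeasurementTable(data=df)
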