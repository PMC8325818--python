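"""Core data model and I/O for spot-table analysis.

Coordinate convention
---------------------
All coordinates are continuous pixels in the *image* convention: origin at
the top-left corner, x increasing to the right, y increasing downward.
This matches the nuclear-stain raster without any axis flip; readers expose
a ``flip_y`` option for data recorded in the mathematical convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpotTable",
    "NuclearImage",
    "SegmentedMap",
    "ClassReference",
    "read_spot_table",
    "write_spot_table",
    "read_image",
    "read_class_reference",
    "select_roi",
]

DEFAULT_SAMPLE = "sample_1"


@dataclass
class SpotTable:
    """One row per decoded read: gene label plus 2D pixel coordinates.

    Read order carries no meaning; every operation downstream is invariant
    to permutations of the rows.
    """

    data: pd.DataFrame  # columns: gene, x, y, sample

    def __post_init__(self) -> None:
        req = {"gene", "x", "y"}
        missing = req - set(self.data.columns)
        if missing:
            raise ValueError(f"SpotTable missing columns: {sorted(missing)}")
        if "sample" not in self.data.columns:
            self.data = self.data.assign(sample=DEFAULT_SAMPLE)
        xy = self.data[["x", "y"]].to_numpy(float)
        if not np.isfinite(xy).all():
            raise ValueError("SpotTable coordinates must be finite")
        if (self.data["gene"].astype(str).str.len() == 0).any():
            raise ValueError("empty gene label in SpotTable")

    # -- convenience accessors -------------------------------------------
    @property
    def genes(self) -> np.ndarray:
        return self.data["gene"].to_numpy()

    @property
    def xy(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(float)

    @property
    def x(self) -> np.ndarray:
        return self.data["x"].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.data["y"].to_numpy(float)

    @property
    def samples(self) -> np.ndarray:
        return self.data["sample"].to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    def gene_panel(self) -> list[str]:
        """Sorted list of distinct gene labels."""
        return sorted(map(str, pd.unique(self.data["gene"])))

    def subset_gene(self, gene: str) -> "SpotTable":
        sub = self.data[self.data["gene"] == gene]
        if sub.empty:
            raise KeyError(
                f"gene {gene!r} not present; available: {self.gene_panel()}"
            )
        return SpotTable(sub.reset_index(drop=True))


@dataclass
class NuclearImage:
    """Single-channel nuclear-stain raster in the same frame as the spots.

    ``transform`` maps pixel indices (col, row) to spot coordinates; the
    default identity means spot (x, y) falls on pixel (row=floor(y),
    col=floor(x)).
    """

    pixels: np.ndarray
    transform: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(
                "NuclearImage must be single-channel 2D; got shape "
                f"{self.pixels.shape}. Select one channel before loading."
            )
        if np.nanmin(self.pixels) < 0:
            raise ValueError("negative intensities in NuclearImage")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SegmentedMap:
    """Units × genes count matrix produced by a segmentation strategy.

    ``unit_kind`` is one of ``cell`` (watershed label mask), ``bin``
    (regular, possibly overlapping lattice bins) or ``spot_env``
    (per-read neighborhood).  Row order matches ``centroids`` order.
    """

    counts: pd.DataFrame  # index: unit ids, columns: gene labels
    unit_kind: str
    centroids: np.ndarray  # (units, 2) in spot coordinates
    geometry: dict = field(default_factory=dict)
    sample: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.unit_kind not in {"cell", "bin", "spot_env"}:
            raise ValueError(f"unknown unit_kind {self.unit_kind!r}")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integer")
            self.counts = self.counts.astype(int)
        self.centroids = np.asarray(self.centroids, float)
        if self.centroids.shape != (len(self.counts), 2):
            raise ValueError("centroid/count row mismatch")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate gene columns")
        if self.sample is None:
            self.sample = np.full(len(self.counts), DEFAULT_SAMPLE, object)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_units(self) -> int:
        return len(self.counts)

    def to_csv(self, prefix: str | Path) -> None:
        """Write counts and centroids as ``<prefix>.counts.csv`` /
        ``<prefix>.centroids.csv``."""
        prefix = Path(prefix)
        self.counts.to_csv(f"{prefix}.counts.csv")
        pd.DataFrame(
            self.centroids, index=self.counts.index, columns=["x", "y"]
        ).to_csv(f"{prefix}.centroids.csv")

    def to_mtx(self, prefix: str | Path) -> None:
        """Matrix-market export for sparse count matrices."""
        from scipy import io as sio
        from scipy import sparse

        prefix = Path(prefix)
        sio.mmwrite(f"{prefix}.counts.mtx", sparse.csr_matrix(self.counts.to_numpy()))
        pd.Series(self.genes).to_csv(f"{prefix}.genes.csv", index=False, header=False)

    @classmethod
    def from_csv(cls, prefix: str | Path, unit_kind: str) -> "SegmentedMap":
        prefix = Path(prefix)
        counts = pd.read_csv(f"{prefix}.counts.csv", index_col=0)
        cents = pd.read_csv(f"{prefix}.centroids.csv", index_col=0)
        return cls(counts=counts, unit_kind=unit_kind, centroids=cents[["x", "y"]].to_numpy())


@dataclass
class ClassReference:
    """Cell-type classes × genes mean-expression matrix from scRNA-seq."""

    means: pd.DataFrame  # index: class labels, columns: gene labels

    def __post_init__(self) -> None:
        vals = self.means.to_numpy(float)
        if not np.isfinite(vals).all():
            raise ValueError("reference means must be finite")
        if (vals < 0).any():
            raise ValueError("reference means must be nonnegative")

    @property
    def classes(self) -> list[str]:
        return list(self.means.index)

    @property
    def genes(self) -> list[str]:
        return list(self.means.columns)

    def align_to_panel(self, panel: Sequence[str]) -> "ClassReference":
        """Restrict to the genes shared with ``panel``, in panel order.

        Reference genes missing from the panel are dropped with a warning;
        matching is case-sensitive exact string match.
        """
        shared = [g for g in panel if g in self.means.columns]
        if not shared:
            raise ValueError("reference shares no genes with the panel")
        extra = set(self.means.columns) - set(panel)
        if extra:
            warnings.warn(
                f"dropping {len(extra)} reference genes not in panel: "
                f"{sorted(extra)[:10]}"
            )
        return ClassReference(self.means[shared])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_spot_table(
    path: str | Path,
    *,
    gene_col: str = "gene",
    x_col: str = "x",
    y_col: str = "y",
    sample_col: str | None = "sample",
    delimiter: str = ",",
    flip_y: bool = False,
) -> tuple[SpotTable, dict]:
    """Read a delimited spot table.

    Returns the table plus a report dict counting rows dropped for
    unparseable coordinates.  Missing mapped columns are a hard error;
    ``sample_col`` absent from the file silently falls back to a single
    sample id.
    """
    df = pd.read_csv(path, sep=delimiter)
    for col in (gene_col, x_col, y_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    out = pd.DataFrame({
        "gene": df[gene_col].astype(str),
        "x": pd.to_numeric(df[x_col], errors="coerce"),
        "y": pd.to_numeric(df[y_col], errors="coerce"),
    })
    if sample_col is not None and sample_col in df.columns:
        out["sample"] = df[sample_col].astype(str)
    ok = np.isfinite(out["x"].to_numpy(float)) & np.isfinite(out["y"].to_numpy(float))
    n_dropped = int((~ok).sum())
    out = out[ok].reset_index(drop=True)
    if out.empty:
        raise ValueError(f"no valid reads in {path}")
    if flip_y:
        out["y"] = out["y"].max() - out["y"]
    return SpotTable(out), {"n_dropped": n_dropped, "n_reads": len(out)}


def write_spot_table(spots: SpotTable, path: str | Path, delimiter: str = ",") -> None:
    spots.data.to_csv(path, sep=delimiter, index=False)


def read_image(path: str | Path) -> NuclearImage:
    """Read a TIFF or PNG nuclear-stain image (single channel)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    return NuclearImage(np.asarray(arr))


def read_class_reference(
    path: str | Path,
    *,
    delimiter: str = ",",
    orientation: str = "classes_by_genes",
) -> ClassReference:
    """Read a per-class mean-expression matrix.

    ``orientation`` is ``classes_by_genes`` (rows are classes) or
    ``genes_by_classes`` (transposed file).
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if orientation == "genes_by_classes":
        df = df.T
    elif orientation != "classes_by_genes":
        raise ValueError(f"unknown orientation {orientation!r}")
    return ClassReference(df.astype(float))


# ---------------------------------------------------------------------------
# ROI selection
# ---------------------------------------------------------------------------

def select_roi(spots: SpotTable, rect: tuple[float, float, float, float]) -> SpotTable:
    """Keep reads inside the half-open box [xmin, xmax) × [ymin, ymax).

    Half-open edges mean a tiling of ROI boxes partitions the reads exactly.
    An empty result is allowed.
    """
    xmin, xmax, ymin, ymax = rect
    if not (xmin < xmax and ymin < ymax):
        raise ValueError("ROI requires xmin < xmax and ymin < ymax")
    m = (
        (spots.x >= xmin)
        & (spots.x < xmax)
        & (spots.y >= ymin)
        & (spots.y < ymax)
    )
    return SpotTable(spots.data[m].reset_index(drop=True))
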