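"""Seeded synthetic-data generators for every analysis surface.

These emulate the structures the toolbox is built to detect: layered tissue
with layer-restricted genes, smooth expression gradients, coincident and
mutually exclusive gene pairs, nuclei as bright Gaussian blobs on a dark
background, and cells whose gene counts are Poisson draws from class
mean-expression profiles.  Every generator is a pure function of its
parameters and seed, and always returns ground truth alongside the data.
Not modeled: optical crowding, decoding errors, autofluorescence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ClassReference, NuclearImage, SpotTable

__all__ = [
    "LayerBand",
    "TissueSpec",
    "make_layered_tissue",
    "make_nuclei_image",
    "make_typed_cells",
]


@dataclass
class LayerBand:
    """A band x in [x_min, x_max) spanning the full field height, with a
    multinomial over its genes."""

    x_min: float
    x_max: float
    gene_probs: dict[str, float]


@dataclass
class TissueSpec:
    """Planted structure for a synthetic spot map.

    Components are independent; each contributes ``reads`` reads and every
    generated read carries a ground-truth component label.
    """

    field_size: tuple[float, float] = (1000.0, 1000.0)
    layers: list[LayerBand] = field(default_factory=list)
    reads_per_layer: int = 0
    gradient_genes: dict[str, float] = field(default_factory=dict)  # gene -> sd of x
    reads_per_gradient_gene: int = 0
    coincident_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    reads_per_pair: int = 0
    background_genes: list[str] = field(default_factory=list)
    reads_per_background_gene: int = 0

    def total_reads(self) -> int:
        return (
            len(self.layers) * self.reads_per_layer
            + len(self.gradient_genes) * self.reads_per_gradient_gene
            + 2 * len(self.coincident_pairs) * self.reads_per_pair
            + len(self.background_genes) * self.reads_per_background_gene
        )


def make_layered_tissue(spec: TissueSpec, seed: int = 0) -> tuple[SpotTable, pd.DataFrame]:
    """Draw a spot table with the planted structure of ``spec``.

    Layer reads are uniform inside their band with genes drawn from the
    band multinomial; gradient genes are Gaussian-concentrated in x at the
    field center and uniform in y; each coincident pair (a, b, offset)
    places b exactly ``offset`` pixels from its a partner in a random
    direction; background genes are uniform over the field.  Returns the
    table plus a truth table with one row per read (component + generator
    metadata).
    """
    if spec.total_reads() == 0:
        raise ValueError("spec generates zero reads")
    rng = np.random.default_rng(seed)
    w, h = spec.field_size
    rows: list[pd.DataFrame] = []

    for li, band in enumerate(spec.layers):
        n = spec.reads_per_layer
        genes = list(band.gene_probs)
        p = np.asarray([band.gene_probs[g] for g in genes], float)
        p = p / p.sum()
        rows.append(pd.DataFrame({
            "gene": rng.choice(genes, size=n, p=p),
            "x": rng.uniform(band.x_min, band.x_max, n),
            "y": rng.uniform(0, h, n),
            "component": f"layer_{li}",
        }))

    for gene, sd in spec.gradient_genes.items():
        n = spec.reads_per_gradient_gene
        x = np.clip(rng.normal(w / 2, sd, n), 0, np.nextafter(w, 0))
        rows.append(pd.DataFrame({
            "gene": gene, "x": x, "y": rng.uniform(0, h, n),
            "component": f"gradient_{gene}",
        }))

    for a, bgene, offset in spec.coincident_pairs:
        n = spec.reads_per_pair
        ax = rng.uniform(0, w, n)
        ay = rng.uniform(0, h, n)
        theta = rng.uniform(0, 2 * np.pi, n)
        rows.append(pd.DataFrame({
            "gene": a, "x": ax, "y": ay, "component": f"pair_{a}_{bgene}",
        }))
        rows.append(pd.DataFrame({
            "gene": bgene,
            "x": ax + offset * np.cos(theta),
            "y": ay + offset * np.sin(theta),
            "component": f"pair_{a}_{bgene}",
        }))

    for gene in spec.background_genes:
        n = spec.reads_per_background_gene
        rows.append(pd.DataFrame({
            "gene": gene, "x": rng.uniform(0, w, n), "y": rng.uniform(0, h, n),
            "component": "background",
        }))

    truth = pd.concat(rows, ignore_index=True)
    spots = SpotTable(truth[["gene", "x", "y"]].copy())
    return spots, truth


def make_nuclei_image(
    *,
    n_nuclei: int | None = None,
    centers: np.ndarray | None = None,
    nucleus_sd: float = 10.0,
    intensity: float = 200.0,
    noise_sd: float = 0.0,
    offset: float = 0.0,
    size: tuple[int, int] = (256, 256),
    min_separation: float | None = None,
    seed: int = 0,
) -> tuple[NuclearImage, np.ndarray, dict]:
    """Synthetic nuclear stain: Gaussian bumps on a dark background.

    Either pass explicit ``centers`` (m, 2) as (x, y) or a count
    ``n_nuclei`` to place uniformly at random (≥ 3 nucleus_sd from the
    border).  Returns the image, the true centers, and metadata flagging
    center pairs closer than ``min_separation`` (default 4 * nucleus_sd)
    as possibly not separable.
    """
    rng = np.random.default_rng(seed)
    h, w = size
    if centers is None:
        if not n_nuclei:
            raise ValueError("give centers or n_nuclei")
        m = 3 * nucleus_sd
        centers = np.column_stack([
            rng.uniform(m, w - m, n_nuclei), rng.uniform(m, h - m, n_nuclei)
        ])
    centers = np.asarray(centers, float)
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.full((h, w), float(offset))
    for cx, cy in centers:
        img += intensity * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * nucleus_sd**2)
        )
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0, noise_sd, img.shape), 0, None)
    if min_separation is None:
        min_separation = 4.0 * nucleus_sd
    flagged = []
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            if np.linalg.norm(centers[i] - centers[j]) < min_separation:
                flagged.append((i, j))
    meta = {"too_close_pairs": flagged, "nucleus_sd": nucleus_sd, "seed": seed}
    return NuclearImage(img), centers, meta


def make_typed_cells(
    ref: ClassReference,
    n_cells: int,
    *,
    depth: float = 1.0,
    cell_radius: float = 12.0,
    size: tuple[int, int] = (512, 512),
    seed: int = 0,
    max_retries: int = 200,
) -> tuple[SpotTable, np.ndarray, pd.DataFrame]:
    """Cells with Poisson counts drawn from class mean-expression profiles.

    Each cell gets a class (uniform over reference classes), a disc
    footprint placed without overlap (rejection sampling up to
    ``max_retries`` per cell), and per-gene counts ~ Poisson(depth * mu);
    reads fall uniformly inside the footprint.  Returns the spot table,
    the disc label mask (cell i -> label i+1), and a truth table with
    class, center and depth per cell.  Cells that draw zero reads are
    flagged in the truth table.
    """
    rng = np.random.default_rng(seed)
    h, w = size
    classes = ref.classes
    genes = ref.genes
    mu = ref.means.to_numpy(float)

    centers = np.empty((n_cells, 2))
    placed = 0
    while placed < n_cells:
        for _ in range(max_retries):
            c = np.array([
                rng.uniform(cell_radius, w - cell_radius),
                rng.uniform(cell_radius, h - cell_radius),
            ])
            if placed == 0 or (
                np.linalg.norm(centers[:placed] - c, axis=1) >= 2 * cell_radius
            ).all():
                centers[placed] = c
                placed += 1
                break
        else:
            raise RuntimeError(
                f"could not place {n_cells} non-overlapping cells in {size}"
            )

    class_idx = rng.integers(0, len(classes), n_cells)
    # reads stay >= 2 px inside the footprint so the floor-to-pixel lookup
    # of assign_spots cannot step outside the disc label
    read_radius = max(cell_radius - 2.0, 1.0)
    spot_rows = []
    truth_rows = []
    for i in range(n_cells):
        lam = depth * mu[class_idx[i]]
        counts = rng.poisson(lam)
        tot = int(counts.sum())
        for g, cnt in zip(genes, counts):
            if cnt == 0:
                continue
            r = read_radius * np.sqrt(rng.uniform(0, 1, cnt))
            th = rng.uniform(0, 2 * np.pi, cnt)
            spot_rows.append(pd.DataFrame({
                "gene": g,
                "x": centers[i, 0] + r * np.cos(th),
                "y": centers[i, 1] + r * np.sin(th),
                "cell": i,
            }))
        truth_rows.append({
            "cell": i, "class": classes[class_idx[i]],
            "x": centers[i, 0], "y": centers[i, 1],
            "depth": depth, "n_reads": tot, "zero_reads": tot == 0,
        })

    truth = pd.DataFrame(truth_rows)
    all_spots = (
        pd.concat(spot_rows, ignore_index=True)
        if spot_rows else pd.DataFrame(columns=["gene", "x", "y", "cell"])
    )
    mask = np.zeros((h, w), dtype=np.int32)
    rad = int(np.ceil(cell_radius)) + 1
    for i, (cx, cy) in enumerate(centers):
        r0, r1 = max(int(cy) - rad, 0), min(int(cy) + rad + 1, h)
        c0, c1 = max(int(cx) - rad, 0), min(int(cx) + rad + 1, w)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= cell_radius**2
        mask[r0:r1, c0:c1][disc] = i + 1
    spots = SpotTable(all_spots[["gene", "x", "y"]].copy())
    return spots, mask, truth
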