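"""Probabilistic cell typing against an scRNA-seq reference.

Each segmented cell is classified by a Poisson-likelihood Bayes rule: for
cell c with gene counts n_cg and class mean-expression profiles mu_kg,

    s_c     = (sum_g n_cg) / median_k (sum_g mu_kg)
    L(c, k) = sum_g [ n_cg * log(s_c * mu_kg + eps) - (s_c * mu_kg + eps) ]
    P(k | c) ∝ prior_k * exp(L(c, k))

The per-cell scale s_c absorbs sequencing-depth differences (median over
class totals makes it robust to outlier classes), and the pseudo-expression
eps guards log 0 for dropout genes.  This is a cell-level reduction of the
pciSeq family of models: spot-level reassignment, misread modeling and gene
efficiency re-estimation are deliberately not included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core import ClassReference, SegmentedMap
from .embed import ClusterAssignment

__all__ = ["TypingResult", "pciseq_assign", "class_composition", "typing_means",
           "domains_for_cells"]


@dataclass
class TypingResult:
    """Posterior class probabilities per cell plus the hard assignment."""

    probabilities: pd.DataFrame  # cells × classes, rows sum to 1
    assignments: pd.Series  # most-probable class per cell
    counts: pd.DataFrame  # gene counts echo (cells × genes used)
    priors: pd.Series
    epsilon: float
    scale: pd.Series  # per-cell s_c
    zero_read_cells: np.ndarray  # unit ids flagged with uniform posterior

    def to_csv(self, prefix: str) -> None:
        self.probabilities.to_csv(f"{prefix}.probabilities.csv")
        self.assignments.to_csv(f"{prefix}.assignments.csv")


def pciseq_assign(
    seg: SegmentedMap,
    ref: ClassReference,
    *,
    priors: pd.Series | None = None,
    epsilon: float = 0.1,
    scale: float | np.ndarray | None = None,
) -> TypingResult:
    """Poisson-Bayes classification of segmented cells.

    Genes are intersected between the count matrix and the reference
    (warning below 5 shared genes).  Priors default to uniform; only their
    ratios matter.  Cells with zero reads get a uniform posterior and are
    flagged; classes with all-zero means are excluded with a warning.
    Ties in the argmax break toward the first class in reference order.
    ``scale`` overrides the per-cell s_c (scalar or per-cell array) when
    the reference is already on the counts' depth scale.
    """
    shared = [g for g in seg.genes if g in ref.means.columns]
    if not shared:
        raise ValueError("no shared genes between counts and reference")
    if len(shared) < 5:
        warnings.warn(f"only {len(shared)} shared genes; typing will be weak")
    counts = seg.counts[shared]
    mu = ref.means[shared].to_numpy(float)  # (K, G)
    classes = list(ref.means.index)
    alive = mu.sum(axis=1) > 0
    if not alive.all():
        warnings.warn(f"excluding all-zero classes: "
                      f"{[c for c, a in zip(classes, alive) if not a]}")
        mu = mu[alive]
        classes = [c for c, a in zip(classes, alive) if a]
    if priors is None:
        priors = pd.Series(1.0 / len(classes), index=classes)
    else:
        priors = priors.reindex(classes)
        if priors.isna().any() or (priors <= 0).any():
            raise ValueError("priors must be positive for every class")

    n = counts.to_numpy(float)  # (C, G)
    cell_tot = n.sum(axis=1)
    if scale is None:
        class_tot = mu.sum(axis=1)
        s = cell_tot / np.median(class_tot)  # (C,)
    else:
        s = np.broadcast_to(np.asarray(scale, float), cell_tot.shape).copy()

    lam = s[:, None, None] * mu[None, :, :] + epsilon  # (C, K, G)
    loglik = (n[:, None, :] * np.log(lam) - lam).sum(axis=2)  # (C, K)
    logpost = loglik + np.log(priors.to_numpy())[None, :]
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    post = np.exp(logpost)

    zero = cell_tot == 0
    post[zero] = 1.0 / len(classes)
    probs = pd.DataFrame(post, index=counts.index, columns=classes)
    hard = pd.Series(
        np.asarray(classes, object)[post.argmax(axis=1)],
        index=counts.index, name="class",
    )
    return TypingResult(
        probabilities=probs,
        assignments=hard,
        counts=counts,
        priors=priors,
        epsilon=float(epsilon),
        scale=pd.Series(s, index=counts.index, name="scale"),
        zero_read_cells=counts.index.to_numpy()[zero],
    )


def domains_for_cells(
    cells: SegmentedMap, domains_seg: SegmentedMap, domains: ClusterAssignment
) -> np.ndarray:
    """Domain id per cell, by nearest domain-unit centroid membership."""
    from scipy.spatial import cKDTree

    _, idx = cKDTree(domains_seg.centroids).query(cells.centroids)
    return np.asarray(domains.labels)[idx]


def class_composition(
    typing: TypingResult, domains: np.ndarray
) -> pd.DataFrame:
    """Relative class frequencies per spatial domain (rows sum to 1).

    ``domains`` is a per-cell domain id aligned with the typing rows;
    use :func:`domains_for_cells` to derive it from clustered bins.
    Domains with no cells get a zero row with a warning.
    """
    domains = np.asarray(domains)
    if len(domains) != len(typing.assignments):
        raise ValueError("domains not aligned to typed cells")
    classes = list(typing.probabilities.columns)
    tab = pd.crosstab(domains, typing.assignments)
    tab = tab.reindex(columns=classes, fill_value=0)
    tot = tab.sum(axis=1)
    if (tot == 0).any():
        warnings.warn("domain(s) with no cells: zero frequency rows")
    freq = tab.div(tot.replace(0, 1), axis=0).astype(float)
    freq.index.name = "domain"
    return freq


def typing_means(typing: TypingResult, seg: SegmentedMap) -> pd.DataFrame:
    """Mean expression per hard-assigned class, column-normalized per gene.

    Each gene column sums to 1 over classes, matching the per-gene
    normalization used elsewhere in the toolbox.
    """
    counts = seg.counts.loc[typing.assignments.index].astype(float)
    df = counts.copy()
    df["_class"] = typing.assignments
    means = df.groupby("_class").mean()
    tot = means.sum(axis=0)
    means = means.div(tot.replace(0, 1), axis=1)
    means.index.name = "class"
    return means
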