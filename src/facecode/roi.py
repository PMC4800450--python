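"""ROI extraction and the three per-subject neural-code measures.

A subject's region of interest (ROI) is the connected component of
supra-threshold voxels (contrast Z > threshold) containing, or nearest to,
a seed coordinate. From the ROI's voxel responses three scalars are derived:

* ``overall_selectivity`` — the contrast Z (faces > objects) averaged over
  ROI voxels: a univariate, localized code.
* ``between_category_dissimilarity`` — 1 minus the Pearson correlation
  between the spatial beta patterns of two categories, after subtracting
  each voxel's mean response across a centering set of categories
  (mean-pattern / "cocktail-blank" removal): a distributed code.
* ``within_category_dissimilarity`` — 1 minus the correlation between two
  independent runs' patterns for the same category: an inverse test-retest
  reliability used as a noise index.

Centering over exactly the two compared categories is rejected by default:
the centered vectors are then exact negatives of each other, forcing the
dissimilarity to 2 regardless of the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ROIMask",
    "PatternMatrix",
    "NeuralMeasures",
    "extract_roi",
    "overall_selectivity",
    "between_category_dissimilarity",
    "within_category_dissimilarity",
    "compute_measures",
]

DEFAULT_CATEGORIES = ("faces", "objects", "scenes", "scrambled")

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class ROIMask:
    """Connected supra-threshold voxel set within a volume grid."""

    indices: np.ndarray          # (k, 3) integer voxel coordinates
    shape: tuple[int, int, int]  # grid shape the indices refer to
    seed: tuple[int, int, int]
    threshold: float

    @property
    def size(self) -> int:
        return int(self.indices.shape[0])

    def to_volume(self) -> np.ndarray:
        vol = np.zeros(self.shape, dtype=bool)
        vol[tuple(self.indices.T)] = True
        return vol


@dataclass(frozen=True)
class PatternMatrix:
    """Per-subject ROI voxel responses.

    betas has shape (n_categories, n_runs, n_voxels); contrast_z has shape
    (n_voxels,) and holds the faces-versus-objects contrast Z per voxel.
    """

    categories: tuple[str, ...]
    betas: np.ndarray
    contrast_z: np.ndarray

    def __post_init__(self):
        betas = np.asarray(self.betas, dtype=float)
        z = np.asarray(self.contrast_z, dtype=float)
        if betas.ndim != 3:
            raise ValueError("betas must be (categories, runs, voxels)")
        if betas.shape[0] != len(self.categories):
            raise ValueError("first beta axis must match the category list")
        if z.shape != (betas.shape[2],):
            raise ValueError("contrast_z must have one value per voxel")
        object.__setattr__(self, "betas", betas)
        object.__setattr__(self, "contrast_z", z)

    @property
    def n_runs(self) -> int:
        return self.betas.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[2]

    def category_index(self, label: str) -> int:
        try:
            return self.categories.index(label)
        except ValueError:
            raise KeyError(f"unknown category {label!r}; have {self.categories}") from None


@dataclass(frozen=True)
class NeuralMeasures:
    """The three derived scalars for one subject."""

    overall_selectivity: float
    between_dissimilarity: float
    within_dissimilarity: float


def extract_roi(
    zmap: np.ndarray,
    seed: tuple[int, int, int],
    threshold: float = 2.3,
    neighborhood: int = 26,
    min_size: int = 1,
    search_radius: float = 5.0,
) -> ROIMask | None:
    """Connected supra-threshold component at (or nearest to) the seed.

    The Z map is thresholded at ``zmap > threshold``; connected components
    are labeled under the requested 3-D neighborhood (6, 18 or 26). If the
    seed voxel itself is supra-threshold its component is returned;
    otherwise the component of the nearest supra-threshold voxel within
    ``search_radius`` (Euclidean, in voxels) is used. Components smaller
    than ``min_size`` are ignored.

    Returns ``None`` when no qualifying ROI exists — "ROI not identified"
    is an expected outcome, not an error.
    """
    zmap = np.asarray(zmap, dtype=float)
    if zmap.ndim != 3:
        raise ValueError("zmap must be a 3-D volume")
    seed = tuple(int(c) for c in seed)
    if len(seed) != 3 or any(not 0 <= c < s for c, s in zip(seed, zmap.shape)):
        raise ValueError(f"seed {seed} outside volume bounds {zmap.shape}")
    if neighborhood not in _STRUCTURES:
        raise ValueError("neighborhood must be 6, 18 or 26")

    supra = zmap > threshold
    labels, n_comp = ndimage.label(supra, structure=_STRUCTURES[neighborhood])
    if n_comp == 0:
        return None

    sizes = np.bincount(labels.ravel())
    target = labels[seed]
    if target == 0 or sizes[target] < min_size:
        cand = np.argwhere(supra & (np.take(sizes, labels) >= min_size))
        if cand.size == 0:
            return None
        dist = np.sqrt(((cand - np.array(seed)) ** 2).sum(axis=1))
        j = int(np.argmin(dist))
        if dist[j] > search_radius:
            return None
        target = labels[tuple(cand[j])]
    if sizes[target] < min_size:
        return None
    indices = np.argwhere(labels == target)
    return ROIMask(indices=indices, shape=zmap.shape, seed=seed, threshold=float(threshold))


def overall_selectivity(contrast_z: np.ndarray) -> float:
    """Arithmetic mean of the contrast Z values over ROI voxels."""
    z = np.asarray(contrast_z, dtype=float)
    if z.size == 0:
        raise ValueError("empty ROI: selectivity undefined")
    return float(z.mean())


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    u = u - u.mean()
    v = v - v.mean()
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-variance pattern vector: correlation undefined")
    return float(np.dot(u, v) / (nu * nv))


def _check_bounds(d: float) -> float:
    assert -1e-12 <= d <= 2 + 1e-12, f"dissimilarity {d} outside [0, 2]"
    return float(min(max(d, 0.0), 2.0))


def between_category_dissimilarity(
    patterns: PatternMatrix,
    category_a: str = "faces",
    category_b: str = "objects",
    centering_categories: tuple[str, ...] | None = DEFAULT_CATEGORIES,
) -> float:
    """1 − Pearson correlation between two categories' spatial patterns.

    Betas are first averaged across runs per category. When
    ``centering_categories`` is given, the voxelwise mean pattern across
    those categories is subtracted from each compared vector before
    correlating (mean-pattern removal). Pass ``None`` to skip centering.

    Centering over exactly {category_a, category_b} is rejected: in that
    case the centered vectors are exact negatives, so the result would be
    2 for any non-identical input.
    """
    if patterns.n_voxels < 2:
        raise ValueError("need at least 2 voxels for a pattern correlation")
    ia = patterns.category_index(category_a)
    ib = patterns.category_index(category_b)
    if ia == ib:
        raise ValueError("category_a and category_b must differ")
    mean_betas = patterns.betas.mean(axis=1)  # (categories, voxels)
    va = mean_betas[ia]
    vb = mean_betas[ib]
    if centering_categories is not None:
        cset = tuple(centering_categories)
        if set(cset) == {category_a, category_b}:
            raise ValueError(
                "centering over exactly the two compared categories is degenerate: "
                "the centered vectors are exact negatives and the dissimilarity is "
                "forced to 2; use at least 3 centering categories or disable centering"
            )
        if len(cset) < 3:
            raise ValueError("centering requires at least 3 categories")
        idx = [patterns.category_index(c) for c in cset]
        mean_pattern = mean_betas[idx].mean(axis=0)
        va = va - mean_pattern
        vb = vb - mean_pattern
    return _check_bounds(1.0 - _pearson(va, vb))


def within_category_dissimilarity(
    patterns: PatternMatrix,
    category: str = "faces",
    run_a: int = 0,
    run_b: int = 1,
) -> float:
    """1 − Pearson correlation between two runs' patterns for one category.

    No cross-category centering is applied; the two runs are independent
    estimates of the same pattern, so this is an inverse test-retest
    reliability (larger = noisier).
    """
    if run_a == run_b:
        raise ValueError("run_a and run_b must differ")
    ic = patterns.category_index(category)
    n_runs = patterns.n_runs
    for r in (run_a, run_b):
        if not 0 <= r < n_runs:
            raise ValueError(f"run index {r} out of range for {n_runs} runs")
    va = patterns.betas[ic, run_a]
    vb = patterns.betas[ic, run_b]
    return _check_bounds(1.0 - _pearson(va, vb))


def compute_measures(
    patterns: PatternMatrix,
    centering_categories: tuple[str, ...] | None = DEFAULT_CATEGORIES,
) -> NeuralMeasures:
    """All three neural-code measures for one subject's ROI patterns."""
    return NeuralMeasures(
        overall_selectivity=overall_selectivity(patterns.contrast_z),
        between_dissimilarity=between_category_dissimilarity(
            patterns, centering_categories=centering_categories
        ),
        within_dissimilarity=within_category_dissimilarity(patterns),
    )
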