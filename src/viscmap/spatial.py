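"""Spatial statistics on labelled neuron (and bouton) point sets.

The segregation index (SI) contrasts, for every point, its mean distance to
the other response group against its mean distance to its own group
(self excluded), averaged over all points, and normalizes by the grand
cross+within mean distance under random label permutations:

    SI = [ (1/(n+m)) * sum_p (cross_mean(p) - within_mean(p)) ]
         / [ mean over permutations of (1/(2(n+m))) * sum_p
             (cross_mean(p) + within_mean(p)) under permuted labels ]

SI > 0 for segregated groups, ~0 for spatially mixed groups, < 0 for
interleaved (anti-clustered) groups. 1,000 random permutations are used by
default; instances small enough that all (n+m)! label permutations can be
enumerated are evaluated exactly. When pooling FOVs, the mean of per-FOV
numerators is divided by the mean of per-FOV denominators.

SI is computed on in-plane (x, y) coordinates by default; pass 3D points
explicitly for depth analyses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist, pdist, squareform
from skimage.feature import canny

logger = logging.getLogger(__name__)

EXHAUSTIVE_LIMIT = 10_000  # enumerate all permutations when (n+m)! <= this


@dataclass
class SegregationResult:
    si: float
    numerator: float
    denominator: float
    n_permutations: int
    seed: int | None
    exhaustive: bool

    def to_dict(self) -> dict:
        return {
            "si": self.si,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "exhaustive": self.exhaustive,
        }


def _check_groups(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] < 2 or Y.shape[0] < 2:
        raise ValueError(
            f"segregation index needs >= 2 points per group, got {X.shape[0]} and "
            f"{Y.shape[0]} (within-group mean undefined)"
        )
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must share dimensionality")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("positions must be finite")
    return X, Y


def si_numerator(X: np.ndarray, Y: np.ndarray) -> float:
    """Observed (un-normalized) segregation: mean over points of
    [mean cross-group distance - mean own-group distance, self excluded]."""
    X, Y = _check_groups(X, Y)
    n, m = X.shape[0], Y.shape[0]
    D = squareform(pdist(np.vstack([X, Y])))
    sx = D[:, :n].sum(axis=1)  # distance sums to group X (self term is 0)
    sy = D[:, n:].sum(axis=1)
    terms_x = sy[:n] / m - sx[:n] / (n - 1)
    terms_y = sx[n:] / n - sy[n:] / (m - 1)
    return float((terms_x.sum() + terms_y.sum()) / (n + m))


def _denominator_terms(D: np.ndarray, n: int, m: int, masks: np.ndarray) -> np.ndarray:
    """Denominator value for each permuted labelling.

    ``masks`` is (P, n+m) boolean, True where a point carries the X label
    under that permutation. Fully vectorized over permutations.
    """
    N = n + m
    rowsum = D.sum(axis=1)  # (N,)
    SX = D @ masks.T.astype(float)  # (N, P): per point, distance sum to X'
    SY = rowsum[:, None] - SX
    Mx = masks.T  # (N, P)
    term_x = Mx * (SY / m + SX / (n - 1))
    term_y = (~Mx) * (SX / n + SY / (m - 1))
    return (term_x.sum(axis=0) + term_y.sum(axis=0)) / (2 * N)


def _permutation_masks(
    N: int,
    n: int,
    n_permutations: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """X'-membership masks for random permutations, or for all N!
    permutations when exhaustively enumerable."""
    if math.factorial(N) <= EXHAUSTIVE_LIMIT:
        perms = np.array(list(iter_permutations(range(N))), dtype=int)
        exhaustive = True
    else:
        perms = np.argsort(rng.random((n_permutations, N)), axis=1)
        exhaustive = False
    masks = np.zeros((perms.shape[0], N), dtype=bool)
    rows = np.arange(perms.shape[0])[:, None]
    masks[rows, perms[:, :n]] = True
    return masks, exhaustive


def segregation_index(
    X: np.ndarray,
    Y: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
    permutations: np.ndarray | None = None,
) -> SegregationResult:
    """Permutation-normalized segregation index of group X against group Y.

    ``permutations`` optionally supplies explicit index permutations
    (P, n+m) in place of random draws (e.g. to share draws with an
    independent oracle). Deterministic for a fixed seed.
    """
    X, Y = _check_groups(X, Y)
    n, m = X.shape[0], Y.shape[0]
    N = n + m
    D = squareform(pdist(np.vstack([X, Y])))

    if permutations is not None:
        perms = np.asarray(permutations, dtype=int)
        masks = np.zeros((perms.shape[0], N), dtype=bool)
        masks[np.arange(perms.shape[0])[:, None], perms[:, :n]] = True
        exhaustive = False
    else:
        masks, exhaustive = _permutation_masks(
            N, n, n_permutations, np.random.default_rng(seed)
        )

    num = si_numerator(X, Y)
    den = float(_denominator_terms(D, n, m, masks).mean())
    if den <= 0:
        raise ValueError("degenerate point set: permutation denominator is zero")
    return SegregationResult(
        si=num / den,
        numerator=num,
        denominator=den,
        n_permutations=masks.shape[0],
        seed=seed,
        exhaustive=exhaustive,
    )


def pooled_segregation_index(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    n_permutations: int = 1000,
    seed: int = 0,
) -> SegregationResult:
    """SI across FOVs: mean of per-FOV numerators over mean of per-FOV
    denominators."""
    if not pairs:
        raise ValueError("no FOVs supplied")
    nums, dens = [], []
    for k, (X, Y) in enumerate(pairs):
        r = segregation_index(X, Y, n_permutations=n_permutations, seed=seed + k)
        nums.append(r.numerator)
        dens.append(r.denominator)
    num, den = float(np.mean(nums)), float(np.mean(dens))
    return SegregationResult(
        si=num / den,
        numerator=num,
        denominator=den,
        n_permutations=n_permutations,
        seed=seed,
        exhaustive=False,
    )


# --------------------------------------------------------- relative positions


def relative_positions(
    points: "pd.DataFrame",
    reference_label: str,
) -> "pd.DataFrame":
    """Re-reference positions to the per-FOV centroid of reference-labelled
    points (columns fov_id, x_um, y_um, z_um, label). FOVs lacking the
    reference label are dropped with a warning."""
    import pandas as pd

    out = []
    for fov, grp in points.groupby("fov_id"):
        ref = grp[grp["label"] == reference_label]
        if ref.empty:
            logger.warning("FOV %s lacks reference label %r; dropped", fov, reference_label)
            continue
        centred = grp.copy()
        for col in ("x_um", "y_um", "z_um"):
            if col in grp.columns:
                centred[col] = grp[col] - ref[col].mean()
        out.append(centred)
    if not out:
        return points.iloc[0:0].copy()
    return pd.concat(out, ignore_index=True)


# ------------------------------------------------------ distance shuffle test


def pairwise_distance_shuffle_test(
    positions: np.ndarray,
    labels: np.ndarray,
    fov_ids: np.ndarray | None = None,
    n_shuffles: int = 100,
    seed: int = 0,
) -> dict:
    """Observed vs label-shuffled within/cross pairwise distance distributions.

    Labels are reassigned at random within each FOV, preserving the observed
    per-FOV label frequencies — controlling for regional variation in point
    density. Returns pooled distance arrays; single-label FOVs contribute
    only the distances that exist (a FOV with one group empty is skipped for
    cross distances with a warning).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    labels = np.asarray(labels)
    if fov_ids is None:
        fov_ids = np.zeros(len(labels), dtype=int)
    fov_ids = np.asarray(fov_ids)
    rng = np.random.default_rng(seed)

    def _collect(lbls: np.ndarray) -> tuple[list, list]:
        within, cross = [], []
        for fov in np.unique(fov_ids):
            sel = fov_ids == fov
            pos, lab = positions[sel], lbls[sel]
            groups = np.unique(lab)
            if len(groups) < 2:
                logger.warning("FOV %s has a single label group; no cross distances", fov)
            for g in groups:
                pts = pos[lab == g]
                if len(pts) >= 2:
                    within.append(pdist(pts))
            for i, g in enumerate(groups):
                for h in groups[i + 1 :]:
                    a, b = pos[lab == g], pos[lab == h]
                    if len(a) and len(b):
                        cross.append(cdist(a, b).ravel())
        cat = lambda parts: np.concatenate(parts) if parts else np.empty(0)
        return cat(within), cat(cross)

    within_obs, cross_obs = _collect(labels)
    within_sh, cross_sh = [], []
    for _ in range(n_shuffles):
        shuffled = labels.copy()
        for fov in np.unique(fov_ids):
            sel = np.flatnonzero(fov_ids == fov)
            shuffled[sel] = shuffled[sel][rng.permutation(len(sel))]
        w, c = _collect(shuffled)
        within_sh.append(w)
        cross_sh.append(c)
    return {
        "within_observed": within_obs,
        "cross_observed": cross_obs,
        "within_shuffled": np.concatenate(within_sh) if within_sh else np.empty(0),
        "cross_shuffled": np.concatenate(cross_sh) if cross_sh else np.empty(0),
        "n_shuffles": n_shuffles,
        "seed": seed,
    }


def bouton_neuron_segregation(
    neuron_positions: np.ndarray,
    bouton_positions: np.ndarray,
    n_shuffles: int = 100,
    seed: int = 0,
) -> dict:
    """Same-structure (neuron-neuron, bouton-bouton) vs cross-structure
    (neuron-bouton) distance comparison, with structure-label shuffling."""
    neuron_positions = np.atleast_2d(np.asarray(neuron_positions, dtype=float))
    bouton_positions = np.atleast_2d(np.asarray(bouton_positions, dtype=float))
    if len(neuron_positions) < 2 or len(bouton_positions) < 2:
        raise ValueError("need >= 2 neurons and >= 2 boutons")
    positions = np.vstack([neuron_positions, bouton_positions])
    labels = np.array(
        ["neuron"] * len(neuron_positions) + ["bouton"] * len(bouton_positions)
    )
    return pairwise_distance_shuffle_test(
        positions, labels, n_shuffles=n_shuffles, seed=seed
    )


# ------------------------------------------------------------------ densities


def enrichment_index(p_cre_pos: float, p_cre_neg: float) -> float | None:
    """(P+ - P-) / (P+ + P-); None when both response fractions are zero."""
    if p_cre_pos < 0 or p_cre_neg < 0:
        raise ValueError("response fractions must be non-negative")
    total = p_cre_pos + p_cre_neg
    if total == 0:
        logger.warning("both response fractions zero; enrichment undefined")
        return None
    return (p_cre_pos - p_cre_neg) / total


def density_map(
    points: np.ndarray,
    bandwidth_um: float = 15.0,
    extent: tuple[float, float, float, float] | None = None,
    grid_n: int = 64,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian kernel density raster of 2D points, normalized to integrate
    to 1 over the grid. Returns (x_centers, y_centers, density[y, x])."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 0:
        raise ValueError("no points supplied")
    if extent is None:
        pad = 3 * bandwidth_um
        extent = (
            points[:, 0].min() - pad,
            points[:, 0].max() + pad,
            points[:, 1].min() - pad,
            points[:, 1].max() + pad,
        )
    x = np.linspace(extent[0], extent[1], grid_n)
    y = np.linspace(extent[2], extent[3], grid_n)
    xx, yy = np.meshgrid(x, y)
    h2 = 2 * bandwidth_um**2
    dens = np.zeros_like(xx)
    for px, py in points[:, :2]:
        dens += np.exp(-((xx - px) ** 2 + (yy - py) ** 2) / h2)
    cell = (x[1] - x[0]) * (y[1] - y[0])
    dens /= dens.sum() * cell
    return x, y, dens


def detect_boutons(
    image: np.ndarray,
    edge_low: float = 0.1,
    edge_high: float = 0.3,
    min_area: int = 4,
    sigma: float = 1.0,
) -> np.ndarray:
    """Centroids of closed bright regions: Canny edges, hole filling,
    connected components, area filter. Returns (k, 2) array of (row, col)."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    edges = canny(image, sigma=sigma, low_threshold=edge_low, high_threshold=edge_high)
    filled = ndimage.binary_fill_holes(edges)
    labelled, n_comp = ndimage.label(filled)
    centroids = []
    for comp in range(1, n_comp + 1):
        pix = np.argwhere(labelled == comp)
        if len(pix) >= min_area:
            centroids.append(pix.mean(axis=0))
    return np.array(centroids) if centroids else np.empty((0, 2))
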