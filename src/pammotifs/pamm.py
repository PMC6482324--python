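"""Probabilistic mode clustering of feature distributions (PAMM).

The pipeline converts a cloud of descriptor vectors into a Gaussian
mixture whose components are the recurrent "motifs" of the data:

1. :func:`fps_select` picks a sparse, approximately uniform grid of
   sample points by farthest-point sampling.
2. :func:`estimate_density` runs an adaptive kernel density estimate on
   the grid: each grid point's kernel covariance comes from the sample
   covariance of its nearest fraction of the data, shrunk by a global
   ``bandwidth_scale``.
3. :func:`quick_shift` links every grid point to its nearest
   higher-density neighbour within a local length scale; link roots are
   density modes and the link forest partitions the grid into clusters.
4. :func:`build_mixture` turns each cluster into one Gaussian mode
   (weight from Voronoi sample counts, moments from density-weighted
   grid statistics) and prunes negligible clusters.

The resulting :class:`ClusterModel` evaluates probabilistic motif
identifiers (PMIs): the posterior-like score that a point belongs to
mode ``k``, regularised by a small background ``zeta`` so that scores
decay to zero far from every mode.

Angular features are supported throughout via per-dimension periods and
minimum-image (nearest periodic copy) displacements; this is exact for
kernels much narrower than the period, which holds for every use here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import solve_triangular

logger = logging.getLogger(__name__)

_MODEL_FORMAT = "pammotifs-model 1"


# ---------------------------------------------------------------------------
# feature container and periodic helpers


@dataclass
class FeatureMatrix:
    """Sample vectors plus per-dimension periodicity metadata.

    ``periodicity[i]`` is the period of dimension ``i`` (e.g. 360 for an
    angle in degrees) or NaN for an aperiodic dimension.  Periodic
    coordinates are stored wrapped into ``[-period/2, period/2)``.
    """

    vectors: np.ndarray
    periodicity: np.ndarray | None = None
    dim_names: list[str] | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.vectors, dtype=float)
        if X.ndim != 2:
            raise ValueError("vectors must be a 2D array")
        if not np.all(np.isfinite(X)):
            raise ValueError("vectors contain non-finite entries")
        d = X.shape[1]
        if self.periodicity is None:
            periods = np.full(d, np.nan)
        else:
            periods = np.asarray(self.periodicity, dtype=float)
            if periods.shape != (d,):
                raise ValueError("periodicity must have one entry per dimension")
        mask = np.isfinite(periods)
        if mask.any():
            p = periods[mask]
            X = X.copy()
            X[:, mask] = (X[:, mask] + p / 2) % p - p / 2
        self.vectors = X
        self.periodicity = periods
        if self.dim_names is not None and len(self.dim_names) != d:
            raise ValueError("dim_names length mismatch")

    @property
    def n_samples(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_dims(self) -> int:
        return self.vectors.shape[1]


def min_image(delta: np.ndarray, periodicity: np.ndarray | None) -> np.ndarray:
    """Wrap displacement(s) to the nearest periodic image per dimension."""
    if periodicity is None:
        return delta
    mask = np.isfinite(periodicity)
    if not mask.any():
        return delta
    delta = np.array(delta, dtype=float, copy=True)
    p = periodicity[mask]
    delta[..., mask] = (delta[..., mask] + p / 2) % p - p / 2
    return delta


def _sq_dists(points: np.ndarray, x: np.ndarray, periodicity) -> np.ndarray:
    d = min_image(points - x, periodicity)
    return np.einsum("ij,ij->i", d, d)


# ---------------------------------------------------------------------------
# farthest-point sampling


def fps_select(
    features: FeatureMatrix | np.ndarray,
    n_grid: int,
    seed: int,
    periodicity: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy farthest-point selection of ``n_grid`` sample indices.

    The first point is drawn with the seeded generator; every later pick
    maximises the minimum (periodic-aware) distance to the points chosen
    so far.  Ties break toward the lowest index, so the result is fully
    determined by the data and the seed.
    """
    if isinstance(features, FeatureMatrix):
        X = features.vectors
        periodicity = features.periodicity
    else:
        X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if n_grid > n:
        raise ValueError(f"n_grid={n_grid} exceeds n_samples={n}")
    if n_grid == n:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    selected = np.empty(n_grid, dtype=np.intp)
    selected[0] = rng.integers(n)
    min_sq = _sq_dists(X, X[selected[0]], periodicity)
    for i in range(1, n_grid):
        nxt = int(np.argmax(min_sq))  # argmax takes the lowest index on ties
        selected[i] = nxt
        np.minimum(min_sq, _sq_dists(X, X[nxt], periodicity), out=min_sq)
    return selected


# ---------------------------------------------------------------------------
# adaptive kernel density estimation on the grid


@dataclass
class Grid:
    """The sparse KDE grid: positions, local kernels, densities, weights."""

    positions: np.ndarray  # (g, d)
    bandwidths: np.ndarray  # (g, d, d) kernel covariances, SPD
    local_scales: np.ndarray  # (g,) linking length: geo-mean std of the
    # unscaled local covariance
    densities: np.ndarray  # (g,)
    voronoi_weights: np.ndarray  # (g,) fraction of samples nearest to each point
    periodicity: np.ndarray | None = None

    @property
    def n_grid(self) -> int:
        return self.positions.shape[0]

    @property
    def n_dims(self) -> int:
        return self.positions.shape[1]


def _gauss_logpdf(delta: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log N(delta; 0, cov) for rows of delta."""
    d = cov.shape[0]
    chol = np.linalg.cholesky(cov)
    z = solve_triangular(chol, delta.T, lower=True, check_finite=False)
    maha = np.einsum("ij,ij->j", z, z)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * np.log(2 * np.pi) + logdet + maha)


def _regularize(cov: np.ndarray) -> np.ndarray:
    """Make a covariance safely positive definite (tiny ridge)."""
    d = cov.shape[0]
    tr = np.trace(cov)
    eps = 1e-8 * (tr / d if tr > 0 else 1.0)
    cov = cov + eps * np.eye(d)
    # escalate the ridge until Cholesky succeeds
    for _ in range(12):
        try:
            np.linalg.cholesky(cov)
            return cov
        except np.linalg.LinAlgError:
            eps *= 100.0
            cov = cov + eps * np.eye(d)
    raise np.linalg.LinAlgError("covariance could not be regularized")


def estimate_density(
    features: FeatureMatrix,
    grid_indices: np.ndarray,
    bandwidth_scale: float,
    f_loc: float = 0.15,
) -> Grid:
    """Adaptive KDE of the sample density at the grid points.

    For each grid point the kernel covariance is the (periodic-aware)
    sample covariance of the nearest ``f_loc`` fraction of the data,
    multiplied by ``bandwidth_scale**2``.  The density is a
    sample-smoothing adaptive KDE: every sample contributes a Gaussian
    kernel with the bandwidth of the grid cell it falls in (its nearest
    grid point), and this one fixed density function is evaluated at
    all grid points — so sparse outlying grid points sit on the true
    low tail instead of acquiring inflated balloon estimates.  Each
    grid point also records its Voronoi weight — the fraction of
    samples for which it is the nearest grid point — and a linking
    length used by quick-shift (geometric-mean standard deviation of
    the *unscaled* local covariance, so the mode-seeking length is not
    tied to the KDE shrink factor).
    """
    if bandwidth_scale <= 0:
        raise ValueError("bandwidth_scale must be positive")
    X = features.vectors
    periods = features.periodicity
    n, d = X.shape
    spans = X.max(axis=0) - X.min(axis=0)
    degenerate = np.where(spans == 0)[0]
    if degenerate.size:
        names = (
            [features.dim_names[i] for i in degenerate]
            if features.dim_names
            else list(degenerate)
        )
        raise ValueError(f"zero-variance dimension(s): {names}")

    grid_indices = np.asarray(grid_indices, dtype=np.intp)
    G = grid_indices.shape[0]
    positions = X[grid_indices]
    k_loc = max(int(round(f_loc * n)), d + 2)
    k_loc = min(k_loc, n)

    bandwidths = np.empty((G, d, d))
    local_scales = np.empty(G)

    # local covariances and Voronoi assignment in one pass over the grid
    nearest_sq = np.full(n, np.inf)
    nearest_grid = np.zeros(n, dtype=np.intp)
    for gi in range(G):
        delta = min_image(X - positions[gi], periods)  # (n, d)
        sq = np.einsum("ij,ij->i", delta, delta)
        closer = sq < nearest_sq
        nearest_sq[closer] = sq[closer]
        nearest_grid[closer] = gi
        near = np.argpartition(sq, k_loc - 1)[:k_loc]
        local = delta[near]
        mu = local.mean(axis=0)
        centered = local - mu
        cov = centered.T @ centered / local.shape[0]
        cov = _regularize(cov)
        sign, logdet = np.linalg.slogdet(cov)
        local_scales[gi] = np.exp(logdet / (2 * d))
        bandwidths[gi] = _regularize(cov * bandwidth_scale**2)

    counts = np.bincount(nearest_grid, minlength=G)
    voronoi = counts / n

    # sample-smoothing density: each sample smeared with its cell's kernel
    densities = np.zeros(G)
    order = np.argsort(nearest_grid, kind="stable")
    boundaries = np.searchsorted(nearest_grid[order], np.arange(G + 1))
    for gi in range(G):
        members = order[boundaries[gi] : boundaries[gi + 1]]
        if members.size == 0:
            continue
        cell = X[members]
        delta = positions[:, None, :] - cell[None, :, :]  # (G, n_g, d)
        delta = min_image(delta, periods)
        logk = _gauss_logpdf(delta.reshape(-1, d), bandwidths[gi]).reshape(
            G, members.size
        )
        densities += np.exp(logk).sum(axis=1) / n

    return Grid(
        positions=positions,
        bandwidths=bandwidths,
        local_scales=local_scales,
        densities=densities,
        voronoi_weights=voronoi,
        periodicity=periods,
    )


# ---------------------------------------------------------------------------
# quick-shift mode seeking


def quick_shift(grid: Grid, qs_scale: float = 1.0) -> np.ndarray:
    """Partition the grid by quick-shift.

    Every grid point links to the *nearest* grid point of strictly
    higher density within ``qs_scale * local_scale``; points with no
    such neighbour are modes.  Following links to their roots yields one
    cluster per mode.  Returns a cluster label per grid point, labels
    ordered by the root's grid index (deterministic).

    The link length is floored at twice the distance to the fourth-
    nearest grid point: the sparse grid cannot support density
    comparisons below its own resolution, and without the floor every
    small group of grid points in a sparsely covered tail would become
    its own spurious mode.  Structure below a few grid spacings is
    unresolvable either way.
    """
    if qs_scale <= 0:
        raise ValueError("qs_scale must be positive")
    pos = grid.positions
    rho = grid.densities
    G = pos.shape[0]
    k_floor = min(4, G - 1)
    parent = np.arange(G)
    for i in range(G):
        delta = min_image(pos - pos[i], grid.periodicity)
        sq = np.einsum("ij,ij->i", delta, delta)
        sq[i] = np.inf
        kth_sq = np.partition(sq, k_floor - 1)[k_floor - 1]
        link = max((qs_scale * grid.local_scales[i]) ** 2, 4.0 * kth_sq)
        eligible = rho > rho[i]
        eligible &= sq <= link
        if eligible.any():
            cand = np.where(eligible)[0]
            parent[i] = cand[np.argmin(sq[cand])]  # nearest; ties → lowest index
    # path-follow to roots (links strictly increase density, so no cycles)
    roots = parent.copy()
    changed = True
    while changed:
        new = parent[roots]
        changed = bool(np.any(new != roots))
        roots = new
    unique_roots = np.unique(roots)
    label_of_root = {int(r): i for i, r in enumerate(unique_roots)}
    return np.array([label_of_root[int(r)] for r in roots], dtype=np.intp)


def merge_shallow_clusters(
    grid: Grid, assignment: np.ndarray, merge_ratio: float = 0.8
) -> np.ndarray:
    """Merge cluster pairs separated by an insignificant density dip.

    A finite-sample KDE is noisy, so quick-shift can split one true
    mode into several micro-modes separated by shallow wiggles.  For
    every pair of adjacent clusters (grid points within twice their
    nearest-grid-neighbour distances) the saddle density is the highest
    min-density over border pairs; when it exceeds ``merge_ratio``
    times the lower of the two mode densities, the dip is judged not a
    real valley and the clusters merge (into the denser mode's
    cluster).  Repeats until stable; deterministic.  ``merge_ratio=0``
    disables merging.
    """
    if not 0.0 <= merge_ratio < 1.0:
        raise ValueError("merge_ratio must be in [0, 1)")
    labels = np.asarray(assignment).copy()
    if merge_ratio == 0.0:
        return labels
    pos = grid.positions
    rho = grid.densities
    G = pos.shape[0]
    # pairwise distances once (grid is small by construction)
    diff = pos[:, None, :] - pos[None, :, :]
    diff = min_image(diff, grid.periodicity)
    dist = np.sqrt(np.einsum("ijd,ijd->ij", diff, diff))
    np.fill_diagonal(dist, np.inf)
    k_near = min(4, G - 1)
    nn = np.partition(dist, k_near - 1, axis=1)[:, k_near - 1]
    border = dist <= 2.0 * np.maximum(nn[:, None], nn[None, :])

    while True:
        labs = np.unique(labels)
        if labs.size < 2:
            break
        mode_rho = {int(l): rho[labels == l].max() for l in labs}
        best = None  # (saddle, -ratio tiebreak fields), pair
        for ai in range(labs.size):
            for bi in range(ai + 1, labs.size):
                a, b = int(labs[ai]), int(labs[bi])
                mask = border[np.ix_(labels == a, labels == b)]
                if not mask.any():
                    continue
                ra = rho[labels == a][:, None]
                rb = rho[labels == b][None, :]
                saddle = float(np.where(mask, np.minimum(ra, rb), -np.inf).max())
                floor = merge_ratio * min(mode_rho[a], mode_rho[b])
                if saddle >= floor and (best is None or saddle > best[0]):
                    best = (saddle, a, b)
        if best is None:
            break
        _, a, b = best
        keep, drop = (a, b) if mode_rho[a] >= mode_rho[b] else (b, a)
        labels[labels == drop] = keep
    # relabel compactly, ordered by first occurrence of the root index
    labs = np.unique(labels)
    remap = {int(l): i for i, l in enumerate(labs)}
    return np.array([remap[int(l)] for l in labels], dtype=np.intp)


# ---------------------------------------------------------------------------
# Gaussian mixture construction and the cluster model


@dataclass
class GaussianMode:
    """One mixture component: weight, mean and covariance."""

    weight: float
    mean: np.ndarray
    covariance: np.ndarray


@dataclass
class ClusterModel:
    """Gaussian mixture over feature space plus the PMI background.

    ``zeta`` is the background probability added to the mixture
    denominator so that motif scores decay to zero far from all modes.
    """

    modes: list[GaussianMode]
    zeta: float = 1e-5
    periodicity: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    @property
    def n_dims(self) -> int:
        return self.modes[0].mean.shape[0]

    def _component_logpdfs(self, x: np.ndarray) -> np.ndarray:
        """log(p_k G_k(x)) for each mode; x is (n, d)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        out = np.empty((self.n_modes, x.shape[0]))
        for k, mode in enumerate(self.modes):
            delta = min_image(x - mode.mean, self.periodicity)
            out[k] = np.log(mode.weight) + _gauss_logpdf(delta, mode.covariance)
        return out

    def pdf(self, x: np.ndarray) -> np.ndarray:
        """Mixture density P(x) = sum_k p_k G(x | mu_k, Sigma_k)."""
        lp = self._component_logpdfs(x)
        m = lp.max(axis=0)
        return np.exp(m) * np.exp(lp - m).sum(axis=0)

    def responsibilities(self, x: np.ndarray, zeta: float | None = None) -> np.ndarray:
        """PMI of every mode at x: rows k, columns samples.

        With ``zeta=0`` the rows sum to one (posterior responsibilities);
        with ``zeta>0`` scores are damped in low-density regions.
        """
        z = self.zeta if zeta is None else zeta
        lp = self._component_logpdfs(x)
        m = lp.max(axis=0)
        with np.errstate(over="ignore", under="ignore"):
            denom = np.exp(lp - m).sum(axis=0) + z * np.exp(-m)
            out = np.exp(lp - m) / denom
        return np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)

    def pmi(self, k: int, x: np.ndarray, zeta: float | None = None) -> np.ndarray:
        """Probabilistic motif identifier of mode ``k`` at point(s) x."""
        return self.responsibilities(x, zeta=zeta)[k]

    # -- text persistence ---------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the model as plain text; round-trips bit-exactly."""
        lines = [f"# {_MODEL_FORMAT}"]
        lines.append(f"# zeta {self.zeta!r}")
        if self.periodicity is None:
            lines.append("# periodicity none")
        else:
            lines.append(
                "# periodicity " + " ".join(repr(float(p)) for p in self.periodicity)
            )
        for key in sorted(self.provenance):
            lines.append(f"# param {key}={self.provenance[key]}")
        lines.append(f"# dims {self.n_dims} modes {self.n_modes}")
        for mode in self.modes:
            nums = [mode.weight, *mode.mean.ravel(), *mode.covariance.ravel()]
            lines.append(" ".join(repr(float(v)) for v in nums))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ClusterModel":
        text = Path(path).read_text().splitlines()
        if not text or text[0] != f"# {_MODEL_FORMAT}":
            raise ValueError(f"{path}: not a {_MODEL_FORMAT} file")
        zeta = 0.0
        periodicity: np.ndarray | None = None
        provenance: dict = {}
        dims = modes_n = None
        body: list[str] = []
        for line in text[1:]:
            if line.startswith("# zeta "):
                zeta = float(line.split()[2])
            elif line.startswith("# periodicity "):
                rest = line.split()[2:]
                periodicity = (
                    None if rest == ["none"] else np.array([float(v) for v in rest])
                )
            elif line.startswith("# param "):
                key, _, value = line[len("# param ") :].partition("=")
                provenance[key] = value
            elif line.startswith("# dims "):
                parts = line.split()
                dims, modes_n = int(parts[2]), int(parts[4])
            elif line.startswith("#"):
                continue
            elif line.strip():
                body.append(line)
        if dims is None or len(body) != modes_n:
            raise ValueError(f"{path}: malformed model file")
        modes = []
        for line in body:
            vals = np.array([float(v) for v in line.split()])
            weight = float(vals[0])
            mean = vals[1 : 1 + dims]
            cov = vals[1 + dims :].reshape(dims, dims)
            modes.append(GaussianMode(weight=weight, mean=mean, covariance=cov))
        return cls(modes=modes, zeta=zeta, periodicity=periodicity, provenance=provenance)


def build_mixture(
    grid: Grid,
    assignment: np.ndarray,
    prune_threshold: float = 1e-5,
    zeta: float = 1e-5,
    provenance: dict | None = None,
) -> ClusterModel:
    """Collapse each quick-shift cluster into one Gaussian mode.

    Mode weight is the summed Voronoi weight of the member grid points;
    mean and covariance are density-weighted moments of the member grid
    positions (computed in minimum-image displacements from the densest
    member, so periodic clusters average correctly).  Clusters below
    ``prune_threshold`` are dropped and the remaining weights
    renormalised to one.
    """
    assignment = np.asarray(assignment)
    labels = np.unique(assignment)
    modes: list[GaussianMode] = []
    d = grid.n_dims
    for lab in labels:
        members = np.where(assignment == lab)[0]
        weight = float(grid.voronoi_weights[members].sum())
        rho = grid.densities[members]
        ref = grid.positions[members[np.argmax(rho)]]
        disp = min_image(grid.positions[members] - ref, grid.periodicity)
        wsum = rho.sum()
        if wsum <= 0:
            rho = np.ones_like(rho)
            wsum = rho.sum()
        mu_disp = (rho[:, None] * disp).sum(axis=0) / wsum
        centered = disp - mu_disp
        cov = (rho[:, None, None] * centered[:, :, None] * centered[:, None, :]).sum(
            axis=0
        ) / wsum
        if members.size < d + 1:
            logger.warning(
                "cluster %d has %d grid points (< dims+1); covariance regularized",
                int(lab),
                members.size,
            )
        cov = _regularize(cov)
        mean = ref + mu_disp
        if grid.periodicity is not None:
            mask = np.isfinite(grid.periodicity)
            if mask.any():
                p = grid.periodicity[mask]
                mean = mean.copy()
                mean[mask] = (mean[mask] + p / 2) % p - p / 2
        modes.append(GaussianMode(weight=weight, mean=mean, covariance=cov))

    survivors = [m for m in modes if m.weight >= prune_threshold]
    if not survivors:
        raise ValueError("all clusters fell below the prune threshold")
    pruned = len(modes) - len(survivors)
    if pruned:
        logger.info("pruned %d cluster(s) below weight %g", pruned, prune_threshold)
    total = sum(m.weight for m in survivors)
    for m in survivors:
        m.weight /= total
    return ClusterModel(
        modes=survivors,
        zeta=zeta,
        periodicity=grid.periodicity,
        provenance=provenance or {},
    )


# ---------------------------------------------------------------------------
# one-call driver


def fit_pamm(
    features: FeatureMatrix,
    n_grid: int = 2000,
    bandwidth_scale: float = 0.3,
    qs_scale: float = 1.0,
    prune_threshold: float = 1e-5,
    zeta: float = 1e-5,
    seed: int = 0,
    f_loc: float = 0.15,
    merge_ratio: float = 0.8,
    max_samples: int | None = None,
) -> ClusterModel:
    """Full pipeline: FPS grid, adaptive KDE, quick-shift with shallow-
    cluster merging, mixture construction.

    ``max_samples`` caps the dataset by seeded uniform subsampling for
    desk-scale runs (logged when applied).
    """
    if max_samples is not None and features.n_samples > max_samples:
        rng = np.random.default_rng(seed)
        idx = rng.choice(features.n_samples, size=max_samples, replace=False)
        idx.sort()
        logger.info("subsampled %d of %d samples", max_samples, features.n_samples)
        features = FeatureMatrix(
            features.vectors[idx], features.periodicity, features.dim_names
        )
    n_grid = min(n_grid, features.n_samples)
    grid_idx = fps_select(features, n_grid, seed)
    grid = estimate_density(features, grid_idx, bandwidth_scale, f_loc=f_loc)
    assignment = quick_shift(grid, qs_scale)
    assignment = merge_shallow_clusters(grid, assignment, merge_ratio)
    provenance = {
        "n_grid": n_grid,
        "bandwidth_scale": bandwidth_scale,
        "qs_scale": qs_scale,
        "prune_threshold": prune_threshold,
        "f_loc": f_loc,
        "merge_ratio": merge_ratio,
        "seed": seed,
        "n_samples": features.n_samples,
    }
    return build_mixture(
        grid, assignment, prune_threshold, zeta=zeta, provenance=provenance
    )


def grid_kde(
    features: FeatureMatrix,
    n_grid: int = 2000,
    bandwidth_scale: float = 1.0,
    seed: int = 0,
    f_loc: float = 0.15,
) -> ClusterModel:
    """Compress a sample cloud into an evaluable density model.

    Every grid point becomes one Gaussian with its Voronoi weight and
    kernel covariance, giving a normalised density evaluable anywhere
    (used e.g. for the conditional densities of the energy-based
    hydrogen-bond score).
    """
    n_grid = min(n_grid, features.n_samples)
    grid_idx = fps_select(features, n_grid, seed)
    grid = estimate_density(features, grid_idx, bandwidth_scale, f_loc=f_loc)
    modes = [
        GaussianMode(
            weight=max(float(w), 1e-300), mean=pos.copy(), covariance=H.copy()
        )
        for w, pos, H in zip(grid.voronoi_weights, grid.positions, grid.bandwidths)
    ]
    total = sum(m.weight for m in modes)
    for m in modes:
        m.weight /= total
    return ClusterModel(modes=modes, zeta=0.0, periodicity=grid.periodicity)
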