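"""Hydrogen-bond motif identifiers and their agreement score.

Three families of scores, all mapping a geometry to [0, 1]:

* the mode-clustering PMI — posterior-like score of the mixture mode
  nearest a reference hydrogen-bond geometry;
* a classic sharp distance–angle criterion (indicator function);
* an energy-based score built from the Kabsch–Sander electrostatic
  energy: the joint density of (d_AH, d_DA) conditioned on the energy
  being below -0.5 kcal/mol, normalised by the total density.

The delta agreement score between two identifiers A and B is the
probability, under the empirical geometry distribution, that both flag
a point as hydrogen bonded relative to the probability that either
does, normalised so that identical identifiers score exactly one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .hbonds import DsspQuadruplet, KS_HB_THRESHOLD, quadruplet_to_features
from .pamm import ClusterModel, FeatureMatrix, grid_kde

logger = logging.getLogger(__name__)

#: reference (d_AH, d_DA) of a canonical hydrogen bond, Angstrom
HB_REFERENCE_POINT = (1.82, 2.74)

#: sharp criterion thresholds: d_DA, d_AH, d_DH (Angstrom), angle (degrees)
DA_THRESHOLDS = {"d_DA": 3.5, "d_AH": 2.5, "d_DH": 1.5, "angle_ADH": 30.0}


@dataclass
class PmiFunction:
    """A named motif identifier: evaluates a triplet table to scores.

    ``evaluator`` maps a DataFrame carrying the geometric columns the
    identifier needs (always d_AH and d_DA; the distance-angle kind
    additionally d_DH and angle_ADH) to scores in [0, 1].
    """

    kind: str  # {"pamm", "distance_angle", "dssp_energy"}
    evaluator: Callable[[pd.DataFrame], np.ndarray]
    zeta: float = 0.0

    def __call__(self, samples: pd.DataFrame) -> np.ndarray:
        scores = np.asarray(self.evaluator(samples), dtype=float)
        if scores.size and (scores.min() < -1e-12 or scores.max() > 1 + 1e-12):
            raise ValueError(f"{self.kind} PMI produced scores outside [0, 1]")
        return np.clip(scores, 0.0, 1.0)


def distance_angle_pmi(
    d_DA: np.ndarray | float,
    d_AH: np.ndarray | float,
    d_DH: np.ndarray | float,
    angle_ADH: np.ndarray | float,
) -> np.ndarray | float:
    """Sharp geometric criterion: 1 iff all four thresholds hold strictly."""
    out = (
        (np.asarray(d_DA) < DA_THRESHOLDS["d_DA"])
        & (np.asarray(d_AH) < DA_THRESHOLDS["d_AH"])
        & (np.asarray(d_DH) < DA_THRESHOLDS["d_DH"])
        & (np.asarray(angle_ADH) < DA_THRESHOLDS["angle_ADH"])
    )
    return out.astype(float) if isinstance(out, np.ndarray) else float(out)


def make_distance_angle_pmi() -> PmiFunction:
    def _eval(df: pd.DataFrame) -> np.ndarray:
        return np.asarray(
            distance_angle_pmi(
                df["d_DA"].to_numpy(),
                df["d_AH"].to_numpy(),
                df["d_DH"].to_numpy(),
                df["angle_ADH"].to_numpy(),
            )
        )

    return PmiFunction(kind="distance_angle", evaluator=_eval)


def identify_hb_mode(
    model: ClusterModel, reference: tuple[float, float] = HB_REFERENCE_POINT
) -> int:
    """Index of the mode whose mean is nearest the reference geometry.

    Feature order is (d_AH, d_DA).  Ties go to the lowest index (logged).
    """
    if model.n_modes == 0:
        raise ValueError("model has no modes")
    ref = np.asarray(reference, dtype=float)
    dists = np.array([np.linalg.norm(m.mean - ref) for m in model.modes])
    best = int(np.argmin(dists))
    if np.sum(np.isclose(dists, dists[best])) > 1:
        logger.info("hydrogen-bond mode tie; choosing lowest index %d", best)
    return best


def make_pamm_pmi(
    model: ClusterModel, mode_index: int | None = None, zeta: float | None = None
) -> PmiFunction:
    """PMI of the hydrogen-bond mode of a fitted 2D (d_AH, d_DA) model."""
    if mode_index is None:
        mode_index = identify_hb_mode(model)
    z = model.zeta if zeta is None else zeta

    def _eval(df: pd.DataFrame) -> np.ndarray:
        x = df[["d_AH", "d_DA"]].to_numpy(dtype=float)
        return model.pmi(mode_index, x, zeta=z)

    return PmiFunction(kind="pamm", evaluator=_eval, zeta=z)


# ---------------------------------------------------------------------------
# energy-based identifier


@dataclass
class DsspPmiModel:
    """Energy-conditioned density model over (d_AH, d_DA).

    ``hb_weight`` is the fraction of backbone (C=O, N-H) pairs with
    Kabsch–Sander energy below -0.5 kcal/mol; the two conditional
    densities are kernel density models over the bonded and non-bonded
    populations.
    """

    hb_weight: float
    hb_density: ClusterModel
    non_hb_density: ClusterModel
    zeta: float = 1e-5

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Score p_HB P_HB(x) / (p_HB P_HB(x) + (1-p_HB) P_non(x) + zeta)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        num = self.hb_weight * self.hb_density.pdf(x)
        total = num + (1.0 - self.hb_weight) * self.non_hb_density.pdf(x)
        return num / (total + self.zeta)


def dssp_features_from_quads(
    quads: list[DsspQuadruplet],
) -> tuple[np.ndarray, np.ndarray]:
    """(n, 2) array of (d_AH, d_DA) plus the energies, from quadruplets."""
    feats = np.array([quadruplet_to_features(q) for q in quads], dtype=float)
    energies = np.array([q.energy for q in quads], dtype=float)
    return feats, energies


def fit_dssp_pmi(
    features: np.ndarray,
    energies: np.ndarray,
    zeta: float = 1e-5,
    n_grid: int = 2000,
    bandwidth_scale: float = 0.3,
    seed: int = 0,
) -> DsspPmiModel:
    """Fit the energy-based identifier from (d_AH, d_DA) features.

    ``hb_weight`` is the fraction with energy < -0.5 kcal/mol; the two
    conditional densities use the same sparse-grid adaptive KDE as the
    mode clustering.  Refuses to fit when no pair is hydrogen bonded
    (the score would be identically zero).
    """
    features = np.asarray(features, dtype=float)
    energies = np.asarray(energies, dtype=float)
    if features.shape[0] != energies.shape[0]:
        raise ValueError("features and energies length mismatch")
    positive = energies < KS_HB_THRESHOLD
    n_pos = int(positive.sum())
    if n_pos == 0:
        raise ValueError(
            "no pairs below the -0.5 kcal/mol threshold; refusing to fit a "
            "hydrogen-bond score that would be identically zero"
        )
    p_hb = n_pos / features.shape[0]
    hb_density = grid_kde(
        FeatureMatrix(features[positive]),
        n_grid=min(n_grid, n_pos),
        bandwidth_scale=bandwidth_scale,
        seed=seed,
    )
    if n_pos == features.shape[0]:
        non_hb_density = hb_density  # unused: weight (1 - p_hb) is zero
    else:
        non_hb_density = grid_kde(
            FeatureMatrix(features[~positive]),
            n_grid=min(n_grid, features.shape[0] - n_pos),
            bandwidth_scale=bandwidth_scale,
            seed=seed,
        )
    return DsspPmiModel(
        hb_weight=p_hb,
        hb_density=hb_density,
        non_hb_density=non_hb_density,
        zeta=zeta,
    )


def make_dssp_pmi(model: DsspPmiModel) -> PmiFunction:
    def _eval(df: pd.DataFrame) -> np.ndarray:
        return model.evaluate(df[["d_AH", "d_DA"]].to_numpy(dtype=float))

    return PmiFunction(kind="dssp_energy", evaluator=_eval, zeta=model.zeta)


# ---------------------------------------------------------------------------
# agreement score


@dataclass
class SimilarityResult:
    """delta agreement between two identifiers on an empirical sample."""

    delta: float
    lambda_norm: float
    n_samples: int


def pmi_similarity(
    f_A: PmiFunction, f_B: PmiFunction, samples: pd.DataFrame
) -> SimilarityResult:
    """Normalised both-flag probability of two identifiers.

    All integrals are Monte-Carlo averages over the sample rows (the
    empirical measure realises the total geometry distribution).  The
    normalisation is the geometric mean of each identifier's
    self-agreement ratio, which makes delta exactly one whenever
    f_A = f_B pointwise, symmetric, and bounded in [0, 1].
    """
    if len(samples) == 0:
        raise ValueError("empty sample set")
    a = f_A(samples)
    b = f_B(samples)
    if not a.any():
        raise ValueError("identifier A evaluates to zero on every sample")
    if not b.any():
        raise ValueError("identifier B evaluates to zero on every sample")
    both = float(np.mean(a * b))
    either = float(np.mean(a + b - a * b))
    rho_a = float(np.mean(a**2)) / float(np.mean(2 * a - a**2))
    rho_b = float(np.mean(b**2)) / float(np.mean(2 * b - b**2))
    lam = float(np.sqrt(rho_a * rho_b))
    delta = both / either / lam
    return SimilarityResult(delta=delta, lambda_norm=lam, n_samples=len(samples))


def restricted_similarity(
    f_A: PmiFunction,
    f_B: PmiFunction,
    samples: pd.DataFrame,
    exclusion: str,
) -> SimilarityResult:
    """delta after discarding intra-residue (or also adjacent-residue)
    donor/acceptor pairs.

    ``exclusion`` is ``"same_residue"`` (drop donor and acceptor in one
    residue) or ``"adjacent_residue"`` (additionally drop sequence
    neighbours, |resnum difference| <= 1 within one chain; different
    chains never count as nearby).
    """
    if exclusion not in ("same_residue", "adjacent_residue"):
        raise ValueError(f"unknown exclusion level {exclusion!r}")
    same_chain = samples["donor_chain"] == samples["acceptor_chain"]
    sep = (samples["donor_resnum"] - samples["acceptor_resnum"]).abs()
    max_sep = 0 if exclusion == "same_residue" else 1
    drop = same_chain & (sep <= max_sep)
    kept = samples.loc[~drop]
    if len(kept) == 0:
        raise ValueError("no samples remain after the residue exclusion")
    return pmi_similarity(f_A, f_B, kept)
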