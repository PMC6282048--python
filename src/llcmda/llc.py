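"""Similarity-network reconstruction by locality-constrained linear coding.

Each entity's interaction profile (a row or column of the binary association
matrix) is expressed as an affine combination of the other entities'
profiles. For sample x_i with dictionary D (columns = the other samples),
the coding weights solve

    min_w  ||x_i - D w||^2  +  lambda1 * ||P_i ⊙ w||^2     s.t.  1^T w = 1

where the locality adapter P_ij = exp(||x_i - x_j||_2 / gamma) penalises
weight on distant dictionary samples (P_ij >= 1, equality iff x_j = x_i).
Setting the gradient of the Lagrangian to zero gives the closed form

    solve (C + lambda1 * diag(P_i)^2) w~ = 1,    w = w~ / (1^T w~)

with C = (x_i 1^T - D)^T (x_i 1^T - D). Collecting each w_i as row i (self
excluded, diagonal zero) yields the reconstructed similarity network; by
default negatives are clipped to zero and the result symmetrized so the
downstream propagation normalization is well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import pdist

from .exceptions import ConfigError, NumericalError, ShapeError, ValidationError
from .matrices import AssociationMatrix, SimilarityMatrix

logger = logging.getLogger(__name__)

MEDIAN_HEURISTIC = "median-heuristic"


@dataclass
class LLCConfig:
    """Parameters of the coding step.

    lambda1
        Weight of the locality penalty (> 0). Also the ridge that keeps the
        linear system nonsingular; raise it if a solve fails.
    gamma
        Bandwidth of the locality adapter: a positive float, or the string
        ``"median-heuristic"`` to use the median pairwise distance among the
        samples being coded (resolved once per reconstruction and logged).
    clip_negative
        Clip negative coding weights to zero in the reconstructed network.
        The affine (not convex) constraint permits negative weights; the
        propagation step needs a nonnegative matrix.
    symmetrize
        Replace W by (W + W^T) / 2 after clipping.
    """

    lambda1: float = 0.1
    gamma: float | str = MEDIAN_HEURISTIC
    clip_negative: bool = True
    symmetrize: bool = True

    def __post_init__(self) -> None:
        if not (self.lambda1 > 0):
            raise ConfigError(f"lambda1 must be > 0, got {self.lambda1}")
        if isinstance(self.gamma, str):
            if self.gamma != MEDIAN_HEURISTIC:
                raise ConfigError(
                    f"gamma must be a positive number or {MEDIAN_HEURISTIC!r}"
                )
        elif not (self.gamma > 0):
            raise ConfigError(f"gamma must be > 0, got {self.gamma}")


def resolve_gamma(samples: np.ndarray, config: LLCConfig) -> float:
    """Return the numeric bandwidth for a sample set (rows = samples)."""
    if not isinstance(config.gamma, str):
        return float(config.gamma)
    if samples.shape[0] < 2:
        return 1.0
    median = float(np.median(pdist(samples)))
    if median <= 0.0:
        # all samples identical: every distance is 0, any bandwidth is equivalent
        logger.info("median pairwise distance is 0; falling back to gamma=1")
        return 1.0
    logger.info("median-heuristic resolved gamma=%.6g", median)
    return median


def locality_adapter(
    x: np.ndarray, dictionary: np.ndarray, gamma: float
) -> np.ndarray:
    """Distance penalties P_ij = exp(||x - x_j||_2 / gamma) per dictionary column."""
    if not (gamma > 0):
        raise ConfigError(f"gamma must be > 0, got {gamma}")
    x = np.asarray(x, dtype=float).ravel()
    dictionary = np.atleast_2d(np.asarray(dictionary, dtype=float))
    if dictionary.shape[0] != x.shape[0]:
        raise ShapeError(
            f"sample dimension {x.shape[0]} != dictionary row count {dictionary.shape[0]}"
        )
    distances = np.linalg.norm(dictionary - x[:, None], axis=0)
    return np.exp(distances / gamma)


def llc_solve(
    x: np.ndarray,
    dictionary: np.ndarray,
    config: LLCConfig,
    gamma: float | None = None,
) -> np.ndarray:
    """Coding weights of one sample against a dictionary (columns = samples).

    Returns w with 1^T w = 1 minimising
    ``||x - D w||^2 + lambda1 ||P ⊙ w||^2``. ``gamma`` overrides the config
    bandwidth (used by :func:`reconstruct_similarity`, which resolves the
    median heuristic once over the whole sample set).
    """
    x = np.asarray(x, dtype=float).ravel()
    dictionary = np.atleast_2d(np.asarray(dictionary, dtype=float))
    if dictionary.shape[1] < 1:
        raise ValidationError("dictionary must contain at least one sample")
    if dictionary.shape[0] != x.shape[0]:
        raise ShapeError(
            f"sample dimension {x.shape[0]} != dictionary row count {dictionary.shape[0]}"
        )
    if gamma is None:
        gamma = resolve_gamma(
            np.vstack([x[None, :], dictionary.T]), config
        )
    p = locality_adapter(x, dictionary, gamma)
    residual = x[:, None] - dictionary  # x 1^T - D
    cov = residual.T @ residual  # C, PSD
    system = cov + config.lambda1 * np.diag(p**2)
    try:
        w_raw = np.linalg.solve(system, np.ones(dictionary.shape[1]))
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "LLC system is singular; raise lambda1 to regularize it"
        ) from exc
    total = float(w_raw.sum())
    if not np.isfinite(total) or abs(total) < 1e-300:
        raise NumericalError(
            "LLC weights could not be normalized (sum ~ 0); raise lambda1"
        )
    return w_raw / total


def reconstruct_similarity(
    profiles: AssociationMatrix,
    axis: str,
    config: LLCConfig | None = None,
) -> SimilarityMatrix:
    """Reconstructed similarity network over one side of the bipartite graph.

    ``axis="mirna"`` codes each miRNA's interaction profile (its row of A)
    against all other miRNAs; ``axis="disease"`` codes columns. Row i of the
    result holds sample i's weights over the other entities, diagonal zero.
    """
    config = config or LLCConfig()
    if axis == "mirna":
        samples = profiles.values
        ids = profiles.mirna_ids
    elif axis == "disease":
        samples = profiles.values.T
        ids = profiles.disease_ids
    else:
        raise ValidationError(f"axis must be 'mirna' or 'disease', got {axis!r}")
    n = samples.shape[0]
    if n < 2:
        # a lone entity has no dictionary to borrow from: empty network
        return SimilarityMatrix(np.zeros((n, n)), list(ids), kind="reconstructed")
    gamma = resolve_gamma(samples, config)
    weights = np.zeros((n, n))
    for i in range(n):
        others = np.arange(n) != i
        w = llc_solve(samples[i], samples[others].T, config, gamma=gamma)
        weights[i, others] = w
    if config.clip_negative:
        np.clip(weights, 0.0, None, out=weights)
    if config.symmetrize:
        weights = (weights + weights.T) / 2.0
    return SimilarityMatrix(weights, list(ids), kind="reconstructed")
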