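"""Label propagation on similarity networks and fusion of the four scores.

Known associations Y diffuse over a degree-normalized similarity graph S:

    F(t+1) = rate * S * F(t) + (1 - rate) * Y,      F(0) = Y

whose fixed point is ``(1 - rate) (I - rate S)^{-1} Y``. With the symmetric
normalization ``S = D^{-1/2} W D^{-1/2}`` (D = diagonal row sums) the
spectral radius of a symmetric nonnegative W is at most 1, so the iteration
converges for any rate in (0, 1).

The full predictor runs this diffusion in miRNA space (labels Y = A, rate
alpha) over the functional similarity FMS and the LLC-reconstructed RMS, and
in disease space (labels Y^T, rate beta) over the semantic similarity DSS
and the reconstructed RDS, then averages the four score matrices:

    F = (F_M + F_RM + F_D' + F_RD') / 4

with the disease-space results transposed back to miRNA x disease.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError, LabelAlignmentError, ValidationError
from .llc import LLCConfig, reconstruct_similarity
from .matrices import (
    AssociationMatrix,
    ScoreMatrix,
    SimilarityMatrix,
    check_alignment,
)

logger = logging.getLogger(__name__)


@dataclass
class PropagationConfig:
    """Propagation rates and convergence controls.

    ``alpha`` is the diffusion rate in miRNA space, ``beta`` in disease
    space; both default to 0.5 (larger values weight network smoothness over
    fidelity to the initial labels). ``mode`` selects the fixed-point
    iteration or the direct linear solve; the two agree to within ~10*tol.
    """

    alpha: float = 0.5
    beta: float = 0.5
    tol: float = 1e-6
    max_iter: int = 1000
    mode: str = "iterative"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (0.0 < self.beta < 1.0):
            raise ConfigError(f"beta must be in (0, 1), got {self.beta}")
        if not (self.tol > 0):
            raise ConfigError(f"tol must be > 0, got {self.tol}")
        if self.max_iter < 1:
            raise ConfigError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.mode not in ("iterative", "closed-form"):
            raise ConfigError(f"mode must be 'iterative' or 'closed-form', got {self.mode!r}")


def normalize_similarity(sim: SimilarityMatrix) -> SimilarityMatrix:
    """Symmetric degree normalization D^{-1/2} S D^{-1/2}.

    Rows (and columns) with zero sum map to zero — an isolated entity simply
    receives no network information.
    """
    values = sim.values
    if (values < 0).any():
        raise ValidationError("cannot normalize a similarity matrix with negative entries")
    row_sums = values.sum(axis=1)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(row_sums > 0, 1.0 / np.sqrt(row_sums), 0.0)
    normalized = inv_sqrt[:, None] * values * inv_sqrt[None, :]
    return SimilarityMatrix(normalized, list(sim.entity_ids), kind="normalized")


def propagate_matrix(
    sim_norm: np.ndarray,
    labels: np.ndarray,
    rate: float,
    config: PropagationConfig | None = None,
) -> tuple[np.ndarray, bool, int]:
    """Core diffusion on raw arrays; returns (F, converged, n_iter)."""
    config = config or PropagationConfig()
    if not (0.0 < rate < 1.0):
        raise ConfigError(f"rate must be in (0, 1), got {rate}")
    S = np.asarray(sim_norm, dtype=float)
    Y = np.asarray(labels, dtype=float)
    if S.shape[0] != S.shape[1] or S.shape[0] != Y.shape[0]:
        raise ValidationError(
            f"similarity {S.shape} and labels {Y.shape} are not aligned"
        )
    if config.mode == "closed-form":
        F = (1.0 - rate) * np.linalg.solve(np.eye(S.shape[0]) - rate * S, Y)
        return F, True, 0
    F = Y.copy()
    for iteration in range(1, config.max_iter + 1):
        F_next = rate * (S @ F) + (1.0 - rate) * Y
        delta = float(np.abs(F_next - F).max(initial=0.0))
        F = F_next
        if delta < config.tol:
            logger.debug("propagation converged after %d iterations", iteration)
            return F, True, iteration
    warnings.warn(
        f"label propagation did not converge within {config.max_iter} iterations "
        f"(last delta {delta:.3g})",
        RuntimeWarning,
        stacklevel=2,
    )
    return F, False, config.max_iter


def propagate(
    sim_norm: SimilarityMatrix,
    labels: AssociationMatrix,
    rate: float,
    config: PropagationConfig | None = None,
) -> ScoreMatrix:
    """Diffuse association labels over one normalized similarity network.

    If the network is over miRNAs the labels propagate as-is; if it is over
    diseases, Y^T propagates and the result is transposed back, so the
    returned scores are always miRNA x disease.
    """
    if sim_norm.entity_ids == labels.mirna_ids:
        F, _, _ = propagate_matrix(sim_norm.values, labels.values, rate, config)
        space = "mirna"
    elif sim_norm.entity_ids == labels.disease_ids:
        F_t, _, _ = propagate_matrix(sim_norm.values, labels.values.T, rate, config)
        F = F_t.T
        space = "disease"
    else:
        raise LabelAlignmentError(
            "similarity labels match neither the miRNA nor the disease axis"
        )
    return ScoreMatrix(F, list(labels.mirna_ids), list(labels.disease_ids), space=space)


def predict(
    assoc: AssociationMatrix,
    fms: SimilarityMatrix,
    dss: SimilarityMatrix,
    llc_cfg: LLCConfig | None = None,
    prop_cfg: PropagationConfig | None = None,
    rms: SimilarityMatrix | None = None,
    rds: SimilarityMatrix | None = None,
) -> ScoreMatrix:
    """Fused association scores from the four similarity networks.

    Reconstructs RMS/RDS from the interaction profiles of ``assoc`` (unless
    precomputed ones are passed), normalizes all four networks, propagates
    the labels on each, and averages the four score matrices elementwise.
    """
    llc_cfg = llc_cfg or LLCConfig()
    prop_cfg = prop_cfg or PropagationConfig()
    check_alignment(assoc, fms, "mirna")
    check_alignment(assoc, dss, "disease")
    if rms is None:
        rms = reconstruct_similarity(assoc, "mirna", llc_cfg)
    if rds is None:
        rds = reconstruct_similarity(assoc, "disease", llc_cfg)
    check_alignment(assoc, rms, "mirna")
    check_alignment(assoc, rds, "disease")

    Y = assoc.values
    f_m, _, _ = propagate_matrix(
        normalize_similarity(fms).values, Y, prop_cfg.alpha, prop_cfg
    )
    f_rm, _, _ = propagate_matrix(
        normalize_similarity(rms).values, Y, prop_cfg.alpha, prop_cfg
    )
    f_d, _, _ = propagate_matrix(
        normalize_similarity(dss).values, Y.T, prop_cfg.beta, prop_cfg
    )
    f_rd, _, _ = propagate_matrix(
        normalize_similarity(rds).values, Y.T, prop_cfg.beta, prop_cfg
    )
    fused = (f_m + f_rm + f_d.T + f_rd.T) / 4.0
    return ScoreMatrix(
        fused, list(assoc.mirna_ids), list(assoc.disease_ids), space="fused"
    )
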