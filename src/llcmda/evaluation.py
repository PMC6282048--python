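"""Cross-validation frameworks and ROC/AUC scoring.

Four evaluation protocols are provided, mirroring standard practice for
bipartite association predictors:

* **global LOOCV** — each known pair is held out in turn and ranked against
  every unknown pair across all diseases;
* **local LOOCV** — the held-out pair is ranked only against the candidate
  miRNAs of its own disease;
* **k-fold CV** — the known pairs are partitioned at random, each fold
  masked in turn; repeated to average out the partition randomness;
* **LODOCV** (leave one disease out) — a disease loses all of its known
  miRNAs at once, probing prediction for diseases with no prior labels.

In every protocol the predictor is re-run from the masked matrix, including
the LLC reconstruction step: the interaction profiles ARE the features, so
reusing full-data reconstructions would leak the held-out labels. AUC uses
the midrank (Mann-Whitney) convention for ties, which equals the trapezoidal
area under the ROC curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .exceptions import ValidationError
from .llc import LLCConfig, reconstruct_similarity
from .matrices import AssociationMatrix, SimilarityMatrix
from .propagation import PropagationConfig, predict

logger = logging.getLogger(__name__)

FRAMEWORKS = ("global-loocv", "local-loocv", "kfold", "lodocv")


@dataclass
class ROCResult:
    """AUC plus the ROC polyline for one positive/negative score split."""

    auc: float
    roc_points: list[tuple[float, float]]


@dataclass
class CVReport:
    """Outcome of one cross-validation run."""

    framework: str
    auc: float
    roc_points: list[tuple[float, float]]
    per_unit: dict[str, float] | None = None
    repeats: int = 1
    seed: int | None = None
    n_positives: int = 0

    def __post_init__(self) -> None:
        if self.framework not in FRAMEWORKS:
            raise ValidationError(f"unknown framework {self.framework!r}")
        if not (0.0 <= self.auc <= 1.0):
            raise ValidationError(f"AUC {self.auc} outside [0, 1]")
        pts = list(self.roc_points)
        if not pts or pts[0] != (0.0, 0.0) or pts[-1] != (1.0, 1.0):
            raise ValidationError("ROC points must start at (0,0) and end at (1,1)")
        fprs = [p[0] for p in pts]
        tprs = [p[1] for p in pts]
        if any(b < a for a, b in zip(fprs, fprs[1:])) or any(
            b < a for a, b in zip(tprs, tprs[1:])
        ):
            raise ValidationError("ROC points must be non-decreasing")

    def to_dict(self) -> dict:
        return {
            "framework": self.framework,
            "auc": self.auc,
            "per_unit": self.per_unit,
            "repeats": self.repeats,
            "seed": self.seed,
            "n_positives": self.n_positives,
        }


def roc_auc(
    positive_scores: Sequence[float], negative_scores: Sequence[float]
) -> ROCResult:
    """AUC by the rank-sum (Mann-Whitney) formulation, ties counted 1/2.

    Equals the trapezoidal area under the ROC curve; the curve itself is
    returned as (FPR, TPR) points.
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    auc = (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0) / (
        pos.size * neg.size
    )
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    fpr, tpr, _ = roc_curve(
        labels, np.concatenate([pos, neg]), drop_intermediate=False
    )
    points = [(float(a), float(b)) for a, b in zip(fpr, tpr)]
    if points[0] != (0.0, 0.0):
        points.insert(0, (0.0, 0.0))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return ROCResult(float(auc), points)


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def _u_statistic(score: float, negatives: np.ndarray) -> float:
    """Fraction of negatives scoring below ``score`` (ties count 1/2)."""
    neg_sorted = np.sort(negatives)
    below = np.searchsorted(neg_sorted, score, side="left")
    tied = np.searchsorted(neg_sorted, score, side="right") - below
    return (below + 0.5 * tied) / neg_sorted.size


def _roc_from_u(u_values: Sequence[float]) -> list[tuple[float, float]]:
    """Rank-threshold ROC: each positive's miss rate r = 1 - u is the FPR at
    which it becomes a true positive; TPR steps up at sorted r values."""
    r = np.sort(1.0 - np.asarray(u_values, dtype=float))
    n = r.size
    points = [(0.0, 0.0)]
    for idx, value in enumerate(r, start=1):
        points.append((float(min(max(value, 0.0), 1.0)), idx / n))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points


def _masked_predict(
    masked: AssociationMatrix,
    fms: SimilarityMatrix,
    dss: SimilarityMatrix,
    llc_cfg: LLCConfig,
    prop_cfg: PropagationConfig,
    recon_cache: dict | None,
) -> np.ndarray:
    """Run the full predictor on a masked matrix, optionally caching the LLC
    reconstructions (they depend on the masked profiles, not on alpha/beta)."""
    rms = rds = None
    if recon_cache is not None:
        key = masked.values.tobytes()
        if key in recon_cache:
            rms, rds = recon_cache[key]
        else:
            rms = reconstruct_similarity(masked, "mirna", llc_cfg)
            rds = reconstruct_similarity(masked, "disease", llc_cfg)
            recon_cache[key] = (rms, rds)
    return predict(
        masked, fms, dss, llc_cfg, prop_cfg, rms=rms, rds=rds
    ).values


def _mask_pairs(
    assoc: AssociationMatrix, pairs: Sequence[tuple[int, int]]
) -> AssociationMatrix:
    masked = assoc.copy()
    for i, j in pairs:
        masked.values[i, j] = 0.0
    return masked


# ---------------------------------------------------------------------------
# cross-validation frameworks
# ---------------------------------------------------------------------------


def global_loocv(
    assoc: AssociationMatrix,
    fms: SimilarityMatrix,
    dss: SimilarityMatrix,
    llc_cfg: LLCConfig | None = None,
    prop_cfg: PropagationConfig | None = None,
    exclude_known_negatives: bool = True,
    recon_cache: dict | None = None,
) -> CVReport:
    """Hold out each known pair; rank it against the global unknown pool.

    The candidate pool is every pair that is 0 in the ORIGINAL matrix; by
    default the other known pairs are neither positives nor negatives in a
    round (set ``exclude_known_negatives=False`` to count them as negatives
    for sensitivity analysis).
    """
    llc_cfg = llc_cfg or LLCConfig()
    prop_cfg = prop_cfg or PropagationConfig()
    knowns = assoc.known_pairs()
    if len(knowns) < 2:
        raise ValidationError("global LOOCV needs at least two known associations")
    unknown_mask = assoc.values == 0
    u_values = []
    for i, j in knowns:
        scores = _masked_predict(
            _mask_pairs(assoc, [(i, j)]), fms, dss, llc_cfg, prop_cfg, recon_cache
        )
        if exclude_known_negatives:
            negatives = scores[unknown_mask]
        else:
            pool = np.ones_like(scores, dtype=bool)
            pool[i, j] = False
            negatives = scores[pool]
        u_values.append(_u_statistic(scores[i, j], negatives))
    return CVReport(
        framework="global-loocv",
        auc=float(np.mean(u_values)),
        roc_points=_roc_from_u(u_values),
        n_positives=len(u_values),
    )


def local_loocv(
    assoc: AssociationMatrix,
    fms: SimilarityMatrix,
    dss: SimilarityMatrix,
    llc_cfg: LLCConfig | None = None,
    prop_cfg: PropagationConfig | None = None,
    recon_cache: dict | None = None,
) -> CVReport:
    """As global LOOCV, but each held-out pair is ranked only among its own
    disease's candidate miRNAs (those not known to be associated with it)."""
    llc_cfg = llc_cfg or LLCConfig()
    prop_cfg = prop_cfg or PropagationConfig()
    u_values = []
    per_disease: dict[str, float] = {}
    for j, disease in enumerate(assoc.disease_ids):
        pos_rows = np.nonzero(assoc.values[:, j] == 1)[0]
        neg_rows = np.nonzero(assoc.values[:, j] == 0)[0]
        if pos_rows.size == 0:
            logger.info("disease %s has no known miRNAs; skipped", disease)
            continue
        if neg_rows.size == 0:
            logger.info("disease %s has no candidate miRNAs; skipped", disease)
            continue
        disease_u = []
        for i in pos_rows:
            scores = _masked_predict(
                _mask_pairs(assoc, [(i, j)]), fms, dss, llc_cfg, prop_cfg, recon_cache
            )
            disease_u.append(_u_statistic(scores[i, j], scores[neg_rows, j]))
        per_disease[disease] = float(np.mean(disease_u))
        u_values.extend(disease_u)
    if not u_values:
        raise ValidationError("no disease had both known and candidate miRNAs")
    return CVReport(
        framework="local-loocv",
        auc=float(np.mean(u_values)),
        roc_points=_roc_from_u(u_values),
        per_unit=per_disease,
        n_positives=len(u_values),
    )


def kfold_cv(
    assoc: AssociationMatrix,
    fms: SimilarityMatrix,
    dss: SimilarityMatrix,
    llc_cfg: LLCConfig | None = None,
    prop_cfg: PropagationConfig | None = None,
    k: int = 5,
    repeats: int = 20,
    seed: int = 0,
    recon_cache: dict | None = None,
) -> CVReport:
    """Repeated random k-fold masking of the known associations.

    Per repeat, the known pairs are shuffled and split into k folds; each
    fold is masked in turn and its pairs ranked against the global unknown
    pool. The AUC is averaged over folds, then repeats. Each repeat draws
    its shuffle from its own child of the top-level seed, so the first
    repeats of runs with equal seeds coincide regardless of ``repeats``.
    """
    llc_cfg = llc_cfg or LLCConfig()
    prop_cfg = prop_cfg or PropagationConfig()
    knowns = assoc.known_pairs()
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if k > len(knowns):
        raise ValidationError(f"k={k} exceeds the {len(knowns)} known associations")
    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    unknown_mask = assoc.values == 0
    children = np.random.SeedSequence(seed).spawn(repeats)
    per_unit: dict[str, float] = {}
    repeat_aucs = []
    all_u: list[float] = []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        order = rng.permutation(len(knowns))
        fold_aucs = []
        for f, fold_idx in enumerate(np.array_split(order, k)):
            fold_pairs = [knowns[idx] for idx in fold_idx]
            scores = _masked_predict(
                _mask_pairs(assoc, fold_pairs), fms, dss, llc_cfg, prop_cfg, recon_cache
            )
            negatives = scores[unknown_mask]
            fold_u = [_u_statistic(scores[i, j], negatives) for i, j in fold_pairs]
            fold_aucs.append(float(np.mean(fold_u)))
            per_unit[f"repeat{r}_fold{f}"] = fold_aucs[-1]
            all_u.extend(fold_u)
        repeat_aucs.append(float(np.mean(fold_aucs)))
    return CVReport(
        framework="kfold",
        auc=float(np.mean(repeat_aucs)),
        roc_points=_roc_from_u(all_u),
        per_unit=per_unit,
        repeats=repeats,
        seed=seed,
        n_positives=len(all_u),
    )


def lodocv(
    assoc: AssociationMatrix,
    fms: SimilarityMatrix,
    dss: SimilarityMatrix,
    llc_cfg: LLCConfig | None = None,
    prop_cfg: PropagationConfig | None = None,
    recon_cache: dict | None = None,
) -> CVReport:
    """Leave one disease out: remove a disease's entire association column,
    re-predict, and rank its removed miRNAs against the remaining ones."""
    llc_cfg = llc_cfg or LLCConfig()
    prop_cfg = prop_cfg or PropagationConfig()
    diseases_with_knowns = [
        j for j in range(assoc.n_diseases) if assoc.values[:, j].sum() >= 1
    ]
    if len(diseases_with_knowns) < 2:
        raise ValidationError("LODOCV needs at least two diseases with known miRNAs")
    per_disease: dict[str, float] = {}
    u_values: list[float] = []
    for j in diseases_with_knowns:
        pos_rows = np.nonzero(assoc.values[:, j] == 1)[0]
        neg_rows = np.nonzero(assoc.values[:, j] == 0)[0]
        if neg_rows.size == 0:
            logger.info(
                "disease %s associates with every miRNA; skipped", assoc.disease_ids[j]
            )
            continue
        masked = _mask_pairs(assoc, [(i, j) for i in pos_rows])
        scores = _masked_predict(masked, fms, dss, llc_cfg, prop_cfg, recon_cache)
        negatives = scores[neg_rows, j]
        disease_u = [_u_statistic(scores[i, j], negatives) for i in pos_rows]
        per_disease[assoc.disease_ids[j]] = float(np.mean(disease_u))
        u_values.extend(disease_u)
    if not u_values:
        raise ValidationError("no disease could be evaluated under LODOCV")
    return CVReport(
        framework="lodocv",
        auc=float(np.mean(u_values)),
        roc_points=_roc_from_u(u_values),
        per_unit=per_disease,
        n_positives=len(u_values),
    )


_FRAMEWORK_FUNCS = {
    "global-loocv": global_loocv,
    "local-loocv": local_loocv,
    "kfold": kfold_cv,
    "lodocv": lodocv,
}


def evaluate(
    framework: str,
    assoc: AssociationMatrix,
    fms: SimilarityMatrix,
    dss: SimilarityMatrix,
    llc_cfg: LLCConfig | None = None,
    prop_cfg: PropagationConfig | None = None,
    k: int = 5,
    repeats: int = 20,
    seed: int = 0,
    recon_cache: dict | None = None,
) -> CVReport:
    """Dispatch to one of the four CV frameworks by name."""
    if framework not in _FRAMEWORK_FUNCS:
        raise ValidationError(f"unknown framework {framework!r}; choose from {FRAMEWORKS}")
    if framework == "kfold":
        return kfold_cv(
            assoc, fms, dss, llc_cfg, prop_cfg,
            k=k, repeats=repeats, seed=seed, recon_cache=recon_cache,
        )
    return _FRAMEWORK_FUNCS[framework](
        assoc, fms, dss, llc_cfg, prop_cfg, recon_cache=recon_cache
    )


def parameter_sweep(
    assoc: AssociationMatrix,
    fms: SimilarityMatrix,
    dss: SimilarityMatrix,
    llc_cfg: LLCConfig | None = None,
    prop_cfg: PropagationConfig | None = None,
    alphas: Sequence[float] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
    betas: Sequence[float] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
    framework: str = "kfold",
    k: int = 5,
    repeats: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """AUC grid over the alpha x beta Cartesian product at fixed seeds.

    Fold partitions are identical across the grid (same seed), and the LLC
    reconstructions are shared across cells via a cache since they do not
    depend on the propagation rates.
    """
    llc_cfg = llc_cfg or LLCConfig()
    prop_cfg = prop_cfg or PropagationConfig()
    for value in list(alphas) + list(betas):
        if not (0.0 < value < 1.0):
            raise ValidationError(f"propagation rates must be in (0, 1), got {value}")
    cache: dict = {}
    grid = pd.DataFrame(
        index=pd.Index([float(a) for a in alphas], name="alpha"),
        columns=pd.Index([float(b) for b in betas], name="beta"),
        dtype=float,
    )
    for a in alphas:
        for b in betas:
            cfg = replace(prop_cfg, alpha=float(a), beta=float(b))
            report = evaluate(
                framework, assoc, fms, dss, llc_cfg, cfg,
                k=k, repeats=repeats, seed=seed, recon_cache=cache,
            )
            grid.loc[float(a), float(b)] = report.auc
    return grid
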