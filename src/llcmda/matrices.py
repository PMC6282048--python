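"""Labeled matrix containers and their TSV readers/writers.

The package works with three containers:

* :class:`AssociationMatrix` — the binary miRNA x disease adjacency matrix A.
  Its rows are the interaction-profile feature vectors of miRNAs and its
  columns those of diseases.
* :class:`SimilarityMatrix` — a square, labeled, real matrix over one entity
  set: the miRNA functional similarity (FMS), the disease semantic similarity
  (DSS), the LLC-reconstructed networks (RMS/RDS), or a normalized form.
* :class:`ScoreMatrix` — a real prediction matrix F aligned to an
  AssociationMatrix's labels.

All on-disk formats are plain UTF-8 TSV: an edge list (no header) or a dense
table (header row of disease ids, first column of miRNA ids) for
associations; a dense labeled table for similarities; a long-format table
sorted by descending score for predictions.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    LabelAlignmentError,
    ParseError,
    ShapeError,
    ValidationError,
)

SIMILARITY_KINDS = ("functional", "semantic", "reconstructed", "normalized")
SCORE_SPACES = ("mirna", "disease", "fused")


def _check_labels(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValidationError(f"duplicate {what} labels: {dupes[:5]}")
    return labels


@dataclass
class AssociationMatrix:
    """Binary bipartite adjacency matrix (miRNAs x diseases)."""

    values: np.ndarray
    mirna_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError("association matrix must be 2-dimensional")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValidationError("association matrix must be non-empty")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValidationError("association entries must be 0 or 1")
        self.mirna_ids = _check_labels(self.mirna_ids, "miRNA")
        self.disease_ids = _check_labels(self.disease_ids, "disease")
        if self.values.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ShapeError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.mirna_ids)} miRNAs x {len(self.disease_ids)} diseases"
            )

    @property
    def n_mirnas(self) -> int:
        return self.values.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.values.shape[1]

    @property
    def n_known(self) -> int:
        """Number of known (=1) associations."""
        return int(self.values.sum())

    def known_pairs(self) -> list[tuple[int, int]]:
        """Index pairs (i, j) of all known associations, row-major order."""
        rows, cols = np.nonzero(self.values)
        return list(zip(rows.tolist(), cols.tolist()))

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            self.values.copy(), list(self.mirna_ids), list(self.disease_ids)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.astype(int), index=self.mirna_ids, columns=self.disease_ids
        )


@dataclass
class SimilarityMatrix:
    """Square labeled similarity matrix over one entity set.

    ``kind`` records provenance: ``functional`` (miRNA functional similarity),
    ``semantic`` (disease DAG similarity), ``reconstructed`` (LLC output,
    possibly signed/asymmetric before clipping and symmetrization) or
    ``normalized`` (after symmetric degree normalization).
    """

    values: np.ndarray
    entity_ids: list[str]
    kind: str = "functional"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in SIMILARITY_KINDS:
            raise ValidationError(f"unknown similarity kind {self.kind!r}")
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ShapeError(f"similarity matrix must be square, got {self.values.shape}")
        self.entity_ids = _check_labels(self.entity_ids, "entity")
        if self.values.shape[0] != len(self.entity_ids):
            raise ShapeError(
                f"{self.values.shape[0]} rows but {len(self.entity_ids)} labels"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("similarity entries must be finite")
        if self.kind in ("functional", "semantic", "normalized") and (self.values < 0).any():
            raise ValidationError(f"{self.kind} similarity entries must be nonnegative")
        if self.kind in ("functional", "semantic"):
            asym = float(np.abs(self.values - self.values.T).max(initial=0.0))
            if asym > 1e-8:
                raise ValidationError(
                    f"{self.kind} similarity must be symmetric (max asymmetry {asym:.3g})"
                )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.entity_ids, columns=self.entity_ids)


@dataclass
class ScoreMatrix:
    """Real-valued prediction scores aligned miRNA x disease."""

    values: np.ndarray
    mirna_ids: list[str]
    disease_ids: list[str]
    space: str = "fused"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.space not in SCORE_SPACES:
            raise ValidationError(f"unknown score space {self.space!r}")
        if self.values.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ShapeError("score matrix shape does not match its labels")
        if not np.isfinite(self.values).all():
            raise ValidationError("scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.mirna_ids, columns=self.disease_ids)

    def to_long(self) -> pd.DataFrame:
        """Long-format (mirna_id, disease_id, score), sorted by descending score.

        Ties are broken by (mirna_id, disease_id) so output is deterministic.
        """
        if self.values.size == 0:
            return pd.DataFrame(columns=["mirna_id", "disease_id", "score"])
        long = self.to_frame().stack().rename("score").reset_index()
        long.columns = ["mirna_id", "disease_id", "score"]
        return long.sort_values(
            ["score", "mirna_id", "disease_id"],
            ascending=[False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)


def check_alignment(assoc: AssociationMatrix, sim: SimilarityMatrix, axis: str) -> None:
    """Raise unless ``sim`` is labeled exactly like the chosen axis of ``assoc``."""
    expected = assoc.mirna_ids if axis == "mirna" else assoc.disease_ids
    if sim.entity_ids != expected:
        raise LabelAlignmentError(
            f"similarity labels do not match association {axis} labels "
            f"(e.g. {sim.entity_ids[:3]} vs {expected[:3]})"
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_associations(path: str | Path, format: str = "edge-list") -> AssociationMatrix:
    """Read a binary association table.

    ``edge-list``: TSV rows ``mirna_id<TAB>disease_id[<TAB>1]``, no header;
    duplicate edges collapse to a single 1; label order is first-seen.
    ``dense``: TSV with a header row of disease ids and a first column of
    miRNA ids; label order is file order.
    """
    path = Path(path)
    if format == "edge-list":
        mirnas: dict[str, int] = {}
        diseases: dict[str, int] = {}
        edges: list[tuple[int, int]] = []
        with open(path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n").rstrip("\r")
                if not line.strip():
                    continue
                tokens = line.split("\t")
                if len(tokens) not in (2, 3):
                    raise ParseError(
                        f"expected 2 or 3 tab-separated fields, got {len(tokens)}",
                        line=lineno,
                    )
                if len(tokens) == 3 and tokens[2].strip() not in ("1", "1.0"):
                    raise ParseError(
                        f"third column must be 1, got {tokens[2]!r}", line=lineno
                    )
                m, d = tokens[0].strip(), tokens[1].strip()
                if not m or not d:
                    raise ParseError("empty identifier", line=lineno)
                mi = mirnas.setdefault(m, len(mirnas))
                dj = diseases.setdefault(d, len(diseases))
                edges.append((mi, dj))
        if not edges:
            raise ValidationError(f"no associations found in {path}")
        values = np.zeros((len(mirnas), len(diseases)))
        for mi, dj in edges:
            values[mi, dj] = 1.0
        return AssociationMatrix(values, list(mirnas), list(diseases))
    if format == "dense":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        if frame.empty:
            raise ValidationError(f"empty association table in {path}")
        return AssociationMatrix(
            frame.to_numpy(dtype=float),
            [str(x) for x in frame.index],
            [str(x) for x in frame.columns],
        )
    raise ValidationError(f"unknown association format {format!r}")


def write_associations(
    assoc: AssociationMatrix, path: str | Path, format: str = "dense"
) -> None:
    path = Path(path)
    if format == "dense":
        assoc.to_frame().to_csv(path, sep="\t")
    elif format == "edge-list":
        with open(path, "w", encoding="utf-8") as fh:
            for i, j in assoc.known_pairs():
                fh.write(f"{assoc.mirna_ids[i]}\t{assoc.disease_ids[j]}\n")
    else:
        raise ValidationError(f"unknown association format {format!r}")


def read_similarity(
    path: str | Path,
    kind: str = "functional",
    asym_tol: float = 1e-4,
) -> SimilarityMatrix:
    """Read a dense labeled square similarity table.

    Small asymmetries (float round-trip noise) are repaired by averaging with
    the transpose; asymmetry above ``asym_tol`` is a hard error.
    """
    frame = pd.read_csv(Path(path), sep="\t", index_col=0)
    values = frame.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ShapeError(f"similarity table must be square, got {values.shape}")
    rows = [str(x) for x in frame.index]
    cols = [str(x) for x in frame.columns]
    if rows != cols:
        raise LabelAlignmentError("similarity row labels differ from column labels")
    if np.isnan(values).any():
        raise ValidationError(f"NaN entries in similarity table {path}")
    asym = float(np.abs(values - values.T).max(initial=0.0))
    if asym > asym_tol:
        raise ValidationError(
            f"similarity table is asymmetric (max |S - S^T| = {asym:.3g} > {asym_tol:.3g})"
        )
    values = (values + values.T) / 2.0
    return SimilarityMatrix(values, rows, kind=kind)


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    sim.to_frame().to_csv(Path(path), sep="\t")


def write_scores(scores: ScoreMatrix, path: str | Path) -> None:
    """Write scores in long format (mirna_id, disease_id, score), best first."""
    if not np.isfinite(scores.values).all():  # defensive: container also checks
        raise ValidationError("scores contain non-finite values")
    long = scores.to_long()
    long.to_csv(Path(path), sep="\t", index=False, float_format="%.12g")


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read a long-format score table back as a DataFrame."""
    frame = pd.read_csv(Path(path), sep="\t")
    expected = ["mirna_id", "disease_id", "score"]
    if list(frame.columns) != expected:
        raise ParseError(f"expected columns {expected}, got {list(frame.columns)}")
    return frame
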