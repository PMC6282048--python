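"""Self-contained synthetic fixtures with planted co-cluster structure.

The predictor's working assumption is that functionally similar miRNAs
associate with semantically similar diseases. The generator plants exactly
that structure: miRNAs and diseases are partitioned into blocks, pairs
inside a co-cluster associate with high probability and pairs across
co-clusters with low probability (plus optional label-flip noise); the
miRNA similarity matrix is high within blocks and low between; and the
disease DAGs give same-block diseases a deep shared ancestor chain while
different blocks share only the ontology root, so the DAG-based semantic
similarity is likewise block-structured.

Everything is deterministic given the seed. The standard regression fixture
used throughout the test suite is ``standard_fixture()``:
20 miRNAs x 15 diseases, 3 blocks, within/between densities 0.7/0.05,
2% flip noise, seed 7.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ValidationError
from .matrices import (
    AssociationMatrix,
    SimilarityMatrix,
    write_associations,
    write_similarity,
)
from .semantic import DiseaseDAG, semantic_similarity_matrix


@dataclass
class FixtureSpec:
    """Parameters of the planted-block generator."""

    n_mirna: int
    n_disease: int
    n_blocks: int
    density_within: float = 0.7
    density_between: float = 0.05
    noise_flip: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirna < 1 or self.n_disease < 1:
            raise ValidationError("need at least one miRNA and one disease")
        if not (1 <= self.n_blocks <= min(self.n_mirna, self.n_disease)):
            raise ValidationError(
                f"n_blocks must be in [1, min(n_mirna, n_disease)], got {self.n_blocks}"
            )
        if not (0.0 < self.density_within <= 1.0):
            raise ValidationError("density_within must be in (0, 1]")
        if not (0.0 <= self.density_between < 1.0):
            raise ValidationError("density_between must be in [0, 1)")
        if self.density_within <= self.density_between:
            raise ValidationError("density_within must exceed density_between")
        if not (0.0 <= self.noise_flip < 0.5):
            raise ValidationError("noise_flip must be in [0, 0.5)")


STANDARD_SPEC = FixtureSpec(
    n_mirna=20, n_disease=15, n_blocks=3,
    density_within=0.7, density_between=0.05, noise_flip=0.02, seed=7,
)


def _block_assignment(n: int, n_blocks: int) -> np.ndarray:
    """Contiguous, nearly equal block labels 0..n_blocks-1."""
    return np.concatenate(
        [np.full(len(chunk), b) for b, chunk in enumerate(np.array_split(np.arange(n), n_blocks))]
    )


def gen_fixture(
    spec: FixtureSpec,
) -> tuple[AssociationMatrix, SimilarityMatrix, SimilarityMatrix, list[DiseaseDAG]]:
    """Generate (associations, miRNA similarity, disease similarity, DAGs).

    The returned disease similarity is computed from the generated DAGs via
    the semantic-similarity machinery, so it is exactly what the package
    would produce from the equivalent on-disk ontology files.
    """
    rng = np.random.default_rng(spec.seed)
    m_blocks = _block_assignment(spec.n_mirna, spec.n_blocks)
    d_blocks = _block_assignment(spec.n_disease, spec.n_blocks)
    mirna_ids = [f"mir{i + 1}" for i in range(spec.n_mirna)]
    disease_ids = [f"dis{j + 1}" for j in range(spec.n_disease)]

    co_cluster = m_blocks[:, None] == d_blocks[None, :]
    prob = np.where(co_cluster, spec.density_within, spec.density_between)
    values = (rng.random(prob.shape) < prob).astype(float)
    flips = rng.random(prob.shape) < spec.noise_flip
    values = np.where(flips, 1.0 - values, values)
    assoc = AssociationMatrix(values, mirna_ids, disease_ids)

    same_block = m_blocks[:, None] == m_blocks[None, :]
    high = rng.uniform(0.6, 0.9, size=same_block.shape)
    low = rng.uniform(0.0, 0.2, size=same_block.shape)
    fms_values = np.where(same_block, high, low)
    fms_values = (fms_values + fms_values.T) / 2.0
    np.fill_diagonal(fms_values, 1.0)
    fms = SimilarityMatrix(fms_values, mirna_ids, kind="functional")

    dags = _gen_dags(disease_ids, d_blocks, rng)
    dss = semantic_similarity_matrix(dags)
    return assoc, fms, dss, dags


def _gen_dags(
    disease_ids: list[str], d_blocks: np.ndarray, rng: np.random.Generator
) -> list[DiseaseDAG]:
    """One rooted DAG per disease over a shared ontology.

    Every DAG ends at the global term ``ROOT``. Diseases of block b climb
    through the shared chain ``mid_b -> anc_b -> ROOT``, so same-block pairs
    share three ancestors while different-block pairs share only ``ROOT``.
    About half the diseases get a private intermediate term, which varies
    the semantic values (and hence the similarities) within a block.
    """
    dags = []
    for disease, block in zip(disease_ids, d_blocks):
        term = f"t_{disease}"
        mid, anc = f"mid_b{block}", f"anc_b{block}"
        nodes = {term, mid, anc, "ROOT"}
        edges = {(mid, anc), (anc, "ROOT")}
        if rng.random() < 0.5:
            private = f"priv_{disease}"
            nodes.add(private)
            edges |= {(term, private), (private, mid)}
        else:
            edges.add((term, mid))
        dags.append(
            DiseaseDAG(disease_id=disease, nodes=nodes, edges=edges, root=term)
        )
    return dags


def standard_fixture() -> tuple[
    AssociationMatrix, SimilarityMatrix, SimilarityMatrix, list[DiseaseDAG]
]:
    """The committed regression fixture (20 x 15, 3 blocks, seed 7)."""
    return gen_fixture(STANDARD_SPEC)


def mask_associations(
    assoc: AssociationMatrix, fraction: float, seed: int
) -> tuple[AssociationMatrix, list[tuple[str, str]]]:
    """Set a random ``round(fraction * n_known)`` of the known pairs to zero.

    At least one known association always remains. Returns the masked copy
    and the list of masked (mirna_id, disease_id) pairs.
    """
    if not (0.0 < fraction < 1.0):
        raise ValidationError(f"fraction must be in (0, 1), got {fraction}")
    knowns = assoc.known_pairs()
    n_mask = int(round(fraction * len(knowns)))
    if n_mask == 0:
        raise ValidationError(
            f"fraction {fraction} masks zero of the {len(knowns)} known pairs"
        )
    n_mask = min(n_mask, len(knowns) - 1)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(knowns), size=n_mask, replace=False)
    masked = assoc.copy()
    pairs = []
    for idx in sorted(chosen.tolist()):
        i, j = knowns[idx]
        masked.values[i, j] = 0.0
        pairs.append((assoc.mirna_ids[i], assoc.disease_ids[j]))
    return masked, pairs


def write_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Materialize a fixture as the package's on-disk formats.

    Writes ``assoc.tsv`` (dense), ``fms.tsv``, ``dss.tsv``,
    ``dag_edges.tsv`` (child<TAB>parent over the whole synthetic ontology)
    and ``roster.tsv`` (disease_id<TAB>root_term).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assoc, fms, dss, dags = gen_fixture(spec)
    paths = {
        "assoc": outdir / "assoc.tsv",
        "fms": outdir / "fms.tsv",
        "dss": outdir / "dss.tsv",
        "dag_edges": outdir / "dag_edges.tsv",
        "roster": outdir / "roster.tsv",
    }
    write_associations(assoc, paths["assoc"], format="dense")
    write_similarity(fms, paths["fms"])
    write_similarity(dss, paths["dss"])
    edges = sorted({edge for dag in dags for edge in dag.edges})
    with open(paths["dag_edges"], "w", encoding="utf-8") as fh:
        for child, parent in edges:
            fh.write(f"{child}\t{parent}\n")
    with open(paths["roster"], "w", encoding="utf-8") as fh:
        for dag in dags:
            fh.write(f"{dag.disease_id}\t{dag.root}\n")
    return paths
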