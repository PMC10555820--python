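"""Phylogenetic ordination: cophenetic distances, classical PCoA, and
genus-to-species score assignment.

The genus-level tree is summarized as patristic (cophenetic) distances,
double-centered and eigendecomposed (classical metric scaling). Axes with
negative eigenvalues are dropped without correction; for ultrametric trees
the distances are Euclidean-embeddable so nothing is lost. Species inherit
the coordinates of their genus verbatim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

__all__ = ["PhyloScores", "cophenetic_distances", "pcoa", "assign_species_scores"]

_EIG_TOL = 1e-10


@dataclass
class PhyloScores:
    """Taxon x axis coordinates with the eigenvalue spectrum.

    Axes are ordered by decreasing eigenvalue; only positive-eigenvalue axes
    are retained, so ``scores.shape[1] == len(eigenvalues) <= n - 1``.
    ``relative_eigenvalues`` are fractions of the summed positive spectrum.
    """

    scores: pd.DataFrame
    eigenvalues: np.ndarray
    relative_eigenvalues: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


def cophenetic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Patristic distance matrix: path sums of branch lengths between leaves.

    Computed by a postorder merge: each node carries distances from its leaf
    set up to itself; pairs across child subtrees are filled at their MRCA.
    Branch lengths must be present (the root edge may be absent).
    """
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    if len(set(labels)) != len(labels):
        raise ValueError("leaf labels must be unique")
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    D = np.zeros((n, n))

    # up[node] = (leaf indices below node, distance from each leaf to node)
    up: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            up[id(node)] = (np.array([index[id(node)]]), np.zeros(1))
        else:
            parts = []
            for child in node.child_nodes():
                length = child.edge.length
                if length is None:
                    raise ValueError("branch lengths are required on all edges")
                idx, dist = up.pop(id(child))
                parts.append((idx, dist + length))
            for a in range(len(parts)):
                for b in range(a + 1, len(parts)):
                    ia, da = parts[a]
                    ib, db = parts[b]
                    block = da[:, None] + db[None, :]
                    D[np.ix_(ia, ib)] = block
                    D[np.ix_(ib, ia)] = block.T
            up[id(node)] = (
                np.concatenate([p[0] for p in parts]),
                np.concatenate([p[1] for p in parts]),
            )
    order = np.argsort(labels)
    labels_sorted = [labels[i] for i in order]
    return pd.DataFrame(D[np.ix_(order, order)], index=labels_sorted, columns=labels_sorted)


def pcoa(d: pd.DataFrame | np.ndarray, n_axes: int | None = None) -> PhyloScores:
    """Classical metric scaling of a distance matrix.

    B = -1/2 C D^(2) C with C the centering projector; coordinates are
    eigenvectors scaled by sqrt(eigenvalue). Negative-eigenvalue axes are
    dropped with no correction. Each axis's first nonzero loading is made
    positive for reproducibility.
    """
    if isinstance(d, pd.DataFrame):
        labels = list(d.index)
        D = d.to_numpy(dtype=float)
    else:
        D = np.asarray(d, dtype=float)
        labels = [f"t{i}" for i in range(D.shape[0])]
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("d must be a square symmetric distance matrix")
    C = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * C @ (D**2) @ C
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > _EIG_TOL * max(abs(eigval).max(), 1.0)
    eigval, eigvec = eigval[pos], eigvec[:, pos]
    if n_axes is not None and n_axes > len(eigval):
        warnings.warn(
            f"requested {n_axes} axes but only {len(eigval)} positive eigenvalues; "
            "returning fewer",
            stacklevel=2,
        )
    k = len(eigval) if n_axes is None else min(n_axes, len(eigval))
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    for j in range(coords.shape[1]):
        nz = np.flatnonzero(np.abs(coords[:, j]) > 1e-12)
        if nz.size and coords[nz[0], j] < 0:
            coords[:, j] = -coords[:, j]
    scores = pd.DataFrame(
        coords, index=labels, columns=[f"axis{j + 1}" for j in range(k)]
    )
    total = eigval.sum()
    rel = eigval[:k] / total if total > 0 else np.zeros(k)
    return PhyloScores(scores, eigval[:k], rel)


def assign_species_scores(
    genus_scores: PhyloScores | pd.DataFrame, species_map: Mapping[str, str]
) -> pd.DataFrame:
    """Each species inherits the ordination coordinates of its genus.

    Species whose genus has no scores are excluded with a warning listing
    them.
    """
    table = genus_scores.scores if isinstance(genus_scores, PhyloScores) else genus_scores
    known = set(table.index)
    unmapped = sorted(sp for sp, g in species_map.items() if g not in known)
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} species with unmapped genus excluded: {unmapped[:10]}",
            stacklevel=2,
        )
    species = sorted(sp for sp in species_map if sp not in set(unmapped))
    out = table.loc[[species_map[sp] for sp in species]].copy()
    out.index = pd.Index(species, name="species")
    return out
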