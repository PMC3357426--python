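"""Cross-metagenome comparison on family-abundance profiles.

Profiles are assembled into a family x metagenome matrix (zero-filled over
the family union), compared by Spearman correlation distance
``d = 1 - rho``, clustered hierarchically (UPGMA by default, serialized as
Newick), embedded by classical (Torgerson) MDS, and exported as pairwise
scatter tables of biomass-modifying enzyme families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .io_formats import ValidationError
from .tiling_profile import FamilyProfile

FAMILY_CLASSES = ("GH", "GT", "CE", "PL", "CBM", "LO", "LDA")

# Glycoside hydrolase families acting on the critical polysaccharide bonds of
# hardwood (cellulose, xylan, glucomannan): endo/exo xylanases and
# glucuronosidases, mannanases/mannosidases, endo/exo cellulases and
# beta-glucosidases.  Together with the lignin-oxidase (LO) and auxiliary
# (LDA) classes they form the default "biomass" scatter set.
BIOMASS_GH_FAMILIES = frozenset(
    f"GH{n}" for n in (
        1, 2, 3, 5, 6, 7, 8, 9, 10, 11, 12, 26, 30, 39, 43, 44, 45, 48,
        51, 52, 54, 61, 67, 74, 113, 115, 116, 120, 124,
    )
)


def family_class(family: str) -> str:
    """Class of a (possibly composite) family label.

    Composite labels like ``GH94/GT84`` are classified by majority of their
    components' class prefixes; ties go to the first component.
    """
    classes = []
    for part in family.split("/"):
        for cls in sorted(FAMILY_CLASSES, key=len, reverse=True):
            if part.startswith(cls):
                classes.append(cls)
                break
        else:
            classes.append("other")
    counts = {c: classes.count(c) for c in classes}
    best = max(counts.values())
    top = [c for c in classes if counts[c] == best]
    return top[0]


def _in_biomass_set(family: str) -> bool:
    if family_class(family) in ("LO", "LDA"):
        return True
    return any(part in BIOMASS_GH_FAMILIES for part in family.split("/"))


@dataclass
class ProfileMatrix:
    """Family x metagenome per-million matrix with family classes."""

    data: pd.DataFrame               # index = families, columns = labels
    family_class: dict[str, str]

    def __post_init__(self):
        if (self.data.values < 0).any():
            raise ValidationError("negative profile values")

    @property
    def families(self) -> list[str]:
        return list(self.data.index)

    @property
    def labels(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        if (v < -1e-12).any() or (v > 2 + 1e-12).any():
            raise ValidationError("correlation distances must lie in [0, 2]")


def assemble_matrix(
    profiles: Sequence[FamilyProfile],
    family_filter: str = "all",
) -> ProfileMatrix:
    """Zero-filled per-million matrix over the profiles' family union.

    ``family_filter``: ``all`` keeps everything; ``gh_only`` keeps families
    whose class is GH (the default variable set for distance computation);
    ``biomass`` keeps the biomass-modifying set (hardwood-active GH families
    plus LO/LDA).
    """
    if len(profiles) < 2:
        raise ValidationError("need at least 2 profiles to compare")
    labels = [p.label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate profile labels")
    families = sorted({f for p in profiles for f in p.per_million})
    if family_filter == "gh_only":
        families = [f for f in families if family_class(f) == "GH"]
    elif family_filter == "biomass":
        families = [f for f in families if _in_biomass_set(f)]
    elif family_filter != "all":
        raise ValidationError(f"unknown family_filter {family_filter!r}")
    data = pd.DataFrame(
        {p.label: [p.per_million.get(f, 0.0) for f in families] for p in profiles},
        index=families,
    )
    return ProfileMatrix(data, {f: family_class(f) for f in families})


def spearman_distance(matrix: ProfileMatrix) -> DistanceMatrix:
    """Pairwise ``1 - rho`` (Spearman, average ranks for ties) of columns.

    A zero-variance column has undefined rank correlation; its pairwise
    distances are defined as 1 (rho = 0) with a warning.
    """
    df = matrix.data
    if df.shape[1] < 2:
        raise ValidationError("need >= 2 columns")
    if df.shape[0] < 3:
        raise ValidationError("need >= 3 families for a rank correlation")
    cols = df.columns
    n = len(cols)
    const = [c for c in cols if np.ptp(df[c].values) == 0]
    if const:
        warnings.warn(
            f"zero-variance profile column(s) {const}: Spearman rho set to 0",
            RuntimeWarning, stacklevel=2)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if cols[i] in const or cols[j] in const:
                rho = 0.0
            else:
                rho = float(stats.spearmanr(df.iloc[:, i], df.iloc[:, j]).statistic)
            d[i, j] = d[j, i] = 1.0 - rho
    return DistanceMatrix(list(cols), d)


def cluster(dist: DistanceMatrix, linkage: str = "average") -> str:
    """Agglomerative clustering of the distance matrix, as a Newick string.

    Heights follow the ultrametric convention (a join at cophenetic distance
    d sits at height d/2), so two leaves join with branch lengths d/2.
    """
    if linkage not in ("average", "complete", "single"):
        raise ValidationError(f"unknown linkage {linkage!r}")
    Z = hierarchy.linkage(squareform(dist.values, checks=False), method=linkage)
    root = hierarchy.to_tree(Z)

    def build(node) -> TreeNode:
        if node.is_leaf():
            t = TreeNode(name=dist.labels[node.id])
            t._height = 0.0
            return t
        left, right = build(node.left), build(node.right)
        t = TreeNode(children=[left, right])
        t._height = node.dist / 2.0
        for child in t.children:
            child.length = t._height - child._height
        return t

    tree = build(root)
    tree.length = None
    return str(tree).strip()


def mds(dist: DistanceMatrix, k: int = 2) -> dict[str, np.ndarray]:
    """Classical (Torgerson) MDS of a distance matrix.

    Axes are ordered by eigenvalue; negative eigenvalues contribute zero
    coordinates.  For determinism each axis is oriented so its first nonzero
    coordinate is positive.
    """
    n = len(dist.labels)
    if n < 3:
        raise ValidationError("need >= 3 labels for an MDS embedding")
    if k >= n:
        raise ValidationError("k must be smaller than the number of labels")
    D2 = dist.values ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:k]
    lam = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)[None, :]
    for axis in range(k):
        col = coords[:, axis]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, axis] = -col
    return {label: coords[i].copy() for i, label in enumerate(dist.labels)}


def pairwise_scatter(
    matrix: ProfileMatrix,
    label_a: str,
    label_b: str,
    family_filter: str = "biomass",
) -> list[tuple[str, float, float, str]]:
    """Per-family value pairs for a two-metagenome scatter plot.

    Zero-valued families are included so absences (e.g. lignin-oxidase
    families in gut-like profiles) stay visible.
    """
    for lab in (label_a, label_b):
        if lab not in matrix.data.columns:
            raise ValidationError(f"unknown label {lab!r}")
    if family_filter == "biomass":
        fams = [f for f in matrix.families if _in_biomass_set(f)]
    elif family_filter == "gh_only":
        fams = [f for f in matrix.families if family_class(f) == "GH"]
    elif family_filter == "all":
        fams = matrix.families
    else:
        raise ValidationError(f"unknown family_filter {family_filter!r}")
    return [
        (f, float(matrix.data.at[f, label_a]), float(matrix.data.at[f, label_b]),
         matrix.family_class[f])
        for f in fams
    ]
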