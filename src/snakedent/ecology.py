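"""Prey-subjugation and diet data: coding, diet network, dissimilarity,
and the phylogenetic Mantel association between diet and dentition.

Prey-subjugation mode uses a closed five-category vocabulary
(medically-significant venom, non-medically-significant venom,
constriction, both, neither; "unknown" is accepted on input so the study
filter can remove it).  Diet is recorded as counts of prey observations
in 11 fixed categories; the bipartite diet graph connects each species to
the categories it consumes with edge weights equal to the fraction of its
records in that category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .tree import Phylogeny

__all__ = [
    "DIET_CATEGORIES",
    "SUBJUGATION_MODES",
    "FANG_STATES_3",
    "FANG_STATES_4",
    "read_ecology_table",
    "write_ecology_table",
    "build_diet_graph",
    "main_prey_item",
    "dissimilarity_matrix",
    "phylo_mantel",
    "MantelResult",
]

DIET_CATEGORIES = [
    "reptiles",
    "reptile_eggs",
    "birds",
    "bird_eggs",
    "mammals",
    "fishes",
    "amphibians",
    "annelids",
    "arthropods",
    "mollusks",
    "other",
]

SUBJUGATION_MODES = ["venom-MS", "venom-NMS", "constriction", "both", "neither"]
FANG_STATES_3 = ["unmodified", "grooved", "hollow"]
FANG_STATES_4 = ["unmodified", "grooved", "hollow", "tubular"]

ECOLOGY_COLUMNS = ["species", "mode", "fang_state", *DIET_CATEGORIES]


def read_ecology_table(path) -> pd.DataFrame:
    """Read and validate a per-species ecology CSV.

    Columns: species, mode, fang_state, then the 11 diet-count columns in
    fixed order.  Modes and fang states must come from the closed
    vocabularies ("unknown" is allowed for mode).
    """
    df = pd.read_csv(path)
    missing = [c for c in ECOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ecology table missing columns: {', '.join(missing)}")
    bad_modes = set(df["mode"].dropna()) - set(SUBJUGATION_MODES) - {"unknown"}
    if bad_modes:
        raise ValueError(f"unknown subjugation modes: {sorted(bad_modes)}")
    bad_states = set(df["fang_state"].dropna()) - set(FANG_STATES_4)
    if bad_states:
        raise ValueError(f"unknown fang states: {sorted(bad_states)}")
    counts = df[DIET_CATEGORIES]
    if (counts.fillna(0) < 0).any().any():
        raise ValueError("negative diet counts")
    df[DIET_CATEGORIES] = counts.fillna(0).astype(int)
    return df.set_index("species")


def write_ecology_table(df: pd.DataFrame, path) -> None:
    df.reset_index().to_csv(path, index=False, columns=ECOLOGY_COLUMNS)


def build_diet_graph(table: pd.DataFrame) -> nx.Graph:
    """Bipartite species-by-prey-category graph.

    Edge weight = fraction of the species' diet records in that category;
    species with no diet records are excluded with a warning.
    """
    unknown = [c for c in table.columns if c in table.columns[3:] and c not in DIET_CATEGORIES and c not in ("mode", "fang_state")]
    if unknown:
        raise ValueError(f"unknown diet categories: {unknown}")
    missing = [c for c in DIET_CATEGORIES if c not in table.columns]
    if missing:
        raise ValueError(f"missing diet categories: {missing}")
    G = nx.Graph()
    dropped = []
    any_records = False
    for species, row in table.iterrows():
        total = float(row[DIET_CATEGORIES].sum())
        if total == 0:
            dropped.append(species)
            continue
        any_records = True
        G.add_node(species, bipartite="species")
        for cat in DIET_CATEGORIES:
            if row[cat] > 0:
                G.add_node(cat, bipartite="prey")
                G.add_edge(species, cat, weight=float(row[cat]) / total)
    if dropped:
        warnings.warn(
            f"species with no diet records excluded from diet graph: {dropped}"
        )
    if not any_records:
        raise ValueError("no species with diet records")
    return G


def main_prey_item(counts) -> str:
    """Most commonly observed prey category.

    Ties are broken by the fixed category order (and flagged with a
    warning).
    """
    if isinstance(counts, pd.Series):
        counts = counts.to_dict()
    unknown = set(counts) - set(DIET_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown diet categories: {sorted(unknown)}")
    vals = {c: counts.get(c, 0) for c in DIET_CATEGORIES}
    top = max(vals.values())
    if top <= 0:
        raise ValueError("all diet counts are zero")
    winners = [c for c in DIET_CATEGORIES if vals[c] == top]
    if len(winners) > 1:
        warnings.warn(f"tie for main prey item among {winners}; using {winners[0]}")
    return winners[0]


def dissimilarity_matrix(
    rows: pd.DataFrame, metric: str = "euclidean"
) -> pd.DataFrame:
    """Pairwise species dissimilarity from numeric trait/diet vectors.

    ``metric="euclidean"`` is the usual L2 distance; ``"gower"`` is the
    range-normalized mean absolute difference (columns with zero range
    carry no information and are dropped with a warning).
    """
    X = rows.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("dissimilarity input contains missing values")
    labels = list(rows.index)
    if metric == "euclidean":
        diff = X[:, None, :] - X[None, :, :]
        D = np.sqrt((diff**2).sum(axis=2))
    elif metric == "gower":
        rng = X.max(axis=0) - X.min(axis=0)
        keep = rng > 0
        if not keep.all():
            dropped = [c for c, k in zip(rows.columns, keep) if not k]
            warnings.warn(f"constant columns dropped under Gower: {dropped}")
        if not keep.any():
            raise ValueError("all columns constant under Gower metric")
        Xk = X[:, keep] / rng[keep]
        diff = np.abs(Xk[:, None, :] - Xk[None, :, :])
        D = diff.mean(axis=2)
    else:
        raise ValueError("metric must be 'euclidean' or 'gower'")
    return pd.DataFrame(D, index=labels, columns=labels)


@dataclass
class MantelResult:
    """Mantel association between two distance matrices."""

    r: float
    p_value: float
    n_permutations: int
    scheme: str
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "scheme": self.scheme,
            "seed": self.seed,
        }


def _as_matrix(D, name: str) -> tuple[np.ndarray, list | None]:
    if isinstance(D, pd.DataFrame):
        return D.to_numpy(dtype=float), list(D.index)
    return np.asarray(D, dtype=float), None


def phylo_mantel(
    tree: Phylogeny | None,
    D1,
    D2,
    nperm: int = 999,
    scheme: str = "free",
    seed: int | None = None,
) -> MantelResult:
    """Mantel correlation of two distance matrices with a permutation null.

    ``r`` is the Pearson correlation of the lower triangles.  The null is
    built by permuting the species labels of ``D2``: either freely
    (``scheme="free"``) or with phylogenetically weighted swaps in which
    the probability of exchanging two species decays as
    ``exp(-d_patristic / tau)`` with ``tau`` the median patristic distance
    (``scheme="phylo"``, requires the tree).  The p-value is two-sided on
    ``|r|`` with the add-one rule.
    """
    M1, lab1 = _as_matrix(D1, "D1")
    M2, lab2 = _as_matrix(D2, "D2")
    if M1.shape != M2.shape or M1.ndim != 2 or M1.shape[0] != M1.shape[1]:
        raise ValueError("distance matrices must be square and of equal shape")
    if lab1 is not None and lab2 is not None and lab1 != lab2:
        raise ValueError("distance matrices have different species orders")
    if nperm < 99:
        raise ValueError("nperm must be at least 99")
    if scheme == "phylo" and tree is None:
        raise ValueError("phylo scheme requires a tree")
    if scheme not in ("free", "phylo"):
        raise ValueError("scheme must be 'free' or 'phylo'")
    n = M1.shape[0]
    tril = np.tril_indices(n, k=-1)

    def corr(a_flat, b_flat):
        return float(np.corrcoef(a_flat, b_flat)[0, 1])

    v1 = M1[tril]
    r_obs = corr(v1, M2[tril])
    rng = np.random.default_rng(seed)

    if scheme == "free":
        def draw_perm():
            return rng.permutation(n)
    else:  # phylo-weighted swaps
        labels = lab1 or lab2 or tree.tip_labels
        if set(labels) != set(tree.tip_labels):
            raise ValueError("matrix labels do not match tree tips")
        P = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                P[i, j] = P[j, i] = tree.patristic_distance(labels[i], labels[j])
        tau = float(np.median(P[tril]))
        W = np.exp(-P / tau)
        np.fill_diagonal(W, 0.0)
        W = W / W.sum(axis=1, keepdims=True)

        def draw_perm():
            perm = np.arange(n)
            for _ in range(n):
                i = int(rng.integers(n))
                j = int(rng.choice(n, p=W[i]))
                perm[i], perm[j] = perm[j], perm[i]
            return perm

    exceed = 0
    for _ in range(nperm):
        perm = draw_perm()
        r_p = corr(v1, M2[np.ix_(perm, perm)][tril])
        if abs(r_p) >= abs(r_obs):
            exceed += 1
    p = (exceed + 1) / (nperm + 1)
    return MantelResult(
        r=r_obs, p_value=float(p), n_permutations=nperm, scheme=scheme, seed=seed
    )
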