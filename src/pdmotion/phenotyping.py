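"""Patient phenotype discovery and characterization.

Two clustering routes over the standardized metric space: a visualization
route (t-SNE embedding followed by K-means) and the primary route — a
self-organizing map (SOM) whose neuron weights are then merged by Ward
hierarchical clustering, with subjects inheriting the cluster of their
best-matching unit (BMU). Clusters are characterized by random-forest
out-of-bag permutation importance and by a dominance table that counts,
per feature, the cluster pairs in which a cluster holds the highest median
after ANOVA + Bonferroni screening. A ratio-based clinical subtyping of
the UPDRS-III exam (tremor-dominant / akinetic-rigid / mixed) provides the
comparison partition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import adjusted_rand_score, silhouette_score
from sklearn.tree import DecisionTreeClassifier

from pdmotion.errors import ConfigError, ValidationError

#: Ratio thresholds for clinical subtyping: tremor-dominant above the
#: first, akinetic-rigid below the second, mixed in between.
SUBTYPE_THRESHOLDS = (1.5, 1.0 / 1.5)
TREMOR_ITEMS = ("Q20", "Q21")
AKINETIC_ITEMS = ("Q22", "Q23", "Q24", "Q25", "Q26", "Q31")


@dataclass
class ClusterAssignment:
    """Subject -> cluster labels (1..k) from one clustering method."""

    labels: np.ndarray
    k: int
    method: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)


# ---------------------------------------------------------------------------
# t-SNE + K-means
# ---------------------------------------------------------------------------


def tsne_kmeans(
    X: np.ndarray,
    k: int = 3,
    perplexity: float = 30.0,
    learning_rate: float = 200.0,
    max_iter: int = 1000,
    seed: int = 0,
) -> tuple[ClusterAssignment, np.ndarray]:
    """2D t-SNE embedding followed by K-means (10 restarts, best inertia).

    The conventional guidance n > 3*perplexity is relaxed to
    n > perplexity with a warning, matching desk-scale cohorts.
    Returns (assignment, embedding).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValidationError(f"k={k} exceeds n={n}")
    perp = perplexity
    if n <= perplexity:
        perp = max((n - 1) / 3.0, 2.0)
        warnings.warn(
            f"perplexity {perplexity} >= n={n}; reduced to {perp:.1f}", stacklevel=2
        )
    elif n <= 3 * perplexity:
        warnings.warn(
            f"n={n} below the conventional 3*perplexity={3 * perplexity:.0f}; "
            "embedding may be unstable",
            stacklevel=2,
        )
    emb = TSNE(
        n_components=2,
        perplexity=perp,
        learning_rate=learning_rate,
        max_iter=max_iter,
        init="pca",
        random_state=seed,
    ).fit_transform(X)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(emb)
    return ClusterAssignment(km.labels_ + 1, k, "tsne_kmeans"), emb


# ---------------------------------------------------------------------------
# Self-organizing map
# ---------------------------------------------------------------------------


@dataclass
class SOMModel:
    """Rectangular-topology SOM with Gaussian neighbourhood.

    ``weights`` has shape (rows*cols, n_features); grid coordinates are
    row-major. QE (quantization error) is the mean Euclidean distance of
    training samples to their best-matching unit.
    """

    rows: int
    cols: int
    weights: np.ndarray
    qe: float = math.nan
    config: dict = field(default_factory=dict)

    @property
    def grid_coords(self) -> np.ndarray:
        rr, cc = np.meshgrid(np.arange(self.rows), np.arange(self.cols), indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)

    def bmu(self, X: np.ndarray) -> np.ndarray:
        """Index of the best-matching unit for each sample."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d = np.linalg.norm(X[:, None, :] - self.weights[None, :, :], axis=2)
        return d.argmin(axis=1)

    def quantization_error(self, X: np.ndarray) -> float:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d = np.linalg.norm(X[:, None, :] - self.weights[None, :, :], axis=2)
        return float(d.min(axis=1).mean())


def som_fit(
    X: np.ndarray,
    rows: int,
    cols: int,
    epochs: int,
    initial_neighborhood: float,
    seed: int | np.random.SeedSequence = 0,
    lr_start: float = 0.5,
    lr_end: float = 0.01,
    init_weights: Optional[np.ndarray] = None,
) -> SOMModel:
    """Train one SOM by online updates.

    Random weight initialization from N(0, 1) per (standardized) feature;
    Gaussian neighbourhood whose radius decays linearly from
    ``initial_neighborhood`` to 1 over training, learning rate linear from
    ``lr_start`` to ``lr_end``. One epoch visits every sample once in a
    shuffled order.
    """
    X = np.asarray(X, dtype=float)
    if rows < 1 or cols < 1 or rows * cols < 1:
        raise ConfigError("SOM grid must be at least 1x1")
    n, p = X.shape
    rng = np.random.default_rng(seed)
    if init_weights is not None:
        weights = np.array(init_weights, dtype=float, copy=True)
        if weights.shape != (rows * cols, p):
            raise ConfigError("init_weights shape mismatch")
    else:
        weights = rng.standard_normal((rows * cols, p))
    coords = np.stack(
        np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij"), axis=-1
    ).reshape(-1, 2).astype(float)

    total_steps = max(epochs * n, 1)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n)
        for i in order:
            frac = step / total_steps
            lr = lr_start + (lr_end - lr_start) * frac
            radius = max(initial_neighborhood + (1.0 - initial_neighborhood) * frac, 1e-9)
            x = X[i]
            b = int(np.argmin(np.linalg.norm(weights - x, axis=1)))
            d2 = ((coords - coords[b]) ** 2).sum(axis=1)
            h = np.exp(-d2 / (2.0 * radius**2))
            weights += (lr * h)[:, None] * (x - weights)
            step += 1
    model = SOMModel(rows, cols, weights, config={
        "epochs": epochs, "initial_neighborhood": initial_neighborhood,
        "lr": (lr_start, lr_end),
    })
    model.qe = model.quantization_error(X)
    return model


def train_som(
    X: np.ndarray,
    grid_sizes: Sequence[tuple[int, int]] = ((6, 6),),
    epochs_list: Sequence[int] = (50,),
    neighborhood_list: Sequence[float] = (2.0, 3.0),
    restarts: int = 10,
    seed: int = 0,
) -> SOMModel:
    """Search over grid sizes, epochs and initial neighbourhoods; each
    configuration is trained ``restarts`` times from different random
    initializations and the lowest-QE model over everything is returned."""
    if not grid_sizes or not epochs_list or not neighborhood_list:
        raise ConfigError("empty SOM search lists")
    root = np.random.SeedSequence(seed)
    best: Optional[SOMModel] = None
    for rows, cols in grid_sizes:
        for epochs in epochs_list:
            for radius in neighborhood_list:
                for child in root.spawn(restarts):
                    model = som_fit(X, rows, cols, epochs, radius, seed=child)
                    if best is None or model.qe < best.qe:
                        best = model
    assert best is not None
    return best


def ward_cut(
    som: SOMModel, X: np.ndarray, k_list: Sequence[int] = (2, 3, 4)
) -> dict[int, ClusterAssignment]:
    """Ward-linkage hierarchical clustering of the SOM neuron weights.

    The dendrogram is cut at each requested k; subjects inherit the
    cluster of their best-matching unit. Cuts of one dendrogram are nested
    across k by construction.
    """
    Z = linkage(som.weights, method="ward")
    bmus = som.bmu(X)
    out: dict[int, ClusterAssignment] = {}
    for k in k_list:
        if k > som.weights.shape[0]:
            raise ValidationError(f"k={k} exceeds {som.weights.shape[0]} neurons")
        node_labels = fcluster(Z, t=k, criterion="maxclust")
        out[k] = ClusterAssignment(node_labels[bmus], k, "som_ward")
    return out


# ---------------------------------------------------------------------------
# Random-forest importance (out-of-bag permutation)
# ---------------------------------------------------------------------------


def _forest_oob_importance(
    X: np.ndarray, y: np.ndarray, n_trees: int, rng: np.random.Generator
) -> np.ndarray:
    """Breiman-style OOB permutation importance for one bagged forest.

    Each tree is fit on a bootstrap sample; its out-of-bag accuracy is
    compared with the accuracy after permuting one feature among the OOB
    rows; the importance of the feature is the mean accuracy drop over
    trees. Only features actually split on by a tree are permuted (others
    contribute an exact zero drop).
    """
    n, p = X.shape
    drops = np.zeros((n_trees, p))
    for t in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0:
            continue
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(X[boot], y[boot])
        base = (tree.predict(X[oob]) == y[oob]).mean()
        used = np.flatnonzero(tree.feature_importances_ > 0)
        X_oob = X[oob]
        for j in used:
            Xp = X_oob.copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            drops[t, j] = base - (tree.predict(Xp) == y[oob]).mean()
    return drops.mean(axis=0)


def rf_importance(
    X: np.ndarray,
    labels: np.ndarray,
    n_seeds: int = 10,
    n_trees: int = 500,
    top: int = 10,
    feature_names: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature importance for a clustering, averaged over ``n_seeds``
    classification forests with out-of-bag permutation importance.

    Returns the ``top`` features ranked by mean importance, with the mean
    and SD across seeds.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValidationError("random-forest importance needs >= 2 clusters")
    p = X.shape[1]
    names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(p)]
    root = np.random.SeedSequence(seed)
    scores = np.stack(
        [
            _forest_oob_importance(X, labels, n_trees, np.random.default_rng(child))
            for child in root.spawn(n_seeds)
        ]
    )
    mean = scores.mean(axis=0)
    order = np.argsort(mean)[::-1][:top]
    return pd.DataFrame(
        {
            "feature": [names[j] for j in order],
            "importance_mean": mean[order],
            "importance_sd": scores.std(axis=0, ddof=1)[order] if n_seeds > 1 else 0.0,
        }
    )


# ---------------------------------------------------------------------------
# Dominance table
# ---------------------------------------------------------------------------


@dataclass
class DominanceTable:
    """Counts of pairwise highest-median wins per (feature, cluster)."""

    counts: pd.DataFrame          # features x clusters
    anova_p: pd.Series            # per feature
    significant_pairs: dict[str, list[tuple[int, int]]]


def dominance(
    X: np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.05,
    feature_names: Optional[Sequence[str]] = None,
) -> DominanceTable:
    """Feature dominance across clusters.

    Per feature: one-way ANOVA across clusters; when p < ``alpha``,
    pairwise two-sample t-tests with Bonferroni correction over the number
    of cluster pairs; for each significant pair the cluster with the higher
    feature median gains one win. Features with degenerate within-cluster
    variance are skipped.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValidationError("dominance needs >= 2 clusters")
    for c in clusters:
        if (labels == c).sum() < 2:
            raise ValidationError(f"cluster {c} has fewer than 2 members")
    p_feats = X.shape[1]
    names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(p_feats)]
    pairs = [(int(a), int(b)) for i, a in enumerate(clusters) for b in clusters[i + 1:]]
    n_pairs = len(pairs)

    counts = pd.DataFrame(0, index=names, columns=[int(c) for c in clusters])
    anova_p = pd.Series(np.nan, index=names)
    sig_pairs: dict[str, list[tuple[int, int]]] = {}
    for j, name in enumerate(names):
        groups = [X[labels == c, j] for c in clusters]
        if all(np.ptp(g) == 0 for g in groups):
            continue
        with np.errstate(invalid="ignore"):
            p_anova = stats.f_oneway(*groups).pvalue
        anova_p[name] = p_anova
        if not (p_anova < alpha):
            continue
        sig: list[tuple[int, int]] = []
        for a, b in pairs:
            ga, gb = X[labels == a, j], X[labels == b, j]
            p_pair = stats.ttest_ind(ga, gb).pvalue * n_pairs
            if p_pair < alpha:
                sig.append((a, b))
                winner = a if np.median(ga) >= np.median(gb) else b
                counts.loc[name, winner] += 1
        if sig:
            sig_pairs[name] = sig
    return DominanceTable(counts=counts, anova_p=anova_p, significant_pairs=sig_pairs)


# ---------------------------------------------------------------------------
# Clinical subtyping and partition comparison
# ---------------------------------------------------------------------------


def subtype_ratio(items: dict[str, int]) -> float:
    """Tremor / akinetic-rigid item-score ratio (inf if denominator 0
    with a positive numerator, 1 if both are 0)."""
    num = float(np.mean([items[q] for q in TREMOR_ITEMS]))
    den = float(np.mean([items[q] for q in AKINETIC_ITEMS]))
    if den == 0:
        return math.inf if num > 0 else 1.0
    return num / den


def eggers_classify(
    items: dict[str, int],
    thresholds: tuple[float, float] = SUBTYPE_THRESHOLDS,
) -> str:
    """Clinical motor subtype from UPDRS-III item ratios:
    ``tremor_dominant`` when the tremor/akinetic ratio is at or above the
    upper threshold, ``akinetic_rigid`` at or below the lower, else
    ``mixed``."""
    missing = [q for q in (*TREMOR_ITEMS, *AKINETIC_ITEMS) if q not in items]
    if missing:
        raise ValidationError(f"UPDRS exam missing items {missing}")
    upper, lower = thresholds
    ratio = subtype_ratio(items)
    if ratio >= upper:
        return "tremor_dominant"
    if ratio <= lower:
        return "akinetic_rigid"
    return "mixed"


def classify_cohort(updrs: pd.DataFrame) -> ClusterAssignment:
    """Subtype every subject of a cohort UPDRS table; labels are encoded
    1=tremor_dominant, 2=akinetic_rigid, 3=mixed."""
    coding = {"tremor_dominant": 1, "akinetic_rigid": 2, "mixed": 3}
    labels = [
        coding[eggers_classify({q: int(row[q]) for q in (*TREMOR_ITEMS, *AKINETIC_ITEMS)})]
        for _, row in updrs.iterrows()
    ]
    return ClusterAssignment(np.asarray(labels), 3, "clinical_subtype")


def compare_partitions(
    a: ClusterAssignment, b: ClusterAssignment, X: np.ndarray
) -> dict:
    """Adjusted Rand index, cross-tabulation, and silhouette of each
    partition in the standardized metric space ``X``."""
    if a.labels.size != b.labels.size:
        raise ValidationError("partitions cover different subjects")
    X = np.asarray(X, dtype=float)

    def _sil(labels: np.ndarray) -> float:
        if np.unique(labels).size < 2:
            return math.nan
        return float(silhouette_score(X, labels))

    return {
        "ari": float(adjusted_rand_score(a.labels, b.labels)),
        "contingency": pd.crosstab(
            pd.Series(a.labels, name=a.method), pd.Series(b.labels, name=b.method)
        ),
        "silhouette_a": _sil(a.labels),
        "silhouette_b": _sil(b.labels),
    }
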