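"""Mixture discriminant analysis of surface feature matrices.

Pretreatment discrimination works on an observations × parameters matrix
(ionic block: per-ion aggregate count / total area / mean size / coverage;
anatomical block: entropy, roughness, waviness, periodicity, excavations).
The classifier is Mixture Discriminant Analysis (MDA): each class
(pretreatment) is a Gaussian mixture of R subclasses sharing one
within-class covariance across all subclasses and classes, fitted by EM
with known class labels.  With R = 1 the model collapses to linear
discriminant analysis.

Downstream of the fit:

* class centroids are projected onto discriminant axes (whitened-centroid
  principal axes); their 1-D order along the first axis is the *similarity
  string* of pretreatment names — neighbors in the string are more alike
  than distant entries;
* a *binary neighbor matrix* assigns 1 to adjacent names in the string
  (optionally only within groups of statistically indistinguishable
  treatments, see ``n_permutations``) and 0 elsewhere;
* averaging such matrices gives a similarity whose complement is clustered
  (average linkage) into a pretreatment tree;
* column-wise jackknifing (leave one parameter or parameter group out,
  refit, measure the drop in discrimination score) attributes importance
  to each parameter group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from ._rng import child_rng, child_seed

__all__ = [
    "FeatureMatrix",
    "MDAModel",
    "DiscriminationResult",
    "DendroTree",
    "assemble_features",
    "mda_fit",
    "discriminate",
    "build_tree",
    "jackknife_importance",
]


# --- feature assembly -------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Standardized observations × parameters table with block membership."""

    X: pd.DataFrame
    blocks: dict[str, str]
    means: pd.Series | None = None
    stds: pd.Series | None = None

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    def block_columns(self, block: str) -> list[str]:
        return [c for c, b in self.blocks.items() if b == block]

    def values(self) -> np.ndarray:
        return self.X.to_numpy(float)


def assemble_features(
    particle_stats: pd.DataFrame | None,
    surface_metrics: pd.DataFrame | None = None,
    coverage_stats: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Join ionic, anatomical and coverage tables into one z-scored matrix.

    All inputs are observation-indexed DataFrames over the *same*
    observation set (treatment × replicate field).  Ionic and coverage
    columns are prefixed ``ion__``, anatomical columns ``anat__``; every
    column is standardized to zero mean / unit variance; zero-variance
    columns are dropped with a warning.
    """
    parts: list[tuple[pd.DataFrame, str, str]] = []
    if particle_stats is not None:
        parts.append((particle_stats, "ionic", "ion__"))
    if coverage_stats is not None:
        parts.append((coverage_stats, "ionic", "ion__"))
    if surface_metrics is not None:
        parts.append((surface_metrics, "anatomical", "anat__"))
    if not parts:
        raise ValueError("no feature tables given")
    index = parts[0][0].index
    frames = []
    blocks: dict[str, str] = {}
    for df, block, prefix in parts:
        if set(df.index) != set(index) or len(df) != len(index):
            raise ValueError("feature tables must share one observation set")
        df = df.loc[index]
        if df.isna().any().any():
            raise ValueError("missing values in feature table")
        renamed = df.add_prefix(prefix)
        frames.append(renamed)
        for c in renamed.columns:
            if c in blocks:
                raise ValueError(f"duplicate column name {c!r}")
            blocks[c] = block
    X = pd.concat(frames, axis=1).astype(float)
    means = X.mean()
    stds = X.std(ddof=0)
    dead = stds[stds == 0.0].index
    if len(dead):
        warnings.warn(f"dropping zero-variance columns: {list(dead)}", stacklevel=2)
        X = X.drop(columns=dead)
        for c in dead:
            blocks.pop(c)
        means, stds = means.drop(dead), stds.drop(dead)
    Z = (X - means) / stds
    return FeatureMatrix(Z, blocks, means, stds)


# --- the MDA model ----------------------------------------------------------


def _as_matrix(features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, FeatureMatrix):
        return features.values(), features.columns
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(float), list(features.columns)
    arr = np.asarray(features, dtype=float)
    return arr, [f"x{i}" for i in range(arr.shape[1])]


@dataclass
class MDAModel:
    """Per-class Gaussian mixtures with one shared within-class covariance."""

    classes_: list
    priors: np.ndarray
    weights: list[np.ndarray]  # subclass mixing weights per class (simplex)
    means: list[np.ndarray]  # per class, (R_k, q)
    cov: np.ndarray  # shared covariance in model space, (q, q)
    ridge_eps: float
    loglik_trace: list[float]
    projection: np.ndarray | None  # (p, q) basis when the input was reduced
    center: np.ndarray
    feature_names: list[str]
    train_X: np.ndarray  # original-space training rows
    train_labels: np.ndarray
    n_subclasses: int
    seed: int

    def _to_model_space(self, X: np.ndarray) -> np.ndarray:
        Z = X - self.center
        return Z @ self.projection if self.projection is not None else Z

    def _class_loglik(self, X: np.ndarray) -> np.ndarray:
        """(n, K) log density of each row under each class mixture."""
        Z = self._to_model_space(np.asarray(X, dtype=float))
        q = Z.shape[1]
        chol = np.linalg.cholesky(self.cov)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        const = -0.5 * (q * np.log(2.0 * np.pi) + logdet)
        out = np.empty((Z.shape[0], len(self.classes_)))
        for k in range(len(self.classes_)):
            comp = np.empty((Z.shape[0], len(self.weights[k])))
            for r, mu in enumerate(self.means[k]):
                diff = Z - mu
                sol = np.linalg.solve(chol, diff.T)
                comp[:, r] = np.log(self.weights[k][r] + 1e-300) + const - 0.5 * (sol**2).sum(axis=0)
            out[:, k] = logsumexp(comp, axis=1)
        return out

    def predict(self, X) -> np.ndarray:
        Xa, _ = _as_matrix(X)
        scores = self._class_loglik(Xa) + np.log(self.priors)
        idx = np.argmax(scores, axis=1)
        return np.asarray([self.classes_[i] for i in idx])

    def score(self, X=None, labels=None) -> float:
        """Classification accuracy (defaults to the training data)."""
        if X is None:
            Xa, labels = self.train_X, self.train_labels
        else:
            Xa, _ = _as_matrix(X)
        pred = self.predict(Xa)
        return float(np.mean(pred == np.asarray(labels)))

    def class_centroids(self) -> np.ndarray:
        """Class-level mixture means in model space, (K, q)."""
        return np.stack([w @ m for w, m in zip(self.weights, self.means)])

    def discriminant_coords(self) -> np.ndarray:
        """Class centroids projected on discriminant axes, (K, min(K-1, q))."""
        C = self.class_centroids()
        evals, evecs = np.linalg.eigh(self.cov)
        evals = np.maximum(evals, 1e-12)
        W = evecs @ np.diag(evals**-0.5) @ evecs.T  # whitening
        Cw = C @ W
        mean = self.priors @ Cw
        B = (Cw - mean).T @ np.diag(self.priors) @ (Cw - mean)
        bvals, bvecs = np.linalg.eigh(B)
        order = np.argsort(bvals)[::-1]
        ndim = min(len(self.classes_) - 1, Cw.shape[1])
        V = bvecs[:, order[:ndim]]
        return (Cw - mean) @ V


def mda_fit(
    features,
    labels,
    n_subclasses: int = 3,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
    ridge_scale: float = 1e-6,
) -> MDAModel:
    """Fit MDA by EM: per-class Gaussian mixtures, one shared covariance.

    Initialization is k-means (k-means++ seeding) within each class,
    derived deterministically from ``seed``.  Convergence when the
    log-likelihood gain drops below ``tol`` (or ``max_iter``).  The shared
    covariance always receives a ridge ``ridge_scale * trace(cov)/q`` for
    numerical safety; when there are more parameters than the within-class
    scatter can support, the data are first reduced to their principal
    subspace (the projection is stored and applied at prediction).
    A class with fewer rows than ``n_subclasses`` gets one subclass per row.
    """
    X, names = _as_matrix(features)
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    n, p = X.shape
    K = len(classes)
    if n < K:
        raise ValueError("fewer rows than classes")
    counts = np.array([(y == c).sum() for c in classes], dtype=float)
    if (counts < 1).any():
        raise ValueError("degenerate class with no rows")
    priors = counts / n

    center = X.mean(axis=0)
    Z0 = X - center
    projection = None
    max_rank = max(1, n - K)
    if p > max_rank:
        # principal-subspace reduction keeps the within-scatter invertible
        _, s, vt = np.linalg.svd(Z0, full_matrices=False)
        keep = min(max_rank, int((s > 1e-10 * max(s[0], 1e-300)).sum()))
        keep = max(keep, 1)
        projection = vt[:keep].T
    Z = Z0 @ projection if projection is not None else Z0
    q = Z.shape[1]

    # --- init: k-means within each class
    means: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    resp: list[np.ndarray] = []
    for k, c in enumerate(classes):
        rows = Z[y == c]
        r_k = int(min(n_subclasses, rows.shape[0]))
        if r_k == 1:
            assign = np.zeros(rows.shape[0], dtype=int)
        else:
            km = KMeans(n_clusters=r_k, n_init=1, random_state=child_seed(seed, "init", k))
            assign = km.fit_predict(rows)
        mu = np.stack([
            rows[assign == r].mean(axis=0) if (assign == r).any() else rows.mean(axis=0)
            for r in range(r_k)
        ])
        w = np.array([(assign == r).sum() for r in range(r_k)], dtype=float)
        w = np.maximum(w, 1e-3)
        means.append(mu)
        weights.append(w / w.sum())
        R = np.zeros((rows.shape[0], r_k))
        R[np.arange(rows.shape[0]), assign] = 1.0
        resp.append(R)

    def shared_cov() -> np.ndarray:
        S = np.zeros((q, q))
        for k, c in enumerate(classes):
            rows = Z[y == c]
            for r in range(means[k].shape[0]):
                d = rows - means[k][r]
                S += (resp[k][:, r][:, None] * d).T @ d
        S /= n
        eps = ridge_scale * max(np.trace(S), 1e-12) / q
        return S + eps * np.eye(q), eps

    cov, eps = shared_cov()
    trace: list[float] = []
    for _ in range(max_iter):
        # E-step
        chol = np.linalg.cholesky(cov)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        const = -0.5 * (q * np.log(2.0 * np.pi) + logdet)
        ll = 0.0
        for k, c in enumerate(classes):
            rows = Z[y == c]
            r_k = means[k].shape[0]
            comp = np.empty((rows.shape[0], r_k))
            for r in range(r_k):
                sol = np.linalg.solve(chol, (rows - means[k][r]).T)
                comp[:, r] = np.log(weights[k][r] + 1e-300) + const - 0.5 * (sol**2).sum(axis=0)
            norm = logsumexp(comp, axis=1)
            ll += float(norm.sum())
            resp[k] = np.exp(comp - norm[:, None])
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            break
        # M-step
        for k, c in enumerate(classes):
            rows = Z[y == c]
            nk = resp[k].sum(axis=0)
            nk = np.maximum(nk, 1e-10)
            means[k] = (resp[k].T @ rows) / nk[:, None]
            weights[k] = nk / nk.sum()
        cov, eps = shared_cov()

    return MDAModel(
        classes_=classes, priors=priors, weights=weights, means=means, cov=cov,
        ridge_eps=eps, loglik_trace=trace, projection=projection, center=center,
        feature_names=names, train_X=X, train_labels=y,
        n_subclasses=n_subclasses, seed=seed,
    )


# --- discrimination result ---------------------------------------------------


@dataclass
class DiscriminationResult:
    """Similarity string, neighbor matrix and training accuracy of one fit."""

    string: list[str]
    binary_matrix: pd.DataFrame
    groups: list[list[str]]
    accuracy: float
    pair_pvalues: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        M = self.binary_matrix.to_numpy()
        if not np.array_equal(M, M.T) or np.diag(M).any():
            raise ValueError("binary matrix must be symmetric with zero diagonal")
        if (M.sum(axis=1) > 2).any():
            raise ValueError("binary matrix row sums must be <= 2")
        if sorted(self.string) != sorted(self.binary_matrix.index):
            raise ValueError("string must be a permutation of the treatment names")


def _loo_nearest_centroid_accuracy(X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out nearest-centroid accuracy for a two-class subset.

    Distances are weighted by the inverse pooled within-class variance per
    dimension (shrunk diagonal metric), so dimensions that vary little
    within treatments but differ between them dominate — the diagonal
    analogue of the model's shared-covariance metric, stable when
    parameters outnumber observations.
    """
    labs = np.unique(y)
    sums = {l: X[y == l].sum(axis=0) for l in labs}
    ns = {l: int((y == l).sum()) for l in labs}
    within = np.zeros(X.shape[1])
    for l in labs:
        within += ((X[y == l] - sums[l] / ns[l]) ** 2).sum(axis=0)
    within /= max(len(y) - len(labs), 1)
    w = 1.0 / (within + 0.01 * max(within.mean(), 1e-12))
    correct = 0
    for i in range(len(y)):
        own = y[i]
        other = labs[1] if own == labs[0] else labs[0]
        if ns[own] < 2:
            continue  # own centroid undefined without the point: count incorrect
        c_own = (sums[own] - X[i]) / (ns[own] - 1)
        c_other = sums[other] / ns[other]
        d_own = (w * (X[i] - c_own) ** 2).sum()
        d_other = (w * (X[i] - c_other) ** 2).sum()
        if d_own < d_other:
            correct += 1
    return correct / len(y)


def _pair_pvalue(
    X: np.ndarray, y: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> float:
    obs = _loo_nearest_centroid_accuracy(X, y)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(y)
        if _loo_nearest_centroid_accuracy(X, perm) >= obs - 1e-12:
            hits += 1
    return (1 + hits) / (n_permutations + 1)


def discriminate(
    model: MDAModel,
    features=None,
    labels=None,
    n_permutations: int = 0,
    alpha: float = 0.05,
    seed: int = 0,
) -> DiscriminationResult:
    """Similarity string, neighbor matrix and accuracy from a fitted model.

    The string orders treatments by the first discriminant coordinate of
    their class centroids (ties broken by the second) and is canonicalized
    to the lexicographically smaller of itself and its reverse.  With
    ``n_permutations`` > 0, every treatment pair is tested for centroid
    separation (permutation test on leave-one-out nearest-centroid
    accuracy at level ``alpha``); treatments that fail are merged — merged
    groups sit contiguously in the string and only *within-group*
    neighbors receive a 1 in the binary matrix.  With the default
    ``n_permutations=0`` every consecutive string pair is a neighbor.
    """
    if features is None:
        X, y = model.train_X, model.train_labels
    else:
        X, _ = _as_matrix(features)
        y = np.asarray(labels if labels is not None else model.train_labels)
    classes = model.classes_
    coords = model.discriminant_coords()
    if coords.shape[1] == 1:
        coords = np.column_stack([coords, np.zeros(len(classes))])
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    string = [classes[i] for i in order]
    first = {classes[i]: coords[i, 0] for i in range(len(classes))}

    # union-find merge of statistically indistinguishable pairs
    parent = {c: c for c in classes}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    pvals: dict[tuple[str, str], float] = {}
    if n_permutations > 0:
        rng = child_rng(seed, "gate")
        for i, a in enumerate(classes):
            for b in classes[i + 1 :]:
                keep = (y == a) | (y == b)
                pv = _pair_pvalue(X[keep], y[keep], n_permutations, rng)
                pvals[(a, b)] = pv
                if pv >= alpha:
                    parent[find(b)] = find(a)

    member_groups: dict[str, list[str]] = {}
    for c in string:  # string order keeps groups deterministic
        member_groups.setdefault(find(c), []).append(c)
    groups = sorted(member_groups.values(), key=lambda g: np.mean([first[m] for m in g]))
    string = [m for g in groups for m in sorted(g, key=lambda m: (first[m], m))]
    if list(reversed(string)) < string:
        string = list(reversed(string))
        groups = [list(reversed(g)) for g in reversed(groups)]

    group_of = {m: gi for gi, g in enumerate(groups) for m in g}
    M = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for a, b in zip(string[:-1], string[1:]):
        if n_permutations == 0 or group_of[a] == group_of[b]:
            M.loc[a, b] = M.loc[b, a] = 1
    acc = float(np.mean(model.predict(X) == y))
    return DiscriminationResult(string, M, groups, acc, pvals)


# --- tree from binary matrices ----------------------------------------------


@dataclass
class DendroTree:
    """Average-linkage tree over 1 − mean(binary neighbor matrices)."""

    labels: list[str]
    linkage_matrix: np.ndarray
    similarity: pd.DataFrame

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def newick(self) -> str:
        root = to_tree(self.linkage_matrix)

        def rec(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

        left, right = root.left, root.right
        return f"({rec(left)},{rec(right)});"

    def clusters_at(self, height: float) -> list[set[str]]:
        from scipy.cluster.hierarchy import fcluster

        flat = fcluster(self.linkage_matrix, t=height, criterion="distance")
        out: dict[int, set[str]] = {}
        for lab, cl in zip(self.labels, flat):
            out.setdefault(cl, set()).add(lab)
        return sorted(out.values(), key=lambda s: sorted(s)[0])


def build_tree(matrices: list[pd.DataFrame]) -> DendroTree:
    """Cluster treatments from one or more binary neighbor matrices.

    The element-wise mean of the matrices is a similarity S in [0, 1];
    the tree is average-linkage hierarchical clustering of 1 − S.
    """
    if not matrices:
        raise ValueError("need at least one binary matrix")
    labels = list(matrices[0].index)
    for m in matrices:
        if list(m.index) != labels or list(m.columns) != labels:
            raise ValueError("all matrices must share one label set, same order")
    S = sum(m.to_numpy(float) for m in matrices) / len(matrices)
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    return DendroTree(labels, Z, pd.DataFrame(S, index=labels, columns=labels))


# --- jackknife importance ----------------------------------------------------


def _loo_model_accuracy(X: np.ndarray, y: np.ndarray, n_subclasses: int, seed: int) -> float:
    correct = 0
    for i in range(len(y)):
        keep = np.ones(len(y), dtype=bool)
        keep[i] = False
        try:
            m = mda_fit(X[keep], y[keep], n_subclasses=n_subclasses, seed=seed)
        except ValueError:
            continue
        if m.predict(X[i : i + 1])[0] == y[i]:
            correct += 1
    return correct / len(y)


def _cv_model_accuracy(X: np.ndarray, y: np.ndarray, n_subclasses: int, seed: int) -> float:
    """Stratified 5-fold cross-validated accuracy of the MDA model."""
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=child_seed(seed, "cv"))
    correct = 0
    for train, test in skf.split(X, y):
        try:
            m = mda_fit(X[train], y[train], n_subclasses=n_subclasses, seed=seed)
        except (ValueError, np.linalg.LinAlgError):
            continue
        correct += int((m.predict(X[test]) == y[test]).sum())
    return correct / len(y)


def jackknife_importance(
    features,
    labels,
    groups: dict[str, list[str]] | None = None,
    n_subclasses: int = 3,
    seed: int = 0,
    score: str = "training",
) -> pd.DataFrame:
    """Leave-one-column(-group)-out importance for the discrimination.

    For each parameter (or named parameter group) the model is refitted
    without it and the drop in discrimination score is expressed as a
    percentage of the full-data score.  ``score`` is the training
    classification accuracy (default), leave-one-out cross-validated
    accuracy (``"loo"``), or stratified 5-fold cross-validated accuracy
    (``"cv"``) — the cross-validated variants are preferred when
    parameters outnumber observations, where training accuracy
    saturates.  A misclassification-count variant is reported
    alongside.  Returns a DataFrame (group, importance_pct,
    misclass_increase, rank) sorted by rank.
    """
    X, names = _as_matrix(features)
    y = np.asarray(labels)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 columns to jackknife")
    if groups is None:
        groups = {c: [c] for c in names}
    col_idx = {c: i for i, c in enumerate(names)}
    n = len(y)

    def fit_score(Xs: np.ndarray) -> tuple[float, int]:
        if score == "loo":
            acc = _loo_model_accuracy(Xs, y, n_subclasses, seed)
        elif score == "cv":
            acc = _cv_model_accuracy(Xs, y, n_subclasses, seed)
        else:
            acc = mda_fit(Xs, y, n_subclasses=n_subclasses, seed=seed).score()
        return acc, int(round((1.0 - acc) * n))

    full_acc, full_miss = fit_score(X)
    rows = []
    for gname, cols in groups.items():
        drop = [col_idx[c] for c in cols]
        keep = [i for i in range(X.shape[1]) if i not in drop]
        if not keep:
            raise ValueError(f"removing group {gname!r} leaves no columns")
        red_acc, red_miss = fit_score(X[:, keep])
        imp = 100.0 * (full_acc - red_acc) / full_acc if full_acc > 0 else 0.0
        rows.append({
            "group": gname,
            "importance_pct": imp,
            "misclass_increase": red_miss - full_miss,
        })
    report = pd.DataFrame(rows)
    order = np.argsort(-report["importance_pct"].to_numpy(), kind="stable")
    ranks = np.empty(len(report), dtype=int)
    ranks[order] = np.arange(1, len(report) + 1)
    report["rank"] = ranks
    return report.sort_values("rank").reset_index(drop=True)
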