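"""Trait-table assembly and race-level statistics.

Implements the analysis battery applied to the accession × trait table:
replicate averaging; Kruskal–Wallis + pairwise Mann–Whitney U tests on
the 37 stand-alone traits (Benjamini–Hochberg adjusted jointly across
traits, and jointly across all trait × race-pair combinations for the
pairwise family); Bartlett + pairwise Brown–Forsythe variance tests; a
1000-permutation L2 test comparing 10-bin distributional traits between
two races; PCA on the correlation matrix; PCA–LDA with leave-one-out
cross-validation; the Mantel test against a (negated) kinship matrix;
two-way hierarchical clustering of race means; and k-means with
silhouette scores.

The permutation p-value uses the strict-inequality estimator
``#{Xi > X0}/n_perm`` (so it can return exactly 0); pass
``plus_one=True`` for the positively biased but never-zero variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from statsmodels.stats.multitest import multipletests

from .catalog import ALL_FEATURES, FEATURE_CATEGORIES, HISTOGRAM_GROUPS, STANDALONE_FEATURES
from .errors import AlignmentError

META_COLUMNS = ("accession", "replicate", "race")


# ---------------------------------------------------------------------------
# table handling

def read_trait_table(path, labels_path=None) -> pd.DataFrame:
    """Read a trait CSV (header = canonical trait names); optionally merge a
    two-column accession → race mapping CSV."""
    df = pd.read_csv(path)
    if labels_path is not None:
        labels = pd.read_csv(labels_path)
        labels.columns = ["accession", "race"]
        df = df.merge(labels, on="accession", how="left")
    return df


def aggregate_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Average replicate rows per accession (missing values ignored)."""
    feature_cols = [c for c in table.columns if c not in META_COLUMNS]
    agg = {c: "mean" for c in feature_cols}
    if "race" in table.columns:
        agg["race"] = "first"
    out = table.groupby("accession", sort=True).agg(agg).reset_index()
    return out


def _race_groups(table: pd.DataFrame, trait: str, min_size: int = 2):
    groups, races = [], []
    for race, sub in table.groupby("race", sort=True):
        vals = sub[trait].dropna().to_numpy()
        if len(vals) < min_size:
            warnings.warn(f"race {race}: fewer than {min_size} accessions; excluded",
                          stacklevel=3)
            continue
        groups.append(vals)
        races.append(race)
    return races, groups


# ---------------------------------------------------------------------------
# univariate batteries

@dataclass
class UnivariateResults:
    """Omnibus + pairwise test results across stand-alone traits."""

    omnibus: pd.DataFrame  # trait, statistic, p, p_adj
    pairwise: pd.DataFrame  # trait, race_a, race_b, statistic, p, p_adj
    letters: dict[str, dict[str, str]]  # trait -> race -> letter group


def univariate_race_tests(table: pd.DataFrame, traits: list[str] | None = None,
                          alpha: float = 0.05) -> UnivariateResults:
    """Kruskal–Wallis across races per trait (BH across traits jointly);
    traits significant after adjustment get all pairwise Mann–Whitney U
    tests, BH-adjusted jointly across every trait × pair."""
    return _battery(table, traits, alpha,
                    omnibus=lambda gs: stats.kruskal(*gs),
                    pair=lambda a, b: stats.mannwhitneyu(a, b, alternative="two-sided",
                                                         method="asymptotic"))


def variance_tests(table: pd.DataFrame, traits: list[str] | None = None,
                   alpha: float = 0.05) -> UnivariateResults:
    """Bartlett across races per trait; pairwise Brown–Forsythe (Levene with
    median centering) for traits significant after BH adjustment."""
    return _battery(table, traits, alpha,
                    omnibus=lambda gs: stats.bartlett(*gs),
                    pair=lambda a, b: stats.levene(a, b, center="median"),
                    skip_zero_variance=True)


def _battery(table, traits, alpha, omnibus, pair, skip_zero_variance=False):
    if traits is None:
        traits = [t for t in STANDALONE_FEATURES if t in table.columns]
    rows = []
    per_trait_groups = {}
    for trait in traits:
        races, groups = _race_groups(table, trait)
        if len(groups) < 2:
            continue
        if skip_zero_variance and any(np.var(g) == 0 for g in groups):
            warnings.warn(f"trait {trait}: zero-variance group; skipped", stacklevel=2)
            continue
        try:
            stat, p = omnibus(groups)
        except ValueError:
            continue
        per_trait_groups[trait] = (races, groups)
        rows.append({"trait": trait, "statistic": float(stat), "p": float(p)})
    omnibus_df = pd.DataFrame(rows)
    if omnibus_df.empty:
        return UnivariateResults(omnibus_df, pd.DataFrame(), {})
    omnibus_df["p_adj"] = multipletests(omnibus_df["p"], method="fdr_bh")[1]

    pair_rows = []
    for trait in omnibus_df.loc[omnibus_df["p_adj"] < alpha, "trait"]:
        races, groups = per_trait_groups[trait]
        for i in range(len(races)):
            for j in range(i + 1, len(races)):
                stat, p = pair(groups[i], groups[j])
                pair_rows.append({"trait": trait, "race_a": races[i],
                                  "race_b": races[j], "statistic": float(stat),
                                  "p": float(p)})
    pairwise_df = pd.DataFrame(pair_rows)
    if not pairwise_df.empty:
        pairwise_df["p_adj"] = multipletests(pairwise_df["p"], method="fdr_bh")[1]
    letters = {}
    for trait in per_trait_groups:
        races, groups = per_trait_groups[trait]
        sig = set()
        if not pairwise_df.empty:
            sub = pairwise_df[(pairwise_df["trait"] == trait)
                              & (pairwise_df["p_adj"] < alpha)]
            sig = {frozenset((a, b)) for a, b in zip(sub["race_a"], sub["race_b"])}
        means = {r: float(np.mean(g)) for r, g in zip(races, groups)}
        letters[trait] = compact_letter_display(races, sig, means)
    return UnivariateResults(omnibus_df, pairwise_df, letters)


def compact_letter_display(groups: list[str], significant_pairs: set[frozenset],
                           means: dict[str, float]) -> dict[str, str]:
    """Assign letters so two groups share a letter iff not significantly different.

    Insert-and-absorb algorithm over groups ordered by decreasing mean.
    """
    order = sorted(groups, key=lambda g: -means[g])
    letter_sets: list[set[str]] = []
    for g in order:
        placed = False
        for s in letter_sets:
            if all(frozenset((g, h)) not in significant_pairs for h in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb letter sets fully contained in another
    letter_sets = [s for i, s in enumerate(letter_sets)
                   if not any(i != j and s < t for j, t in enumerate(letter_sets))]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in order:
            if g in s:
                out[g] += letter
    return out


# ---------------------------------------------------------------------------
# distributional traits: L2 permutation test

@dataclass
class PermutationResult:
    """Observed and permuted L2 distances between group mean vectors."""

    x0: float
    xi: np.ndarray
    p_value: float


def distribution_permutation_test(
    vectors_a: np.ndarray,
    vectors_b: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    plus_one: bool = False,
) -> PermutationResult:
    """Permutation test on the L2 distance between two races' mean 10-bin vectors.

    ``X0 = ‖mean_A − mean_B‖₂``; each permutation reshuffles the group
    labels over the pooled accessions preserving group sizes, and
    ``p = #{Xi > X0} / n_perm`` (strict inequality).
    """
    a = np.atleast_2d(np.asarray(vectors_a, float))
    b = np.atleast_2d(np.asarray(vectors_b, float))
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 members")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse", stacklevel=2)
    rng = np.random.default_rng(rng)
    x0 = float(np.linalg.norm(a.mean(0) - b.mean(0)))
    pooled = np.vstack([a, b])
    na = len(a)
    xi = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(pooled))
        xi[i] = np.linalg.norm(pooled[perm[:na]].mean(0) - pooled[perm[na:]].mean(0))
    if plus_one:
        p = (float((xi > x0).sum()) + 1.0) / (n_perm + 1.0)
    else:
        p = float((xi > x0).sum()) / n_perm
    return PermutationResult(x0, xi, p)


def distribution_tests_all_pairs(table: pd.DataFrame, n_perm: int = 1000,
                                 rng: np.random.Generator | int | None = None
                                 ) -> pd.DataFrame:
    """Run the L2 permutation test for every histogram group and race pair."""
    rng = np.random.default_rng(rng)
    races = sorted(table["race"].dropna().unique())
    rows = []
    for name, cols in HISTOGRAM_GROUPS.items():
        for i in range(len(races)):
            for j in range(i + 1, len(races)):
                va = table.loc[table["race"] == races[i], cols].dropna().to_numpy()
                vb = table.loc[table["race"] == races[j], cols].dropna().to_numpy()
                res = distribution_permutation_test(va, vb, n_perm, rng)
                rows.append({"distribution": name, "race_a": races[i],
                             "race_b": races[j], "x0": res.x0, "p": res.p_value})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multivariate analyses

@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples × PCs
    loadings: pd.DataFrame  # features × PCs
    variance_explained: np.ndarray  # percent per PC, sums to 100


def _standardized_matrix(table: pd.DataFrame, features: list[str] | None,
                         missing: str) -> tuple[pd.DataFrame, np.ndarray]:
    if features is None:
        features = [c for c in ALL_FEATURES if c in table.columns]
    X = table[features].copy()
    if missing == "drop":
        X = X.dropna(axis=0)
    elif missing == "mean":
        X = X.fillna(X.mean())
    else:
        raise ValueError(f"unknown missing policy {missing!r}")
    sd = X.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant columns: {constant}", stacklevel=3)
        X = X.drop(columns=constant)
        sd = sd.drop(constant)
    Z = (X - X.mean()) / sd
    return Z, X.index.to_numpy()


def pca(table: pd.DataFrame, features: list[str] | None = None,
        standardize: bool = True, missing: str = "drop") -> PCAResult:
    """PCA of the z-scored trait table (eigendecomposition of the correlation
    matrix); variance explained is reported in percent and sums to 100."""
    from sklearn.decomposition import PCA as SkPCA

    Z, idx = _standardized_matrix(table, features, missing)
    if not standardize:
        Z = table.loc[idx, Z.columns] - table.loc[idx, Z.columns].mean()
    model = SkPCA(n_components=min(Z.shape), svd_solver="full")
    scores = model.fit_transform(Z.to_numpy())
    pcs = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=idx, columns=pcs),
        loadings=pd.DataFrame(model.components_.T, index=Z.columns, columns=pcs),
        variance_explained=model.explained_variance_ratio_ * 100.0,
    )


@dataclass
class LDAResult:
    accuracy: float  # fraction correct under LOOCV
    confusion: pd.DataFrame  # true race × predicted race
    predictions: pd.Series
    pc_variance: float  # percent of variance captured by the PCs used
    ld_scores: pd.DataFrame  # discriminant coordinates from the full-data fit


def pca_lda_loocv(table: pd.DataFrame, labels: pd.Series | None = None,
                  features: list[str] | None = None, n_pcs: int = 8,
                  refit_pca: bool = False, missing: str = "drop") -> LDAResult:
    """LDA on the first ``n_pcs`` principal-component scores, with
    leave-one-out cross-validation over accessions.

    By default the PCA is fitted once on the full table and LOOCV is
    applied to the LDA alone; ``refit_pca=True`` refits scaler + PCA
    inside every fold.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    Z, idx = _standardized_matrix(table, features, missing)
    if labels is None:
        labels = table.loc[idx, "race"]
    y = pd.Series(np.asarray(labels), index=idx).loc[idx]
    keep = y.notna().to_numpy()
    Z, y = Z.iloc[keep], y[keep]
    classes = sorted(y.unique())
    n = len(Z)
    n_pcs = min(n_pcs, min(Z.shape) - 1)
    res = pca(pd.DataFrame(Z), features=list(Z.columns), missing="drop")
    pc_var = float(res.variance_explained[:n_pcs].sum())
    scores = res.scores.iloc[:, :n_pcs].to_numpy()
    counts = y.value_counts()
    if (counts < 2).any():
        warnings.warn(f"classes with a single member: "
                      f"{counts[counts < 2].index.tolist()}; their LOOCV "
                      "predictions cannot be correct", stacklevel=2)
    preds = np.empty(n, dtype=object)
    yarr = y.to_numpy()
    for i in range(n):
        train = np.arange(n) != i
        if refit_pca:
            sub = pd.DataFrame(Z[train], columns=Z.columns)
            sub_res = pca(sub, features=list(Z.columns), missing="drop")
            mu, sd = Z[train].mean(), Z[train].std(ddof=1).replace(0, 1.0)
            tr = sub_res.scores.iloc[:, :n_pcs].to_numpy()
            te = (((Z.iloc[[i]] - mu) / sd).fillna(0.0).to_numpy()
                  @ sub_res.loadings.to_numpy()[:, :n_pcs])
        else:
            tr, te = scores[train], scores[[i]]
        lda = LinearDiscriminantAnalysis()
        lda.fit(tr, yarr[train])
        preds[i] = lda.predict(te)[0]
    accuracy = float((preds == yarr).mean())
    confusion = pd.crosstab(pd.Series(yarr, name="true"),
                            pd.Series(preds, name="predicted"),
                            dropna=False).reindex(index=classes, columns=classes,
                                                  fill_value=0)
    full = LinearDiscriminantAnalysis().fit(scores, yarr)
    ld = full.transform(scores)
    ld_scores = pd.DataFrame(ld, index=Z.index,
                             columns=[f"LD{i + 1}" for i in range(ld.shape[1])])
    return LDAResult(accuracy, confusion, pd.Series(preds, index=Z.index), pc_var,
                     ld_scores)


def mantel_test(m1: np.ndarray, m2: np.ndarray, n_perm: int = 999,
                rng: np.random.Generator | int | None = None) -> tuple[float, float]:
    """Mantel correlation between two square symmetric matrices.

    ``r`` is the Pearson correlation over the strictly-lower triangles;
    ``p`` comes from simultaneous row/column permutations of the second
    matrix, one-sided (greater), with the +1 small-sample correction.
    A kinship (similarity) matrix should be negated by the caller.
    """
    m1, m2 = np.asarray(m1, float), np.asarray(m2, float)
    if m1.shape != m2.shape or m1.shape[0] != m1.shape[1]:
        raise AlignmentError(f"matrix shapes {m1.shape} vs {m2.shape} do not match")
    for m in (m1, m2):
        if not np.allclose(m, m.T, atol=1e-9):
            raise AlignmentError("matrices must be symmetric")
    n = m1.shape[0]
    tri = np.tril_indices(n, k=-1)
    v1 = m1[tri]
    r = float(np.corrcoef(v1, m2[tri])[0, 1])
    rng = np.random.default_rng(rng)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        mp = m2[np.ix_(perm, perm)]
        if np.corrcoef(v1, mp[tri])[0, 1] >= r:
            count += 1
    p = (count + 1.0) / (n_perm + 1.0)
    return r, p


@dataclass
class ClustergramResult:
    matrix: pd.DataFrame  # features × races, row-standardized means
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def race_mean_clustergram(table: pd.DataFrame,
                          features: list[str] | None = None) -> ClustergramResult:
    """Two-way hierarchical clustering (Euclidean, average linkage) of the
    features × races matrix of race means, each row centered on the
    across-race mean and scaled by its SD."""
    if features is None:
        features = [c for c in ALL_FEATURES if c in table.columns]
    means = table.groupby("race")[features].mean().T  # features × races
    sd = means.std(axis=1, ddof=1).replace(0, 1.0)
    std = means.sub(means.mean(axis=1), axis=0).div(sd, axis=0)
    row_l = linkage(std.to_numpy(), method="average", metric="euclidean")
    col_l = linkage(std.to_numpy().T, method="average", metric="euclidean")
    return ClustergramResult(std, row_l, col_l)


def kmeans_silhouette(table: pd.DataFrame, features: list[str] | None = None,
                      k_values: tuple[int, ...] = (2, 3, 4, 5), n_start: int = 25,
                      rng_seed: int = 0, missing: str = "drop"
                      ) -> dict[int, dict]:
    """Best-of-``n_start`` k-means on the standardized table for each k,
    with the mean silhouette value."""
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    Z, idx = _standardized_matrix(table, features, missing)
    X = Z.to_numpy()
    out = {}
    for k in k_values:
        if k >= len(X):
            raise ValueError(f"k={k} ≥ number of samples {len(X)}")
        km = KMeans(n_clusters=k, n_init=n_start, random_state=rng_seed)
        assign = km.fit_predict(X)
        out[k] = {"assignments": pd.Series(assign, index=idx),
                  "silhouette": float(silhouette_score(X, assign)),
                  "inertia": float(km.inertia_)}
    return out


def spearman_correlations(table: pd.DataFrame,
                          features: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Spearman ρ between traits, accessions as observations."""
    if features is None:
        features = [c for c in ALL_FEATURES if c in table.columns]
    rho = stats.spearmanr(table[features].to_numpy(), nan_policy="omit")[0]
    return pd.DataFrame(np.atleast_2d(rho), index=features, columns=features)


def table1_analysis(table: pd.DataFrame, n_pcs: int = 8,
                    kinship: pd.DataFrame | None = None,
                    n_perm: int = 999, rng_seed: int = 0) -> pd.DataFrame:
    """PCA–LDA LOOCV accuracy and 8-PC variance per feature category and for
    all features, optionally with Mantel tests against −kinship.

    ``table`` must be replicate-averaged with a ``race`` column; this is
    the analysis that summarizes classification power per trait category.
    """
    blocks = {"All features": [c for c in ALL_FEATURES if c in table.columns]}
    names = {"panicle_3d": "3D panicle features", "panicle_2d": "2D panicle features",
             "seed_morphology": "Seed morphology", "seed_spatial": "Seed spatial features",
             "branch": "Branch features"}
    for key, feats in FEATURE_CATEGORIES.items():
        blocks[names[key]] = [c for c in feats if c in table.columns]
    rows = []
    for name, feats in blocks.items():
        res = pca_lda_loocv(table, features=feats, n_pcs=n_pcs)
        row = {"category": name, "n_traits": len(feats),
               "pc_variance_pct": res.pc_variance,
               "accuracy_pct": res.accuracy * 100.0}
        if kinship is not None:
            sub = table.dropna(subset=feats)
            common = [a for a in sub["accession"] if a in kinship.index]
            sub = sub.set_index("accession").loc[common]
            Z = ((sub[feats] - sub[feats].mean()) / sub[feats].std(ddof=1).replace(0, 1))
            from scipy.spatial.distance import pdist, squareform

            d = squareform(pdist(Z.fillna(0.0).to_numpy()))
            k = kinship.loc[common, common].to_numpy()
            r, p = mantel_test(d, -k, n_perm=n_perm, rng=rng_seed)
            row |= {"mantel_r": r, "mantel_p": p}
        rows.append(row)
    return pd.DataFrame(rows)
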