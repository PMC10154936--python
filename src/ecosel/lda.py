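"""Canonical (linear) discriminant analysis of genotype-mean traits.

Solves the generalized eigenproblem of between-group versus pooled
within-group scatter to obtain canonical axes, the eigenvalue share of
each axis (percent discrimination), trait loadings (pooled within-group
correlations between traits and canonical scores), and equal-prior
classification under the pooled covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg


class SingularScatterError(np.linalg.LinAlgError):
    """Pooled within-group scatter is singular.

    Remove collinear/constant traits or pass ``ridge > 0``.
    """


@dataclass
class LDAResult:
    groups: list
    trait_names: list
    canonical_axes: np.ndarray  # trait x axis, raw-trait coefficients
    eigenvalues: np.ndarray
    pct_discrimination: np.ndarray
    loadings: pd.DataFrame  # trait x axis structure coefficients
    group_centroids: pd.DataFrame  # group x axis canonical means
    scores: np.ndarray  # row x axis
    grand_mean: np.ndarray
    group_means: np.ndarray  # group x trait
    pooled_cov: np.ndarray
    confusion: pd.DataFrame | None = None
    accuracy_overall: float | None = None
    accuracy_by_group: pd.Series | None = None


def _scatter(X: np.ndarray, labels: np.ndarray, groups):
    n, p = X.shape
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    means = np.zeros((len(groups), p))
    for k, g in enumerate(groups):
        Xg = X[labels == g]
        mu = Xg.mean(axis=0)
        means[k] = mu
        R = Xg - mu
        W += R.T @ R
        B += len(Xg) * np.outer(mu - grand, mu - grand)
    return W, B, means, grand


def lda_fit(means: pd.DataFrame, groups, traits=None, ridge: float = 0.0) -> LDAResult:
    """Fit canonical discriminant axes on a genotype-mean trait matrix.

    ``means`` holds one row per genotype with numeric trait columns;
    ``groups`` is the per-row ecotype label.  Rows with missing traits are
    dropped listwise.  Traits are internally standardized to unit pooled
    within-group variance before the eigensolve (results are reported on
    the raw trait scale, to which the ratio criterion is invariant).
    """
    labels = np.asarray(groups)
    if traits is None:
        traits = [c for c in means.columns if np.issubdtype(means[c].dtype, np.number)]
    X = means[list(traits)].to_numpy(dtype=float)
    keep = ~np.isnan(X).any(axis=1)
    X, labels = X[keep], labels[keep]

    glevels = sorted(pd.unique(labels))
    if len(glevels) < 2:
        raise ValueError("need at least 2 groups")
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValueError(f"every group needs >= 2 members; got {counts.to_dict()}")

    n, p = X.shape
    W, B, gmeans, grand = _scatter(X, labels, glevels)
    Sw = W / (n - len(glevels))  # pooled within-group covariance

    # unit pooled-within-variance scaling for conditioning
    s = np.sqrt(np.diag(Sw))
    if np.any(s <= 0):
        bad = [traits[i] for i in np.where(s <= 0)[0]]
        raise SingularScatterError(f"zero within-group variance in trait(s): {bad}")
    D = np.diag(1.0 / s)
    Ws, Bs = D @ W @ D, D @ B @ D
    if ridge > 0:
        Ws = Ws + ridge * np.eye(p)
    try:
        evals, evecs = scipy.linalg.eigh(Bs, Ws)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as err:
        raise SingularScatterError(
            "within-group scatter is singular; drop collinear traits or set ridge > 0"
        ) from err

    order = np.argsort(evals)[::-1]
    n_axes = min(len(glevels) - 1, p)
    evals = np.clip(evals[order][:n_axes], 0.0, None)
    A = (D @ evecs[:, order][:, :n_axes])  # raw-trait coefficients

    scores = (X - grand) @ A
    centroids = (gmeans - grand) @ A

    # structure coefficients: pooled within-group correlation trait <-> score
    Sw_scores = A.T @ Sw @ A
    denom = np.outer(s, np.sqrt(np.diag(Sw_scores)))
    loadings = (Sw @ A) / denom

    total = evals.sum()
    pct = evals / total if total > 0 else np.full(n_axes, np.nan)

    axis_names = [f"CA{i + 1}" for i in range(n_axes)]
    res = LDAResult(
        groups=glevels,
        trait_names=list(traits),
        canonical_axes=A,
        eigenvalues=evals,
        pct_discrimination=pct,
        loadings=pd.DataFrame(loadings, index=list(traits), columns=axis_names),
        group_centroids=pd.DataFrame(centroids, index=glevels, columns=axis_names),
        scores=scores,
        grand_mean=grand,
        group_means=gmeans,
        pooled_cov=Sw,
    )
    pred, _ = lda_classify(res, pd.DataFrame(X, columns=list(traits)))
    conf = pd.crosstab(
        pd.Categorical(labels, categories=glevels),
        pd.Categorical(pred, categories=glevels),
        dropna=False,
    )
    conf.index.name, conf.columns.name = "observed", "predicted"
    res.confusion = conf
    res.accuracy_overall = float(np.diag(conf).sum() / conf.to_numpy().sum())
    res.accuracy_by_group = pd.Series(np.diag(conf) / conf.sum(axis=1), index=glevels)
    return res


def lda_classify(result: LDAResult, means: pd.DataFrame):
    """Assign rows to the group with maximal linear discriminant score.

    Equal priors and the pooled within-group covariance; returns
    ``(predicted labels, discriminant score matrix)``.
    """
    missing = [t for t in result.trait_names if t not in means.columns]
    if missing:
        raise ValueError(f"trait set mismatch; missing: {missing}")
    X = means[result.trait_names].to_numpy(dtype=float)
    Sinv_mu = np.linalg.solve(result.pooled_cov, result.group_means.T)  # p x g
    disc = X @ Sinv_mu - 0.5 * np.sum(result.group_means.T * Sinv_mu, axis=0)
    pred = np.asarray(result.groups, dtype=object)[np.argmax(disc, axis=1)]
    return pred, disc


def lda_loo_accuracy(means: pd.DataFrame, groups, traits=None) -> float:
    """Leave-one-out classification accuracy (refit per held-out row)."""
    labels = np.asarray(groups)
    if traits is None:
        traits = [c for c in means.columns if np.issubdtype(means[c].dtype, np.number)]
    X = means[list(traits)].to_numpy(dtype=float)
    keep = ~np.isnan(X).any(axis=1)
    X, labels = X[keep], labels[keep]
    hits = 0
    for i in range(len(X)):
        mask = np.ones(len(X), bool)
        mask[i] = False
        fit = lda_fit(pd.DataFrame(X[mask], columns=list(traits)), labels[mask])
        pred, _ = lda_classify(fit, pd.DataFrame(X[i : i + 1], columns=list(traits)))
        hits += pred[0] == labels[i]
    return hits / len(X)
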