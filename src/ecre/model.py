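"""Enhancer probability scoring with an ensemble of lasso-logistic fits.

The training design follows the matched-negative recipe: validated
enhancers are the positives, an equal number of length-matched regions is
drawn at random from the genome (avoiding the positives and a blacklist)
as negatives, and each region is described by binary overlap indicators
against a library of epigenetic peak tracks plus base-pair-weighted
coverage sums against bedGraph tracks.  An L1-penalised logistic
regression is fitted on a stratified 80% split with the penalty chosen by
stratified K-fold cross-validation; the whole procedure (negatives, split,
CV, fit) is repeated R times and a query region's score is the mean of
the R predicted probabilities, called an enhancer when the mean exceeds
the threshold (strictly).

The solver minimises

    (1/n) sum_i [ -y_i log p_i - (1-y_i) log(1-p_i) ]  +  lambda * ||beta||_1

with p_i = sigmoid(beta0 + x_i beta), the intercept unpenalised and the
columns standardised to zero mean / unit variance on the training data
(coefficients are reported on the original scale).  It is an iteratively
reweighted least squares outer loop around cyclic coordinate descent with
soft-thresholding, warm-started along a geometric lambda path — the
standard glmnet-style scheme.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numba
import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.model_selection import StratifiedKFold, train_test_split

from .intervals import (
    CoverageTrack,
    GenomeTable,
    Region,
    RegionSet,
    shuffle_match,
)

__all__ = [
    "TrackLibrary",
    "FeatureMatrix",
    "TrainConfig",
    "LassoFit",
    "CVResult",
    "TrainResult",
    "EnsembleScore",
    "binary_overlap_features",
    "coverage_sum_features",
    "assemble_features",
    "lambda_max",
    "lambda_grid",
    "fit_l1_logistic",
    "cv_select_lambda",
    "train_once",
    "ensemble_predict",
    "classify",
]


@dataclass
class TrackLibrary:
    """Named peak tracks (binary-feature sources) and coverage tracks."""

    peak_tracks: dict[str, RegionSet]
    coverage_tracks: dict[str, CoverageTrack] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clash = set(self.peak_tracks) & set(self.coverage_tracks)
        if clash:
            raise ValueError(f"track names used in both groups: {sorted(clash)}")
        if not self.peak_tracks and not self.coverage_tracks:
            raise ValueError("track library is empty")

    @property
    def n_features(self) -> int:
        return len(self.peak_tracks) + len(self.coverage_tracks)

    @property
    def column_names(self) -> list[str]:
        return list(self.peak_tracks) + list(self.coverage_tracks)


@dataclass
class FeatureMatrix:
    """Labelled regions x feature columns."""

    ids: list[str]
    columns: list[str]
    X: np.ndarray
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.shape != (len(self.ids), len(self.columns)):
            raise ValueError("feature matrix shape does not match ids/columns")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=np.int64)
            if self.y.shape != (len(self.ids),):
                raise ValueError("label vector length mismatch")


@dataclass
class TrainConfig:
    """Knobs of the training procedure (defaults mirror the study design)."""

    train_frac: float = 0.8
    cv_folds: int = 10
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    repeats: int = 10
    threshold: float = 0.5
    seed: int = 0
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


def binary_overlap_features(
    regions: RegionSet | Sequence[Region],
    peak_tracks: Mapping[str, RegionSet],
) -> np.ndarray:
    """(i, j) = 1 iff region i overlaps at least one peak of track j."""
    names = list(peak_tracks)
    if len(names) != len(set(names)):
        raise ValueError("duplicate peak track names")
    regions = list(regions)
    out = np.zeros((len(regions), len(names)), dtype=np.float64)
    for j, name in enumerate(names):
        track = peak_tracks[name]
        for i, r in enumerate(regions):
            if track.any_overlap(r):
                out[i, j] = 1.0
    return out


def coverage_sum_features(
    regions: RegionSet | Sequence[Region],
    coverage_tracks: Mapping[str, CoverageTrack],
) -> np.ndarray:
    """(i, j) = base-pair-weighted coverage sum of track j over region i."""
    regions = list(regions)
    out = np.zeros((len(regions), len(coverage_tracks)), dtype=np.float64)
    for j, name in enumerate(coverage_tracks):
        track = coverage_tracks[name]
        for i, r in enumerate(regions):
            out[i, j] = track.region_sum(r)
    return out


def feature_block(regions: RegionSet | Sequence[Region], tracks: TrackLibrary) -> np.ndarray:
    """Binary block then coverage block, in library column order."""
    blocks = []
    if tracks.peak_tracks:
        blocks.append(binary_overlap_features(regions, tracks.peak_tracks))
    if tracks.coverage_tracks:
        blocks.append(coverage_sum_features(regions, tracks.coverage_tracks))
    return np.hstack(blocks)


def assemble_features(
    pos: RegionSet, neg: RegionSet, tracks: TrackLibrary
) -> FeatureMatrix:
    """Stack positives then negatives; y = 1 for positives, 0 for negatives."""
    if tracks.n_features == 0:
        raise ValueError("empty feature space: no tracks")
    regions = list(pos) + list(neg)
    ids = [f"pos:{r.id}" for r in pos] + [f"neg:{r.id}" for r in neg]
    X = feature_block(regions, tracks)
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return FeatureMatrix(ids, tracks.column_names, X, y)


# ---------------------------------------------------------------------------
# L1-penalised logistic regression (IRLS + cyclic coordinate descent)
# ---------------------------------------------------------------------------

_WEIGHT_FLOOR = 1e-5
_PROB_CLIP = 1e-10


@dataclass
class LassoFit:
    """A fitted penalised logistic model, coefficients on the original scale."""

    intercept: float
    coef: np.ndarray
    lam: float
    columns: list[str]
    # standardisation used during fitting, kept for serialisation
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return expit(self.intercept + X @ self.coef)

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "coef": self.coef.tolist(),
                "lambda": self.lam,
                "columns": self.columns,
                "center": None if self.center is None else self.center.tolist(),
                "scale": None if self.scale is None else self.scale.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LassoFit":
        d = json.loads(text)
        return cls(
            intercept=d["intercept"],
            coef=np.asarray(d["coef"], dtype=np.float64),
            lam=d["lambda"],
            columns=list(d["columns"]),
            center=None if d["center"] is None else np.asarray(d["center"]),
            scale=None if d["scale"] is None else np.asarray(d["scale"]),
        )


@dataclass
class CVResult:
    """Cross-validation profile over the lambda grid."""

    lambdas: np.ndarray
    mean_deviance: np.ndarray
    lambda_best: float

    def __post_init__(self) -> None:
        if self.lambda_best not in set(np.asarray(self.lambdas).tolist()):
            raise ValueError("lambda_best must belong to the grid")


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Zero-mean unit-variance columns (population variance).

    Zero-variance columns become all-zero (scale recorded as 1) so they
    are inert under the penalty rather than producing NaNs.
    """
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd_safe


def _objective(Xs, y, b0, beta, lam):
    eta = b0 + Xs @ beta
    # log(1 + exp(-s*eta)) computed stably
    s = 2.0 * y - 1.0
    nll = np.logaddexp(0.0, -s * eta).mean()
    return nll + lam * np.abs(beta).sum()


@numba.njit(cache=True)
def _cd_kernel(XsT, y, lam, b0, beta, tol, max_iter):  # pragma: no cover
    """IRLS + cyclic coordinate descent on standardised data.

    ``XsT`` is the (p, n) transposed design so each coordinate's column is
    contiguous.  Returns the updated intercept; ``beta`` is modified in
    place.  Counts coordinate sweeps against ``max_iter``.
    """
    p, n = XsT.shape
    eta = np.empty(n)
    w = np.empty(n)
    r = np.empty(n)
    wx2 = np.empty(p)
    # initial objective
    obj = lam * np.abs(beta).sum()
    for i in range(n):
        e = b0
        for j in range(p):
            e += XsT[j, i] * beta[j]
        eta[i] = e
        s = 2.0 * y[i] - 1.0
        v = -s * e
        obj += (v + np.log1p(np.exp(-v))) / n if v > 0 else np.log1p(np.exp(v)) / n
    it = 0
    for _outer in range(100):
        w_sum = 0.0
        for i in range(n):
            pr = 1.0 / (1.0 + np.exp(-eta[i]))
            wi = pr * (1.0 - pr)
            if wi < 1e-5:
                wi = 1e-5
            w[i] = wi
            w_sum += wi
            r[i] = (y[i] - pr) / wi  # z - eta
        for j in range(p):
            acc = 0.0
            for i in range(n):
                acc += w[i] * XsT[j, i] * XsT[j, i]
            wx2[j] = acc / n
        for _inner in range(200):
            max_delta = 0.0
            d0 = 0.0
            for i in range(n):
                d0 += w[i] * r[i]
            d0 /= w_sum
            b0 += d0
            for i in range(n):
                r[i] -= d0
            md = d0 * d0 * w_sum / n
            if md > max_delta:
                max_delta = md
            for j in range(p):
                if wx2[j] <= 0.0:
                    continue
                acc = 0.0
                for i in range(n):
                    acc += w[i] * XsT[j, i] * r[i]
                grad = acc / n + wx2[j] * beta[j]
                mag = abs(grad) - lam
                bj = 0.0 if mag <= 0.0 else (mag if grad > 0 else -mag) / wx2[j]
                d = bj - beta[j]
                if d != 0.0:
                    beta[j] = bj
                    for i in range(n):
                        r[i] -= d * XsT[j, i]
                    md = wx2[j] * d * d
                    if md > max_delta:
                        max_delta = md
            it += 1
            if max_delta < 1e-10 or it >= max_iter:
                break
        # recompute eta and the objective
        new_obj = lam * np.abs(beta).sum()
        for i in range(n):
            e = b0
            for j in range(p):
                e += XsT[j, i] * beta[j]
            eta[i] = e
            s = 2.0 * y[i] - 1.0
            v = -s * e
            new_obj += (v + np.log1p(np.exp(-v))) / n if v > 0 else np.log1p(np.exp(v)) / n
        done = abs(obj - new_obj) <= tol * (abs(obj) + 0.1) or it >= max_iter
        obj = new_obj
        if done:
            break
    return b0


def _cd_fit(
    Xs: np.ndarray,
    y: np.ndarray,
    lam: float,
    b0: float,
    beta: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> tuple[float, np.ndarray]:
    """Minimise the penalised deviance on standardised data.

    Outer IRLS loop; inner cyclic coordinate descent with soft-threshold
    updates on the weighted quadratic approximation.  Converges when the
    relative change of the objective drops below ``tol``.
    """
    beta = beta.copy()
    XsT = np.ascontiguousarray(Xs.T)
    b0 = _cd_kernel(XsT, np.asarray(y, dtype=np.float64), float(lam), float(b0), beta, float(tol), int(max_iter))
    return float(b0), beta


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty that zeroes every coefficient (on standardised X)."""
    Xs, _, _ = _standardize(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    resid = y - y.mean()
    # tiny relative inflation keeps the null model strictly optimal at the
    # grid top regardless of floating-point summation order
    return float(np.abs(Xs.T @ resid).max() / len(y)) * (1.0 + 1e-10)


def lambda_grid(
    lam_max: float, n_lambda: int = 100, min_ratio: float = 1e-4
) -> np.ndarray:
    """Geometric grid from lambda_max down to lambda_max * min_ratio."""
    if n_lambda == 1:
        return np.array([lam_max])
    return lam_max * min_ratio ** (np.arange(n_lambda) / (n_lambda - 1))


def _check_Xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in feature matrix")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in y")
    if X.shape[0] != y.shape[0] or X.shape[0] < 2:
        raise ValueError("need n >= 2 rows with matching labels")
    return X, y


def fit_l1_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    columns: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> LassoFit:
    """Fit one L1-penalised logistic regression at penalty ``lam``.

    Columns are standardised internally; the returned intercept and
    coefficients are on the original feature scale.
    """
    X, y = _check_Xy(X, y)
    Xs, mu, sd = _standardize(X)
    b0 = float(logit(np.clip(y.mean(), _PROB_CLIP, 1 - _PROB_CLIP)))
    beta = np.zeros(X.shape[1])
    b0, beta = _cd_fit(Xs, y, lam, b0, beta, tol=tol, max_iter=max_iter)
    coef = beta / sd
    intercept = b0 - float(coef @ mu)
    cols = list(columns) if columns is not None else [f"x{j}" for j in range(X.shape[1])]
    return LassoFit(intercept, coef, float(lam), cols, center=mu, scale=sd)


def fit_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    tol: float = 1e-8,
    dev_ratio_stop: float = 0.999,
) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started fits along a descending lambda path (standardised scale).

    Returns (intercepts, coefficient matrix) with one row per lambda; the
    coefficients are on the *original* feature scale.  As in the usual
    regularisation-path schemes, once the fitted model explains
    ``dev_ratio_stop`` of the null deviance the remaining (smaller)
    penalties reuse the current solution: on (near-)separable data the
    unpenalised tail would otherwise diverge without changing predictions
    meaningfully.
    """
    X, y = _check_Xy(X, y)
    Xs, mu, sd = _standardize(X)
    XsT = np.ascontiguousarray(Xs.T)
    b0 = float(logit(np.clip(y.mean(), _PROB_CLIP, 1 - _PROB_CLIP)))
    beta = np.zeros(X.shape[1])
    null_dev = _binomial_deviance(y, np.full_like(y, y.mean()))
    b0s = np.empty(len(lambdas))
    B = np.empty((len(lambdas), X.shape[1]))
    for k, lam in enumerate(lambdas):
        b0 = float(_cd_kernel(XsT, y, float(lam), b0, beta, float(tol), 100_000))
        coef = beta / sd
        b0s[k] = b0 - float(coef @ mu)
        B[k] = coef
        dev = _binomial_deviance(y, expit(b0 + Xs @ beta))
        if null_dev > 0 and 1.0 - dev / null_dev >= dev_ratio_stop:
            b0s[k + 1:] = b0s[k]
            B[k + 1:] = coef
            break
    return b0s, B


def _binomial_deviance(y: np.ndarray, prob: np.ndarray) -> float:
    prob = np.clip(prob, _PROB_CLIP, 1 - _PROB_CLIP)
    return float(-2.0 * (y * np.log(prob) + (1 - y) * np.log(1 - prob)).mean())


def cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> CVResult:
    """Choose lambda by stratified K-fold CV, minimising held-out deviance.

    The grid is computed once from the full data; each fold refits the
    whole path (with per-fold standardisation) and scores the left-out
    part.  Deterministic given ``rng``.
    """
    X, y = _check_Xy(X, y)
    if cfg.cv_folds > len(y):
        raise ValueError("more CV folds than samples")
    lams = lambda_grid(lambda_max(X, y), cfg.n_lambda, cfg.lambda_min_ratio)
    skf = StratifiedKFold(
        n_splits=cfg.cv_folds,
        shuffle=True,
        random_state=int(rng.integers(2**31 - 1)),
    )
    dev = np.zeros((cfg.cv_folds, len(lams)))
    for f, (tr, te) in enumerate(skf.split(X, y)):
        b0s, B = fit_path(X[tr], y[tr], lams)
        probs = expit(b0s[None, :] + X[te] @ B.T)  # n_te x n_lambda
        for k in range(len(lams)):
            dev[f, k] = _binomial_deviance(y[te], probs[:, k])
    mean_dev = dev.mean(axis=0)
    best = float(lams[int(np.argmin(mean_dev))])
    return CVResult(lams, mean_dev, best)


def classify(score: float, tau: float = 0.5) -> bool:
    """Enhancer call: strictly greater than the threshold."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    return score > tau


@dataclass
class TrainResult:
    """One repeat: the fit, its CV profile, test accuracy and query scores."""

    fit: LassoFit
    cv: CVResult
    test_accuracy: float
    query_scores: np.ndarray
    negatives: RegionSet


def train_once(
    pos: RegionSet,
    tracks: TrackLibrary,
    genome: GenomeTable,
    excl: RegionSet,
    queries: RegionSet | None,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> TrainResult:
    """One full training round with freshly sampled matched negatives.

    Negatives avoid both the positives and ``excl`` (blacklist).  The
    80/20 split is stratified by label; CV and the final fit see only the
    training portion; accuracy is the fraction of test regions whose
    thresholded score equals the label.
    """
    avoid = RegionSet(list(pos) + list(excl))
    neg = shuffle_match(pos, genome, avoid, rng, max_attempts=cfg.max_attempts)
    fm = assemble_features(pos, neg, tracks)
    assert fm.y is not None
    idx = np.arange(len(fm.ids))
    tr, te = train_test_split(
        idx,
        test_size=1.0 - cfg.train_frac,
        stratify=fm.y,
        random_state=int(rng.integers(2**31 - 1)),
    )
    cv = cv_select_lambda(fm.X[tr], fm.y[tr], cfg, rng)
    fit = fit_l1_logistic(fm.X[tr], fm.y[tr], cv.lambda_best, columns=fm.columns)
    test_prob = fit.predict_proba(fm.X[te])
    test_pred = test_prob > cfg.threshold
    accuracy = float((test_pred == (fm.y[te] == 1)).mean())
    if queries is not None and len(queries) > 0:
        Xq = feature_block(queries, tracks)
        q_scores = fit.predict_proba(Xq)
    else:
        q_scores = np.empty(0)
    return TrainResult(fit, cv, accuracy, q_scores, neg)


@dataclass
class EnsembleScore:
    """Per-query repeat scores, their mean, and the thresholded call."""

    region_ids: list[str]
    scores: np.ndarray  # repeats x queries
    threshold: float
    test_accuracies: np.ndarray
    lambdas: np.ndarray
    fits: list[LassoFit] = field(default_factory=list)

    @property
    def mean_score(self) -> np.ndarray:
        return self.scores.mean(axis=0)

    @property
    def is_enhancer(self) -> np.ndarray:
        return self.mean_score > self.threshold

    def score_of(self, region_id: str) -> float:
        try:
            return float(self.mean_score[self.region_ids.index(region_id)])
        except ValueError:
            raise KeyError(f"no score for region {region_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores.T,
            columns=[f"score_rep{r + 1}" for r in range(self.scores.shape[0])],
        )
        df.insert(0, "region_id", self.region_ids)
        df["mean_score"] = self.mean_score
        df["is_enhancer"] = self.is_enhancer
        return df.sort_values("mean_score", ascending=False, kind="stable").reset_index(
            drop=True
        )

    def write_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def ensemble_predict(
    pos: RegionSet,
    tracks: TrackLibrary,
    genome: GenomeTable,
    excl: RegionSet,
    queries: RegionSet,
    cfg: TrainConfig,
) -> EnsembleScore:
    """R independent training rounds; the final score is their mean.

    Each repeat draws fresh negatives and a fresh stratified split from an
    independent substream of ``cfg.seed``, so repeats are exchangeable and
    the whole ensemble is reproducible from the one seed.
    """
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.repeats)
    Xq = feature_block(queries, tracks) if len(queries) else np.empty((0, tracks.n_features))
    results = [
        train_once(pos, tracks, genome, excl, None, cfg, np.random.default_rng(s))
        for s in streams
    ]
    scores = np.vstack([r.fit.predict_proba(Xq) for r in results])
    return EnsembleScore(
        region_ids=[r.id for r in queries],
        scores=scores,
        threshold=cfg.threshold,
        test_accuracies=np.array([r.test_accuracy for r in results]),
        lambdas=np.array([r.cv.lambda_best for r in results]),
        fits=[r.fit for r in results],
    )
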