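"""PCA, two-class LDA and leave-one-out species classification of wing shapes.

Superimposed shape coordinates are rank-deficient (2D alignment removes two
translation, one rotation and one scale degree of freedom), so the pooled
within-class covariance of the raw coordinates is singular.  LDA therefore
operates on full-rank PCA scores by default — an orthogonal rotation of the
data that preserves all shape information and makes results identical to any
generalized-inverse treatment of the raw coordinates.

The discriminant is the classical Fisher/Gaussian two-class rule: pooled
within-class covariance W (divisor n − 2), direction w = W⁻¹(μ₁ − μ₂),
threshold midway between the projected class means shifted by the log prior
ratio, posteriors from the equal-covariance two-Gaussian model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gpa import mean_shape


@dataclass
class PcaResult:
    scores: np.ndarray  # (n, m)
    loadings: np.ndarray  # (p, m), orthonormal columns
    explained_variance_ratio: np.ndarray  # (m,)
    mean: np.ndarray  # (p,)

    @property
    def m(self) -> int:
        return self.scores.shape[1]

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) @ self.loadings


def pca(shapes: np.ndarray, rank_tol: float = 1e-12) -> PcaResult:
    """Principal component analysis of shape vectors via SVD.

    Components are ordered by decreasing eigenvalue; rank is determined by
    singular values above ``rank_tol`` times the largest.  Sign gauge: the
    largest-magnitude element of each loading vector is positive, so scores
    and loadings are reproducible across platforms.
    """
    x = np.asarray(shapes, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("PCA needs an (n >= 3, p) matrix of shape vectors")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    m = int(np.sum(s > rank_tol * s[0])) if s[0] > 0 else 0
    if m == 0:
        raise ValueError("shape matrix has no variation")
    u, s, vt = u[:, :m], s[:m], vt[:m]
    # sign gauge on loadings
    flips = np.sign(vt[np.arange(m), np.argmax(np.abs(vt), axis=1)])
    vt = vt * flips[:, None]
    u = u * flips[None, :]
    scores = u * s
    var = s**2
    return PcaResult(
        scores=scores,
        loadings=vt.T,
        explained_variance_ratio=var / var.sum(),
        mean=mean,
    )


class RankDeficiencyError(np.linalg.LinAlgError):
    """Pooled within-class covariance is singular; reduce with PCA first."""


@dataclass
class LdaModel:
    classes: tuple[str, str]
    w: np.ndarray  # discriminant direction (class 1 positive)
    threshold_shift: float  # ln(prior1 / prior2)
    mean1: np.ndarray
    mean2: np.ndarray
    priors: tuple[float, float]

    def scores(self, x: np.ndarray) -> np.ndarray:
        """Signed discriminant scores; positive → class 1."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        mid = 0.5 * (self.mean1 + self.mean2)
        return (x - mid) @ self.w + self.threshold_shift

    def predict(self, x: np.ndarray) -> np.ndarray:
        s = self.scores(x)
        return np.where(s >= 0.0, self.classes[0], self.classes[1])

    def posteriors(self, x: np.ndarray) -> np.ndarray:
        """P(class 1 | x) under the equal-covariance two-Gaussian model."""
        from scipy.special import expit

        return expit(self.scores(x))


def lda_fit(
    features: np.ndarray,
    labels,
    priors: str = "proportional",
) -> LdaModel:
    """Fit the two-class linear discriminant.

    ``priors``: "proportional" (class frequencies) or "equal".  Classes are
    ordered by first appearance in ``labels``, so swapping the two labels
    exactly negates every discriminant score.
    """
    x = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if x.ndim != 2 or labels.shape != (x.shape[0],):
        raise ValueError("features must be (n, m) with one label per row")
    classes = list(dict.fromkeys(labels.tolist()))  # order of appearance
    if len(classes) != 2:
        raise ValueError("LDA here is strictly two-class")
    c1, c2 = classes
    x1, x2 = x[labels == c1], x[labels == c2]
    n1, n2 = x1.shape[0], x2.shape[0]
    if min(n1, n2) < 2:
        raise ValueError("each class needs at least two specimens")
    mu1, mu2 = x1.mean(axis=0), x2.mean(axis=0)
    r1, r2 = x1 - mu1, x2 - mu2
    w_cov = (r1.T @ r1 + r2.T @ r2) / (n1 + n2 - 2)
    try:
        direction = np.linalg.solve(w_cov, mu1 - mu2)
    except np.linalg.LinAlgError as exc:
        raise RankDeficiencyError(
            "pooled within-class covariance is singular; "
            "use full-rank PCA scores as LDA features"
        ) from exc
    cond = np.linalg.cond(w_cov)
    if not np.isfinite(cond) or cond > 1e12:
        raise RankDeficiencyError(
            "pooled within-class covariance is numerically singular "
            f"(cond={cond:.2e}); use full-rank PCA scores as LDA features"
        )
    if priors == "proportional":
        p1, p2 = n1 / (n1 + n2), n2 / (n1 + n2)
    elif priors == "equal":
        p1 = p2 = 0.5
    else:
        raise ValueError("priors must be 'proportional' or 'equal'")
    return LdaModel(
        classes=(str(c1), str(c2)),
        w=direction,
        threshold_shift=float(np.log(p1 / p2)),
        mean1=mu1,
        mean2=mu2,
        priors=(p1, p2),
    )


@dataclass
class ClassificationReport:
    """LOOCV species-assignment summary.

    confusion is true × predicted with classes in ``classes`` order; accuracy
    is always trace(confusion) / n.
    """

    classes: tuple[str, str]
    confusion: np.ndarray  # (2, 2) ints, rows = true, cols = predicted
    per_specimen: list[dict] = field(default_factory=list)
    ld_vector: np.ndarray | None = None  # discriminant direction in shape space
    priors: tuple[float, float] | None = None
    n_components: int | None = None
    n_ties: int = 0
    feature_mode: str = "pca"

    @property
    def n(self) -> int:
        return int(self.confusion.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion)) / self.n

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "n": self.n,
            "n_components": self.n_components,
            "n_ties": self.n_ties,
            "priors": list(self.priors) if self.priors else None,
            "feature_mode": self.feature_mode,
            "per_specimen": self.per_specimen,
        }

    def confusion_text(self) -> str:
        c1, c2 = self.classes
        width = max(len(c1), len(c2), 9)
        corner = "true\\pred"
        lines = [
            f"{corner:>{width}}  {c1:>{width}}  {c2:>{width}}",
            f"{c1:>{width}}  {self.confusion[0, 0]:>{width}d}  {self.confusion[0, 1]:>{width}d}",
            f"{c2:>{width}}  {self.confusion[1, 0]:>{width}d}  {self.confusion[1, 1]:>{width}d}",
            f"accuracy: {self.accuracy:.3f} ({int(np.trace(self.confusion))}/{self.n})",
        ]
        return "\n".join(lines)


def report_from_confusion(
    confusion, classes: tuple[str, str] = ("japonicus", "koreicus")
) -> ClassificationReport:
    """Build a report directly from confusion counts (e.g. published tables)."""
    confusion = np.asarray(confusion, dtype=int)
    if confusion.shape != (2, 2):
        raise ValueError("confusion matrix must be 2x2")
    return ClassificationReport(classes=classes, confusion=confusion)


def loocv_classify(
    shapes: np.ndarray,
    labels,
    ids=None,
    n_components: int | str = "rank",
    priors: str = "proportional",
    feature_mode: str = "pca",
) -> ClassificationReport:
    """Leave-one-out cross-validated LDA species assignment.

    The PCA basis is computed once on the full sample (the standard
    cross-validation of discriminant toolchains operating on precomputed
    coordinates; mildly optimistic relative to refitting the basis per fold);
    within each fold the LDA itself is refit on all-but-one specimens.

    ``n_components`` = "rank" keeps every component with nonzero variance,
    capped at min(n − 2, p_effective) so the pooled covariance stays
    invertible in every fold.
    """
    shapes = np.asarray(shapes, dtype=float)
    labels = np.asarray(labels)
    n = shapes.shape[0]
    if n < 6:
        raise ValueError("LOOCV needs at least 6 specimens")
    classes = list(dict.fromkeys(labels.tolist()))
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    counts = {c: int(np.sum(labels == c)) for c in classes}
    if min(counts.values()) < 3:
        raise ValueError("both classes need at least 3 specimens")
    if ids is None:
        ids = [str(i) for i in range(n)]

    if feature_mode == "pca":
        p = pca(shapes)
        # n - 3: each leave-one-out fold must keep its pooled covariance
        # full rank (n - 1 training specimens, two class means)
        cap = min(n - 3, p.m)
        if n_components == "rank":
            m = cap
        else:
            m = int(n_components)
            if not 1 <= m <= cap:
                raise ValueError(f"n_components must be in [1, {cap}]")
        features = p.scores[:, :m]
        back = p.loadings[:, :m]  # to map the LD vector back to shape space
    elif feature_mode == "raw":
        features = shapes
        back = np.eye(shapes.shape[1])
        m = shapes.shape[1]
    else:
        raise ValueError("feature_mode must be 'pca' or 'raw'")

    c1, c2 = classes
    idx = {c1: 0, c2: 1}
    confusion = np.zeros((2, 2), dtype=int)
    per_specimen = []
    n_ties = 0
    all_rows = np.arange(n)
    for i in range(n):
        train = all_rows != i
        if min(np.sum(labels[train] == c1), np.sum(labels[train] == c2)) < 2:
            raise ValueError("a fold leaves a class with fewer than 2 members")
        model = lda_fit(features[train], labels[train], priors=priors)
        score = float(model.scores(features[i])[0])
        if score == 0.0:
            n_ties += 1
        pred = model.classes[0] if score >= 0.0 else model.classes[1]
        post = float(model.posteriors(features[i])[0])
        if model.classes[0] != c1:  # orient reporting to global class order
            score, post = -score, 1.0 - post
            # pred already a concrete label; no change needed
        confusion[idx[str(labels[i])], idx[pred]] += 1
        per_specimen.append(
            {
                "id": str(ids[i]),
                "true": str(labels[i]),
                "predicted": pred,
                "score": score,
                "posterior_class1": post,
            }
        )

    full_model = lda_fit(features, labels, priors=priors)
    ld_shape_space = back @ full_model.w

    return ClassificationReport(
        classes=(str(c1), str(c2)),
        confusion=confusion,
        per_specimen=per_specimen,
        ld_vector=ld_shape_space,
        priors=full_model.priors,
        n_components=m,
        n_ties=n_ties,
        feature_mode=feature_mode,
    )


@dataclass
class LandmarkDifferenceSummary:
    displacements: np.ndarray  # (k, 2) group-mean differences per landmark
    magnitudes: np.ndarray  # (k,)
    ranking: np.ndarray  # (k,) landmark indices (1-based), largest first
    single_landmark_accuracy: np.ndarray | None = None  # (k,) LOOCV accuracies

    def to_dict(self) -> dict:
        out = {
            "magnitudes": self.magnitudes.tolist(),
            "ranking": self.ranking.tolist(),
        }
        if self.single_landmark_accuracy is not None:
            out["single_landmark_accuracy"] = self.single_landmark_accuracy.tolist()
        return out


def landmark_differences(
    shapes: np.ndarray,
    labels,
    single_landmark_loocv: bool = True,
) -> LandmarkDifferenceSummary:
    """Per-landmark displacement between the two group mean shapes.

    Ranks landmarks by the magnitude of the mean-shape displacement and,
    optionally, scores each landmark alone with a 2-feature LOOCV-LDA to
    quantify how little any single landmark discriminates.
    """
    shapes = np.asarray(shapes, dtype=float)
    labels = np.asarray(labels)
    classes = list(dict.fromkeys(labels.tolist()))
    if len(classes) != 2:
        raise ValueError("exactly two groups required")
    g1 = shapes[labels == classes[0]]
    g2 = shapes[labels == classes[1]]
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be nonempty")
    k = shapes.shape[1] // 2
    diff = (mean_shape(g1) - mean_shape(g2)).reshape(k, 2)
    mags = np.linalg.norm(diff, axis=1)
    ranking = np.argsort(-mags, kind="stable") + 1  # 1-based landmark numbers

    single_acc = None
    if single_landmark_loocv:
        single_acc = np.empty(k)
        for lm in range(k):
            cols = shapes[:, 2 * lm : 2 * lm + 2]
            rep = loocv_classify(cols, labels, feature_mode="raw")
            single_acc[lm] = rep.accuracy

    return LandmarkDifferenceSummary(
        displacements=diff,
        magnitudes=mags,
        ranking=ranking,
        single_landmark_accuracy=single_acc,
    )
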