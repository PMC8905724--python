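"""Split-half PCA + canonical variate pattern analysis of PET scan sets.

Voxel-based multivariate discrimination of time-point classes (baseline,
month 4, month 8): scans are globally normalized (divided by their
in-mask mean), reduced to ``q`` principal components, and a canonical
variate analysis — the multi-class Fisher discriminant maximizing
between-class over within-class variance — combines those components into
``N - 1`` spatial patterns of relative hypo-/hypermetabolism.  Model
stability is assessed with split-half resampling in the NPAIRS style:
subjects are repeatedly partitioned into halves, a model is fit on each,
and every split yields

* a *reproducibility* metric: Pearson correlation between the two halves'
  primary-pattern (CV1) voxel weights after sign alignment, and
* a *prediction* metric: accuracy of classifying each half's scans with
  the other half's model (nearest class centroid in canonical space),
  averaged over the two directions.

Consensus patterns are reproducibility-weighted, sign-aligned averages of
the split patterns.

Within-class scatter is ridge-regularized (``lambda = 1e-6 * trace/q``)
so duplicated scans cannot make it singular; canonical scores are scaled
to unit pooled within-class variance; the sign of each variate is
arbitrary and only fixed by alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import ParameterError, SampleSizeError

#: Ridge factor applied to the within-class covariance diagonal.
RIDGE_FACTOR = 1e-6


@dataclass
class ScanMatrix:
    """Scans as rows, in-mask voxels as columns, with subject and class ids.

    Each subject contributes at most one scan per class (one PET scan per
    time point).
    """

    X: np.ndarray
    subjects: np.ndarray  # per-row subject id
    classes: np.ndarray  # per-row class label (e.g. M0/M4/M8)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.subjects = np.asarray(self.subjects)
        self.classes = np.asarray(self.classes)
        if self.X.ndim != 2:
            raise ParameterError("scan matrix must be 2-D (scans x voxels)")
        if len(self.subjects) != len(self.X) or len(self.classes) != len(self.X):
            raise ParameterError("subject/class labels must match the number of rows")
        if not np.all(np.isfinite(self.X)):
            raise ParameterError("scan matrix contains missing values")
        pairs = list(zip(self.subjects.tolist(), self.classes.tolist()))
        if len(set(pairs)) != len(pairs):
            raise ParameterError("a subject contributes more than one scan to a class")

    @property
    def n_scans(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    def class_names(self) -> list:
        return sorted(set(self.classes.tolist()))

    def subject_ids(self) -> list:
        return sorted(set(self.subjects.tolist()))

    def subset(self, rows: np.ndarray) -> "ScanMatrix":
        return ScanMatrix(self.X[rows], self.subjects[rows], self.classes[rows])


@dataclass
class PatternModel:
    """A fitted PCA+CVA model: basis, canonical weights, patterns, scores."""

    q: int
    mean: np.ndarray  # voxel-space mean of the (normalized) training scans
    pc_basis: np.ndarray  # (voxels, q)
    canonical_weights: np.ndarray  # (q, n_classes - 1)
    patterns: np.ndarray  # (n_classes - 1, voxels), voxel-space
    scores: np.ndarray  # (scans, n_classes - 1) training canonical scores
    centroids: dict  # class -> canonical-space centroid
    class_labels: list
    eigenvalues: np.ndarray
    normalized: bool = True

    def project(self, X: np.ndarray, normalized_input: bool = False) -> np.ndarray:
        """Canonical scores of new scans under this model."""
        X = np.asarray(X, dtype=float)
        if self.normalized and not normalized_input:
            X = normalize_global(X)
        return (X - self.mean) @ self.pc_basis @ self.canonical_weights

    def classify(self, X: np.ndarray, normalized_input: bool = False) -> np.ndarray:
        """Nearest-centroid class assignment in canonical space."""
        z = self.project(X, normalized_input=normalized_input)
        labels = self.class_labels
        cents = np.stack([self.centroids[c] for c in labels])
        d = np.linalg.norm(z[:, None, :] - cents[None, :, :], axis=2)
        return np.asarray(labels, dtype=object)[np.argmin(d, axis=1)]


@dataclass
class SplitHalfMetrics:
    """Per-split reproducibility and prediction, with medians."""

    reproducibility: np.ndarray
    prediction: np.ndarray
    n_splits: int
    seed: int
    q: int
    models: list = field(default_factory=list, repr=False)  # (half1, half2) per split

    @property
    def median_reproducibility(self) -> float:
        return float(np.median(self.reproducibility))

    @property
    def median_prediction(self) -> float:
        return float(np.median(self.prediction))


def normalize_global(X: np.ndarray) -> np.ndarray:
    """Divide each scan (row) by its in-mask mean ("relative to whole brain")."""
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=1, keepdims=True)
    if np.any(means <= 0):
        raise ParameterError("global normalization requires positive scan means")
    return X / means


def fit_pca_cva(scans: ScanMatrix, q: int, normalize: bool = True) -> PatternModel:
    """Fit the PCA + canonical variate model.

    PCA is computed on the row-centered (optionally globally normalized)
    matrix via SVD; the Fisher discriminant is solved in the
    ``q``-dimensional PC score space as the generalized eigenproblem
    ``Sb w = lambda Sw w`` with ridge-stabilized within-class covariance.
    Patterns are the canonical weight vectors back-projected to voxel
    space; training scores have unit pooled within-class variance.
    """
    labels = scans.class_names()
    if len(labels) < 2:
        raise ParameterError("need at least 2 classes")
    counts = {c: int((scans.classes == c).sum()) for c in labels}
    small = [c for c, n in counts.items() if n < 2]
    if small:
        raise SampleSizeError(f"classes with fewer than 2 scans: {small}")

    X = normalize_global(scans.X) if normalize else np.asarray(scans.X, float)
    mean = X.mean(axis=0)
    Xc = X - mean
    # economy SVD; rank limited by scans - 1 after centering
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size and s[0] > 0 else 0
    if q < 1 or q > rank:
        raise ParameterError(f"q={q} outside the usable range 1..rank={rank}")
    pc_basis = Vt[:q].T  # (voxels, q)
    T = Xc @ pc_basis  # PC scores (scans, q)

    n = scans.n_scans
    k = len(labels)
    overall = T.mean(axis=0)
    Sw = np.zeros((q, q))
    Sb = np.zeros((q, q))
    for c in labels:
        rows = scans.classes == c
        Tc = T[rows]
        mc = Tc.mean(axis=0)
        d = Tc - mc
        Sw += d.T @ d
        Sb += rows.sum() * np.outer(mc - overall, mc - overall)
    Sw /= max(n - k, 1)
    Sb /= max(k - 1, 1)
    ridge = RIDGE_FACTOR * np.trace(Sw) / q
    if ridge <= 0:
        ridge = RIDGE_FACTOR
    Sw_r = Sw + ridge * np.eye(q)

    evals, evecs = scipy.linalg.eigh(Sb, Sw_r)  # ascending; w' Sw_r w = 1
    order = np.argsort(evals)[::-1][: k - 1]
    W = evecs[:, order]  # unit pooled within-class variance by construction
    evals = evals[order]

    scores = T @ W
    patterns = (pc_basis @ W).T  # (k-1, voxels)
    centroids = {c: scores[scans.classes == c].mean(axis=0) for c in labels}
    return PatternModel(
        q=q,
        mean=mean,
        pc_basis=pc_basis,
        canonical_weights=W,
        patterns=patterns,
        scores=scores,
        centroids=centroids,
        class_labels=labels,
        eigenvalues=evals,
        normalized=normalize,
    )


def _balanced_halves(subject_ids: list, rng: np.random.Generator):
    perm = rng.permutation(len(subject_ids))
    half = len(subject_ids) // 2
    ids = np.asarray(subject_ids, dtype=object)
    return set(ids[perm[:half]].tolist()), set(ids[perm[half:]].tolist())


def split_half(
    scans: ScanMatrix,
    q: int,
    n_splits: int = 100,
    seed: int = 0,
    normalize: bool = True,
) -> SplitHalfMetrics:
    """Split-half resampling of the PCA+CVA model.

    Subjects — not scans — are partitioned into random halves (each
    subject has one scan per class, so class balance follows); a model is
    fit on each half; reproducibility and prediction are computed per
    split as described in the module docstring.
    """
    subjects = scans.subject_ids()
    if len(subjects) < 4:
        raise SampleSizeError(f"split-half needs >= 4 subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    repro = np.empty(n_splits)
    pred = np.empty(n_splits)
    models: list[tuple[PatternModel, PatternModel]] = []
    for i in range(n_splits):
        a_ids, b_ids = _balanced_halves(subjects, rng)
        rows_a = np.array([s in a_ids for s in scans.subjects])
        half_a, half_b = scans.subset(rows_a), scans.subset(~rows_a)
        ma = fit_pca_cva(half_a, q, normalize=normalize)
        mb = fit_pca_cva(half_b, q, normalize=normalize)
        r = _pattern_correlation(ma.patterns[0], mb.patterns[0])
        repro[i] = abs(r)  # sign-aligned correlation
        acc_ab = float(np.mean(ma.classify(half_b.X) == half_b.classes))
        acc_ba = float(np.mean(mb.classify(half_a.X) == half_a.classes))
        pred[i] = 0.5 * (acc_ab + acc_ba)
        models.append((ma, mb))
    return SplitHalfMetrics(
        reproducibility=repro, prediction=pred, n_splits=n_splits, seed=seed, q=q,
        models=models,
    )


def _pattern_correlation(p: np.ndarray, r: np.ndarray) -> float:
    p = p - p.mean()
    r = r - r.mean()
    denom = np.linalg.norm(p) * np.linalg.norm(r)
    if denom == 0:
        return 0.0
    return float(p @ r / denom)


def consensus_pattern(
    metrics: SplitHalfMetrics,
    models: list | None = None,
    scans: ScanMatrix | None = None,
) -> PatternModel:
    """Reproducibility-weighted, sign-aligned consensus of split CV1 patterns.

    Each split contributes its two half-model CV1 patterns, weighted by
    the split's reproducibility (negative weights are clipped to zero; if
    every split has nonpositive reproducibility an unweighted mean is
    used and a warning issued).  The consensus is renormalized to unit
    norm.  When ``scans`` is given, consensus CV1 scores are computed for
    every scan by projecting the centered (normalized) data onto the
    consensus pattern.
    """
    models = metrics.models if models is None else models
    if len(models) < 2:
        raise SampleSizeError("consensus needs at least 2 splits")
    pats, weights = [], []
    for (ma, mb), r in zip(models, metrics.reproducibility):
        pats.extend([ma.patterns[0], mb.patterns[0]])
        weights.extend([r, r])
    pats = np.stack(pats)
    weights = np.clip(np.asarray(weights, float), 0.0, None)
    if weights.sum() <= 0:
        warnings.warn(
            "all split reproducibilities are nonpositive; using unweighted mean",
            stacklevel=2,
        )
        weights = np.ones(len(pats))
    ref = pats[int(np.argmax(weights))]
    signs = np.array([1.0 if _pattern_correlation(ref, p) >= 0 else -1.0 for p in pats])
    consensus = (signs[:, None] * pats * weights[:, None]).sum(axis=0) / weights.sum()
    norm = np.linalg.norm(consensus)
    if norm == 0:
        raise ParameterError("consensus pattern vanished (all patterns cancel)")
    consensus = consensus / norm

    template = models[0][0]
    scores = np.zeros((0, 1))
    class_labels = template.class_labels
    centroids = {c: np.zeros(1) for c in class_labels}
    if scans is not None:
        X = normalize_global(scans.X) if template.normalized else np.asarray(scans.X, float)
        z = (X - X.mean(axis=0)) @ consensus
        scores = z[:, None]
        centroids = {c: np.array([z[scans.classes == c].mean()]) for c in class_labels}
    return PatternModel(
        q=metrics.q,
        mean=template.mean,
        pc_basis=consensus[:, None],
        canonical_weights=np.eye(1),
        patterns=consensus[None, :],
        scores=scores,
        centroids=centroids,
        class_labels=class_labels,
        eigenvalues=np.array([np.nan]),
        normalized=template.normalized,
    )


def choose_q(
    scans: ScanMatrix,
    q_grid: list[int] | None = None,
    n_splits: int = 25,
    seed: int = 0,
    normalize: bool = True,
) -> tuple[int, dict[int, SplitHalfMetrics]]:
    """Pick the PC count maximizing median prediction + median reproducibility.

    The grid defaults to ``2..min(15, rank - 1)`` where rank is limited by
    the smaller split half.
    """
    if q_grid is None:
        n_half_scans = (len(scans.subject_ids()) // 2) * len(scans.class_names())
        q_max = min(15, n_half_scans - 2)
        if q_max < 2:
            raise SampleSizeError("too few scans to search over PC counts")
        q_grid = list(range(2, q_max + 1))
    results: dict[int, SplitHalfMetrics] = {}
    best_q, best_val = None, -np.inf
    for q in q_grid:
        m = split_half(scans, q, n_splits=n_splits, seed=seed, normalize=normalize)
        results[q] = m
        val = m.median_prediction + m.median_reproducibility
        if val > best_val:
            best_q, best_val = q, val
    assert best_q is not None
    return best_q, results
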