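"""Supervised maximum-likelihood pixel classification of protein stain.

Each class (protein, plus one or more background subclasses capturing the
different tones of unstained tissue) is modelled as a multivariate Gaussian
over RGB.  A pixel x is assigned to the class maximising the quadratic
discriminant

    ln(prior) - 0.5 ln|Sigma| - 0.5 (x - mu)^T Sigma^{-1} (x - mu),

i.e. plain maximum-likelihood classification with equal priors.  Ties go to
the lowest class index.  No spatial smoothing or morphology is applied: the
decision is strictly per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .imgio import EndospermMask, SectionImage

PROTEIN_LABEL = "protein"

#: default ridge added to each class covariance, on the 0-255 intensity scale
DEFAULT_REGULARISATION = 1e-3


@dataclass
class TrainingSet:
    """Labelled RGB pixel samples from one round of manual ROI selection.

    ``rois`` is a list of ``(label, pixels)`` pairs where ``pixels`` is an
    ``(n, 3)`` array of RGB triples.  Labels equal to ``"protein"`` (or
    starting with ``"protein"``) are the stain class; all others are
    background subclasses.
    """

    rois: list[tuple[str, np.ndarray]]
    replicate_id: int = 1

    def __post_init__(self) -> None:
        if not self.rois:
            raise ValueError("training set has no ROIs")
        self.rois = [(str(lbl), np.atleast_2d(np.asarray(px, dtype=float)))
                     for lbl, px in self.rois]
        labels = {lbl for lbl, _ in self.rois}
        if not any(_is_protein(lbl) for lbl in labels):
            raise ValueError("training set needs at least one protein ROI")
        if all(_is_protein(lbl) for lbl in labels):
            raise ValueError("training set needs at least one background ROI")
        for lbl, px in self.rois:
            if px.shape[1] != 3:
                raise ValueError(f"ROI '{lbl}' pixels must be RGB triples")
            if len(px) < 4:
                raise ValueError(
                    f"ROI '{lbl}' has {len(px)} pixels; >= 4 required for a "
                    "covariance estimate")

    def pooled(self) -> dict[str, np.ndarray]:
        """Pixel samples pooled per class label, in sorted label order."""
        out: dict[str, np.ndarray] = {}
        for lbl, px in self.rois:
            out.setdefault(lbl, []).append(px)
        return {lbl: np.vstack(chunks) for lbl, chunks in sorted(out.items())}


def _is_protein(label: str) -> bool:
    return label.startswith(PROTEIN_LABEL)


@dataclass
class ClassModel:
    """Fitted Gaussian class-conditional model over RGB.

    ``means`` is (C, 3), ``covariances`` (C, 3, 3) — already regularised and
    symmetric positive-definite — and ``priors`` (C,) summing to one.
    """

    labels: list[str]
    means: np.ndarray
    covariances: np.ndarray
    priors: np.ndarray
    protein_labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        if len(self.labels) < 2:
            raise ValueError("a class model needs >= 2 classes")
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("class priors must sum to 1")
        for k, cov in enumerate(self.covariances):
            if not np.allclose(cov, cov.T):
                raise ValueError(f"covariance of class {self.labels[k]} not symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError(
                    f"covariance of class {self.labels[k]} is singular; "
                    "use a positive regularisation")

    @property
    def protein_indices(self) -> np.ndarray:
        return np.array([i for i, lbl in enumerate(self.labels)
                         if lbl in self.protein_labels], dtype=int)


def fit_class_model(training: TrainingSet,
                    regularisation: float = DEFAULT_REGULARISATION) -> ClassModel:
    """Fit per-class Gaussians to the pooled ROI pixels of one training set.

    Each class gets its sample mean and full sample covariance (denominator
    ``n - 1``) plus ``regularisation * I``; priors are equal across classes.
    """
    if regularisation < 0:
        raise ValueError("regularisation must be >= 0")
    pooled = training.pooled()
    labels = list(pooled)
    means, covs = [], []
    for lbl, px in pooled.items():
        if len(px) < 4:
            raise ValueError(f"class '{lbl}' has fewer than 4 pixels")
        means.append(px.mean(axis=0))
        cov = np.cov(px, rowvar=False) + regularisation * np.eye(3)
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError(
                f"class '{lbl}' has a degenerate covariance (identical pixels?) "
                "and regularisation is 0")
        covs.append(cov)
    priors = np.full(len(labels), 1.0 / len(labels))
    return ClassModel(labels=labels, means=np.array(means),
                      covariances=np.array(covs), priors=priors,
                      protein_labels=frozenset(l for l in labels if _is_protein(l)))


@dataclass
class ProteinMask:
    """Boolean protein raster from one classification replicate.

    Always a subset of the endosperm region: out-of-mask pixels are False.
    """

    protein: np.ndarray
    replicate_id: int = 1

    def __post_init__(self) -> None:
        self.protein = np.asarray(self.protein, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.protein.shape

    @property
    def area_px(self) -> int:
        return int(self.protein.sum())


def discriminant_scores(pixels: np.ndarray, model: ClassModel) -> np.ndarray:
    """Per-class Gaussian log-discriminants for an (n, 3) pixel array."""
    x = np.asarray(pixels, dtype=float)
    scores = np.empty((len(x), len(model.labels)))
    for k in range(len(model.labels)):
        cov = model.covariances[k]
        cho = linalg.cho_factor(cov, lower=True)
        logdet = 2.0 * np.log(np.diag(cho[0])).sum()
        dx = x - model.means[k]
        maha = np.einsum("ij,ij->i", dx, linalg.cho_solve(cho, dx.T).T)
        scores[:, k] = np.log(model.priors[k]) - 0.5 * logdet - 0.5 * maha
    return scores


def classify_pixels(image: SectionImage, mask: EndospermMask,
                    model: ClassModel, replicate_id: int | None = None) -> ProteinMask:
    """Assign every in-mask pixel to its maximum-likelihood class.

    Returns the union of pixels assigned to protein classes; pixels outside
    the endosperm mask are always False.  Ties break to the lowest class
    index (argmax keeps the first maximum).
    """
    if mask.shape != image.shape:
        raise ValueError("mask shape does not match image shape")
    inside = mask.region
    scores = discriminant_scores(image.pixels[inside], model)
    assigned = np.argmax(scores, axis=1)
    is_protein = np.isin(assigned, model.protein_indices)
    protein = np.zeros(image.shape, dtype=bool)
    protein[inside] = is_protein
    rep = replicate_id if replicate_id is not None else 1
    return ProteinMask(protein=protein, replicate_id=rep)


def classify_replicates(image: SectionImage, mask: EndospermMask,
                        trainings: list[TrainingSet],
                        regularisation: float = DEFAULT_REGULARISATION,
                        ) -> list[ProteinMask]:
    """Run the classification once per training set (the triplicate protocol).

    Each image is classified independently with each training set, mirroring
    the practice of repeating the analysis with freshly drawn training
    samples to absorb operator variation.
    """
    if not trainings:
        raise ValueError("at least one training set is required")
    out = []
    for ts in trainings:
        model = fit_class_model(ts, regularisation=regularisation)
        out.append(classify_pixels(image, mask, model, replicate_id=ts.replicate_id))
    return out


def replicate_agreement(masks: list[ProteinMask],
                        mask: EndospermMask) -> np.ndarray:
    """Pairwise in-mask pixel agreement between classification replicates.

    Returns a symmetric matrix of agreement fractions; no pass/fail threshold
    is imposed — this is a QC statistic for the operator to inspect.
    """
    inside = mask.region
    n = len(masks)
    agree = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a = masks[i].protein[inside]
            b = masks[j].protein[inside]
            agree[i, j] = agree[j, i] = float((a == b).mean())
    return agree
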