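"""Variance decomposition and PCA visualization of 9-band spectra.

The spread of a group of spectra is summarized by a single standard
deviation pooled over the nine bands,

    sigma = sqrt( sum_lambda sum_i (y_i,lambda - ybar_lambda)^2 / n ),

with the population divisor n (not n-1) and the band sum inside the square
root.  Computed per group (e.g. per patient) and averaged across groups with
a simple unweighted mean, this separates within-group from total variance at
each aggregation level (pixel / image / patient).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA


@dataclass
class VarianceResult:
    sigma: float
    n: int
    group: str = ""
    level: str = "pixel"


@dataclass
class WithinPatientResult:
    sigma_within: float
    per_patient_sigmas: list
    n_patients: int


def group_sigma(spectra: np.ndarray, group: str = "", level: str = "pixel") -> VarianceResult:
    """Pooled population standard deviation of a set of 9-band spectra.

    ``spectra`` is (n, 9).  Equals sqrt of the sum over bands of the
    per-band population variance.
    """
    X = np.asarray(spectra, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("need an (n, 9) array with n >= 1")
    dev = X - X.mean(axis=0, keepdims=True)
    sigma = float(np.sqrt((dev**2).sum() / X.shape[0]))
    return VarianceResult(sigma=sigma, n=X.shape[0], group=group, level=level)


def within_patient_sigma(per_patient: list) -> WithinPatientResult:
    """Simple unweighted mean of per-patient group sigmas."""
    if not per_patient:
        raise ValueError("need at least one per-patient sigma")
    sigmas = [r.sigma if isinstance(r, VarianceResult) else float(r) for r in per_patient]
    return WithinPatientResult(
        sigma_within=float(np.mean(sigmas)),
        per_patient_sigmas=sigmas,
        n_patients=len(sigmas),
    )


@dataclass
class PcaProjection:
    scores: np.ndarray  # (n, k)
    explained_variance_ratio: np.ndarray  # (k,)
    components: np.ndarray  # (k, 9)
    mean: np.ndarray  # (9,)


def pca_project(spectra: np.ndarray, n_components: int = 2) -> PcaProjection:
    """Mean-centered orthogonal PCA projection of spectra.

    Sign convention: each component's largest-magnitude loading is positive,
    so scores are reproducible across library versions.
    """
    X = np.asarray(spectra, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 spectra")
    if not 1 <= n_components <= X.shape[1]:
        raise ValueError("n_components must lie in 1..9")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    comps = pca.components_.copy()
    for k in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[k]))
        if comps[k, j] < 0:
            comps[k] = -comps[k]
            scores[:, k] = -scores[:, k]
    return PcaProjection(
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        components=comps,
        mean=pca.mean_.copy(),
    )
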