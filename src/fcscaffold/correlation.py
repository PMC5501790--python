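"""Per-subject and group correlation matrices, and inter-subject variability.

The group matrix is the Fisher-averaged correlation matrix: subject-wise
Pearson matrices are z-transformed (atanh), averaged across subjects, and
back-transformed (tanh). Downstream analysis operates on its pointwise
square w_ij = r_ij^2, which discards the sign of a correlation while
preserving the ranking of its magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .timeseries import SubjectTimeSeries

_ATANH_CLIP = 1 - 1e-12


@dataclass
class CorrelationStack:
    """Per-subject N x N correlation matrices, all over the same ROIs."""

    matrices: list[np.ndarray]
    roi_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.matrices:
            raise ValueError("empty correlation stack")
        self.matrices = [np.asarray(m, dtype=float) for m in self.matrices]
        n = self.matrices[0].shape[0]
        for k, m in enumerate(self.matrices):
            if m.shape != (n, n):
                raise ValueError(f"subject {k}: shape {m.shape}, expected ({n}, {n})")
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"subject {k}: matrix not symmetric")
            if not np.allclose(np.diag(m), 1.0, atol=1e-10):
                raise ValueError(f"subject {k}: diagonal not 1")
            if np.abs(m).max() > 1 + 1e-10:
                raise ValueError(f"subject {k}: entries outside [-1, 1]")
        if self.roi_labels is None:
            self.roi_labels = [f"ROI{i + 1}" for i in range(n)]

    @property
    def n_subjects(self) -> int:
        return len(self.matrices)

    @property
    def n_rois(self) -> int:
        return self.matrices[0].shape[0]

    @classmethod
    def from_cohort(cls, cohort: list[SubjectTimeSeries]) -> "CorrelationStack":
        return cls(
            matrices=[pearson_matrix(ts) for ts in cohort],
            roi_labels=cohort[0].roi_labels,
        )


@dataclass
class GroupMatrix:
    """Fisher-averaged group correlation matrix r and its weight matrix w = r^2.

    The diagonal of w is zeroed by convention: self-links play no role in
    percolation or spanning-structure extraction.
    """

    r: np.ndarray
    roi_labels: list[str] | None = None
    w: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.w = self.r**2
        np.fill_diagonal(self.w, 0.0)
        if self.roi_labels is None:
            self.roi_labels = [f"ROI{i + 1}" for i in range(self.r.shape[0])]

    @property
    def n_rois(self) -> int:
        return self.r.shape[0]

    def weights(self, mode: str = "r2") -> np.ndarray:
        """Weight matrix under the chosen mode: r2 (default), r, or abs_r."""
        if mode == "r2":
            return self.w
        if mode in ("r", "abs_r"):
            m = np.abs(self.r) if mode == "abs_r" else self.r.copy()
            np.fill_diagonal(m, 0.0)
            return m
        raise ValueError(f"unknown weight mode {mode!r}")


@dataclass
class VariabilityMaps:
    """Entrywise across-subject mean, SD and coefficient of variation.

    ``mean`` is the plain arithmetic across-subject average. ``cv`` = sd/|mean|
    is reported only on edges whose across-subject Fisher-z values differ from
    zero after Benjamini-Hochberg FDR control; elsewhere it is NaN and
    ``retained`` is False.
    """

    mean: np.ndarray
    sd: np.ndarray
    cv: np.ndarray
    retained: np.ndarray


def pearson_matrix(ts: SubjectTimeSeries) -> np.ndarray:
    """Pairwise Pearson correlation of a subject's ROI time series."""
    x = ts.values
    if x.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        label = ts.roi_labels[bad] if ts.roi_labels else f"column {bad}"
        raise ValueError(f"constant time series for ROI {label}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -_ATANH_CLIP, _ATANH_CLIP))


def fisher_average(stack: CorrelationStack) -> GroupMatrix:
    """Group correlation matrix: tanh of the across-subject mean of atanh r."""
    z = np.mean([_fisher_z(m) for m in stack.matrices], axis=0)
    r = np.tanh(z)
    np.fill_diagonal(r, 1.0)
    return GroupMatrix(r=r, roi_labels=stack.roi_labels)


def variability_maps(stack: CorrelationStack, fdr_q: float = 0.05) -> VariabilityMaps:
    """Across-subject mean/SD maps and the FDR-masked coefficient of variation.

    The FDR mask applies a one-sample t-test of the Fisher-z values against 0,
    per edge (all N(N-1)/2 off-diagonal pairs as the family), with
    Benjamini-Hochberg control at ``fdr_q``.
    """
    if not (0 < fdr_q < 1):
        raise ValueError("fdr_q must lie in (0, 1)")
    if stack.n_subjects < 3:
        raise ValueError("need at least 3 subjects for variability maps")
    arr = np.array(stack.matrices)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    n = stack.n_rois
    iu = np.triu_indices(n, k=1)
    z = np.array([_fisher_z(m)[iu] for m in stack.matrices])
    zbar, zsd = z.mean(axis=0), z.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = zbar / (zsd / np.sqrt(stack.n_subjects))
    # zero-variance edges: t is +-inf (p=0) or nan (all-zero edge -> p=1)
    from scipy import stats

    p = 2 * stats.t.sf(np.abs(t), df=stack.n_subjects - 1)
    p = np.where(np.isnan(t), 1.0, p)
    keep = multipletests(p, alpha=fdr_q, method="fdr_bh")[0]
    retained = np.zeros((n, n), dtype=bool)
    retained[iu] = keep
    retained |= retained.T
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(retained, sd / np.abs(mean), np.nan)
    np.fill_diagonal(cv, np.nan)
    np.fill_diagonal(retained, False)
    return VariabilityMaps(mean=mean, sd=sd, cv=cv, retained=retained)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between the vectorised strict upper triangles."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    iu = np.triu_indices(a.shape[0], k=1)
    va, vb = a[iu], b[iu]
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm upper triangle")
    return float(np.dot(va, vb) / (na * nb))


def jackknife_similarity(stack: CorrelationStack) -> np.ndarray:
    """Pairwise cosine similarity between leave-one-subject-out group matrices.

    Each subject is dropped in turn and the remaining matrices are
    Fisher-averaged; the returned n x n matrix holds the cosine similarities
    between the n resulting group matrices. High off-diagonal values mean no
    single subject drives the group average.
    """
    if stack.n_subjects < 3:
        raise ValueError("jackknife needs at least 3 subjects")
    zs = np.array([_fisher_z(m) for m in stack.matrices])
    ztot = zs.sum(axis=0)
    loo = []
    for k in range(stack.n_subjects):
        r = np.tanh((ztot - zs[k]) / (stack.n_subjects - 1))
        np.fill_diagonal(r, 1.0)
        loo.append(r)
    n = stack.n_subjects
    sim = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            sim[a, b] = sim[b, a] = cosine_similarity(loo[a], loo[b])
    return sim
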