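"""Spectrum-preserving null ensemble of random correlation matrices.

The benchmark keeps the eigenvalue spectrum of the observed group
correlation matrix fixed while destroying all network structure: a random
orthogonal similarity transformation is applied to the diagonal matrix of
eigenvalues, and a sequence of Givens rotations then restores the unit
diagonal one entry at a time. By construction every member is symmetric,
unit-diagonal and positive semidefinite — no post-hoc repair is needed — so
the ensemble is a valid set of correlation matrices against which plateau
lengths and spanning-structure statistics can be benchmarked. Downstream
comparisons use the pointwise square of each member, neglecting signs while
keeping the ranking of correlation magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_EPS = 1e-12


@dataclass
class SpectrumProfile:
    """Eigenvalue spectrum of a correlation matrix: nonnegative, summing to N."""

    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.eigenvalues, dtype=float)
        if lam.min() < -1e-10:
            raise ValueError(f"negative eigenvalue {lam.min():.3e} in spectrum")
        lam = np.clip(lam, 0.0, None)
        n = len(lam)
        if abs(lam.sum() - n) > 1e-8:
            raise ValueError(
                f"eigenvalues sum to {lam.sum():.10f}, expected N={n} "
                "(trace of a correlation matrix)"
            )
        self.eigenvalues = np.sort(lam)

    @property
    def n(self) -> int:
        return len(self.eigenvalues)

    @classmethod
    def from_correlation(cls, r: np.ndarray, tol: float = 1e-8) -> "SpectrumProfile":
        """Extract the spectrum, clipping eigenvalues negative within ``tol``."""
        lam = np.linalg.eigvalsh(np.asarray(r, dtype=float))
        if lam.min() < -tol:
            raise ValueError(
                f"matrix has eigenvalue {lam.min():.3e} < -{tol:g}; "
                "repair it to PSD upstream before building the null ensemble"
            )
        lam = np.clip(lam, 0.0, None)
        lam *= len(lam) / lam.sum()  # restore trace N exactly after clipping
        return cls(eigenvalues=lam)


@dataclass
class NullEnsemble:
    matrices: list[np.ndarray]
    seeds: list[int]
    source_spectrum: SpectrumProfile

    def __len__(self) -> int:
        return len(self.matrices)

    def squared(self) -> list[np.ndarray]:
        """Pointwise-squared members with zeroed diagonal (comparison scale)."""
        out = []
        for m in self.matrices:
            w = m**2
            np.fill_diagonal(w, 0.0)
            out.append(w)
        return out


def haar_orthogonal(n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Random orthogonal matrix from the Haar (rotation-invariant) measure.

    A standard Gaussian matrix is QR-factorised and the signs of Q's columns
    are fixed by the sign of R's diagonal, which makes the distribution
    exactly rotation invariant.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = rng.standard_normal((n, n))
    q, r = np.linalg.qr(g)
    d = np.diag(r)
    return q * np.where(d == 0, 1.0, np.sign(d))


def _givens_fix(a: np.ndarray, i: int, j: int) -> None:
    """Rotate in the (i, j) plane so that a[i, i] becomes exactly 1.

    Requires (a_ii - 1)(a_jj - 1) < 0. Of the two angles achieving the fix,
    the smaller-magnitude one is used.
    """
    aii, ajj, aij = a[i, i], a[j, j], a[i, j]
    # t = tan(theta) solves t^2 (ajj - 1) + 2 t aij + (aii - 1) = 0
    disc = aij * aij - (aii - 1.0) * (ajj - 1.0)
    disc = max(disc, 0.0)
    root = np.sqrt(disc)
    t1 = (-aij + root) / (ajj - 1.0)
    t2 = (-aij - root) / (ajj - 1.0)
    t = t1 if abs(t1) <= abs(t2) else t2
    c = 1.0 / np.sqrt(1.0 + t * t)
    s = t * c
    rows_i, rows_j = a[i].copy(), a[j].copy()
    a[i] = c * rows_i + s * rows_j
    a[j] = -s * rows_i + c * rows_j
    cols_i, cols_j = a[:, i].copy(), a[:, j].copy()
    a[:, i] = c * cols_i + s * cols_j
    a[:, j] = -s * cols_i + c * cols_j
    a[i, i] = 1.0  # exact by construction; kill roundoff
    a[i, j] = a[j, i] = (a[i, j] + a[j, i]) / 2.0


def fixed_spectrum_correlation(
    spectrum: SpectrumProfile, seed: int | np.random.Generator
) -> np.ndarray:
    """Random correlation matrix with exactly the given eigenvalue spectrum.

    Start from A0 = Q diag(lambda) Q^T with Q Haar orthogonal, then apply at
    most N-1 Givens rotations, each making one diagonal entry exactly 1: a
    rotation in the (i, j) plane with a_ii < 1 < a_jj can set a_ii = 1 while
    leaving the spectrum untouched (similarity transform). Because the trace
    is N, such a pair exists whenever the diagonal is not all ones.
    """
    n = spectrum.n
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = haar_orthogonal(n, rng)
    a = (q * spectrum.eigenvalues) @ q.T
    a = (a + a.T) / 2.0
    for _ in range(n - 1):
        d = np.diag(a)
        low = np.flatnonzero(d < 1.0 - _EPS)
        high = np.flatnonzero(d > 1.0 + _EPS)
        if low.size == 0 or high.size == 0:
            break
        _givens_fix(a, int(low[0]), int(high[0]))
    if np.abs(np.diag(a) - 1.0).max() > 1e-9:
        raise RuntimeError(
            "Givens sweep failed to restore the unit diagonal; this indicates a bug"
        )
    np.fill_diagonal(a, 1.0)
    a = (a + a.T) / 2.0
    np.clip(a, -1.0, 1.0, out=a)
    return a


def ensemble_generate(
    group, n: int = 100, master_seed: int = 0
) -> NullEnsemble:
    """Generate n spectrum-preserving randomizations of a group matrix.

    ``group`` is a GroupMatrix or a plain correlation matrix. Member i uses
    seed ``master_seed * 10000 + i``.
    """
    r = group.r if hasattr(group, "r") else np.asarray(group, dtype=float)
    spectrum = SpectrumProfile.from_correlation(r)
    seeds = [master_seed * 10000 + i for i in range(n)]
    matrices = [fixed_spectrum_correlation(spectrum, s) for s in seeds]
    return NullEnsemble(matrices=matrices, seeds=seeds, source_spectrum=spectrum)
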