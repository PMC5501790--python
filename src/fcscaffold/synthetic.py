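"""Synthetic multi-subject ROI time series with planted modular structure.

The generator emulates a resting-state cohort: a population correlation
matrix with block/chain modular structure (tunable within-module,
between-module and bilateral-pair correlation levels), perturbed per subject
on the Fisher-z scale, then sampled as zero-mean multivariate-normal time
series. Every downstream stage of the pipeline (group averaging,
percolation, null comparison, spanning scaffold) is testable against the
planted ground truth without any data download.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .timeseries import SubjectTimeSeries

TOPOLOGIES = ("chain", "star", "clique", "pair")


@dataclass
class ModuleSpec:
    """One planted module: a named group of ROI indices and its topology.

    ``members`` are 0-based ROI indices. Topology fixes which pairs are
    "adjacent" (receive the full within-module correlation): chain links
    consecutive members, star links the first member (hub) to every other,
    pair links the two members, clique links all pairs.
    """

    name: str
    members: list[int]
    topology: str = "chain"

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"module {self.name!r}: unknown topology {self.topology!r}")
        if len(self.members) < 1:
            raise ValueError(f"module {self.name!r}: empty member list")
        if self.topology == "pair" and len(self.members) != 2:
            raise ValueError(f"module {self.name!r}: pair topology needs exactly 2 members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"module {self.name!r}: duplicate members")

    def graph_distances(self) -> np.ndarray:
        """Topology-graph distance between members (by position in the module)."""
        m = len(self.members)
        d = np.full((m, m), np.inf)
        np.fill_diagonal(d, 0)
        if self.topology in ("chain", "pair"):
            for a in range(m):
                for b in range(m):
                    d[a, b] = abs(a - b)
        elif self.topology == "star":
            d[0, 1:] = d[1:, 0] = 1
            d[1:, 1:] = 2
            np.fill_diagonal(d, 0)
        else:  # clique
            d[:] = 1
            np.fill_diagonal(d, 0)
        return d


@dataclass
class CohortSpec:
    """Design of a synthetic cohort.

    Defaults emulate the study scale this pipeline targets: 40 subjects,
    T = 240 time points, N = 116 regions organised into 8 chain modules.
    ``r_within`` is the correlation of topology-adjacent pairs, ``r_between``
    the baseline between-module correlation, and ``subject_noise_sd`` the SD
    of i.i.d. subject-level perturbations applied on the Fisher-z scale.
    """

    modules: list[ModuleSpec]
    n_subjects: int = 40
    n_timepoints: int = 240
    r_within: float = 0.6
    r_between: float = 0.1
    subject_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_timepoints < 3:
            raise ValueError("need n_subjects >= 1 and n_timepoints >= 3")
        if not (0 <= self.r_within < 1):
            raise ValueError("r_within must lie in [0, 1)")
        if not (0 <= self.r_between <= self.r_within):
            raise ValueError("need 0 <= r_between <= r_within")
        members = sorted(i for m in self.modules for i in m.members)
        n = len(members)
        if members != list(range(n)):
            raise ValueError("modules must partition ROI indices 0..N-1 exactly")
        if self.n_timepoints <= n:
            warnings.warn(
                f"T={self.n_timepoints} <= N={n}: subject correlation matrices "
                "will be rank-deficient",
                stacklevel=2,
            )

    @property
    def n_rois(self) -> int:
        return sum(len(m.members) for m in self.modules)

    def roi_labels(self) -> list[str]:
        labels = [""] * self.n_rois
        for mod in self.modules:
            for pos, idx in enumerate(mod.members):
                labels[idx] = f"{mod.name}_{pos + 1}"
        return labels

    def module_of(self) -> list[str]:
        """Module name for each ROI index."""
        out = [""] * self.n_rois
        for mod in self.modules:
            for idx in mod.members:
                out[idx] = mod.name
        return out


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The documented default design: 8 chain modules over N=116 ROIs.

    Chain sizes [26, 18, 14, 12, 12, 12, 12, 10] mimic a parcellation-scale
    network with a few long chains (cerebellum-like) and several shorter ones.
    """
    sizes = [26, 18, 14, 12, 12, 12, 12, 10]
    modules, start = [], 0
    for k, s in enumerate(sizes):
        modules.append(ModuleSpec(f"chain{k + 1}", list(range(start, start + s)), "chain"))
        start += s
    return CohortSpec(modules=modules, seed=seed, **overrides)


def _psd_repair(a: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues at 0 and renormalise to unit diagonal."""
    lam, v = np.linalg.eigh(a)
    lam = np.clip(lam, 0, None)
    fixed = (v * lam) @ v.T
    d = np.sqrt(np.diag(fixed))
    if np.any(d <= 0):
        raise ValueError("PSD repair produced a zero-variance row")
    fixed = fixed / np.outer(d, d)
    fixed = (fixed + fixed.T) / 2
    np.fill_diagonal(fixed, 1.0)
    return fixed


def planted_population_correlation(spec: CohortSpec) -> np.ndarray:
    """Ground-truth population correlation matrix for a cohort design.

    Topology-adjacent within-module pairs get ``r_within``; non-adjacent
    within-module pairs decay geometrically with topology-graph distance d
    (``r_within**d``, the correlation profile of a Gaussian chain), floored at
    ``r_between``; between-module pairs get ``r_between``. The result is
    repaired to positive semidefiniteness by eigenvalue clipping at zero and
    diagonal renormalisation; if the repair moves any entry by more than 0.05
    a ``ValueError`` names the offending module.
    """
    n = spec.n_rois
    target = np.full((n, n), spec.r_between, dtype=float)
    np.fill_diagonal(target, 1.0)
    for mod in spec.modules:
        idx = np.array(mod.members)
        d = mod.graph_distances()
        with np.errstate(over="ignore"):
            vals = np.where(
                np.isfinite(d), np.maximum(spec.r_within ** d, spec.r_between), spec.r_between
            )
            vals = np.where(d == 1, spec.r_within, vals)  # adjacency carries r_within exactly
        np.fill_diagonal(vals, 1.0)
        target[np.ix_(idx, idx)] = vals
    repaired = _psd_repair(target)
    distortion = np.abs(repaired - target)
    if distortion.max() > 0.05:
        i, j = np.unravel_index(np.argmax(distortion), distortion.shape)
        module_of = spec.module_of()
        where = module_of[i] if module_of[i] == module_of[j] else f"{module_of[i]}/{module_of[j]}"
        raise ValueError(
            f"requested correlation levels are not realisable: PSD repair moved "
            f"entry ({i},{j}) in module {where} by {distortion.max():.3f} (> 0.05)"
        )
    return repaired


def planted_adjacency(spec: CohortSpec) -> np.ndarray:
    """Boolean N x N matrix marking topology-adjacent within-module pairs."""
    n = spec.n_rois
    adj = np.zeros((n, n), dtype=bool)
    for mod in spec.modules:
        idx = np.array(mod.members)
        d = mod.graph_distances()
        adj[np.ix_(idx, idx)] = d == 1
    return adj


def _subject_correlation(
    planted_z: np.ndarray, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    n = planted_z.shape[0]
    noise = np.triu(rng.normal(0.0, noise_sd, (n, n)), 1)
    z = planted_z + noise + noise.T
    r = np.tanh(z)
    np.fill_diagonal(r, 1.0)
    return _psd_repair(r)


def generate_cohort(spec: CohortSpec) -> list[SubjectTimeSeries]:
    """Draw a cohort of subject time series from the planted design.

    Each subject's correlation matrix is the planted matrix perturbed on the
    Fisher-z scale by i.i.d. N(0, subject_noise_sd^2) noise (re-symmetrised,
    diagonal restored, PSD-clipped); T samples are then drawn from a zero-mean
    multivariate normal with that correlation. Deterministic given the spec's
    seed: subject i uses seed ``spec.seed * 1000 + i``.
    """
    planted = planted_population_correlation(spec)
    planted_z = np.arctanh(np.clip(planted, -1 + 1e-12, 1 - 1e-12))
    np.fill_diagonal(planted_z, 0.0)
    labels = spec.roi_labels()
    cohort = []
    for i in range(spec.n_subjects):
        rng = np.random.default_rng(spec.seed * 1000 + i)
        corr = None
        for _ in range(10):
            try:
                corr = _subject_correlation(planted_z, spec.subject_noise_sd, rng)
                break
            except ValueError:
                continue
        if corr is None:
            raise RuntimeError(f"subject {i}: could not build a valid correlation matrix")
        lam, v = np.linalg.eigh(corr)
        root = v * np.sqrt(np.clip(lam, 0, None))
        values = rng.standard_normal((spec.n_timepoints, spec.n_rois)) @ root.T
        cohort.append(
            SubjectTimeSeries(values=values, subject_id=f"subject{i:03d}", roi_labels=labels)
        )
    return cohort
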