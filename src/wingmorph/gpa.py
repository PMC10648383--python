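"""Generalized Procrustes analysis for 2D landmark configurations.

Superimposition removes the similarity nuisances — translation (centering),
size (scaling every configuration to unit centroid size) and orientation
(least-squares rotation onto an iteratively re-estimated consensus).  The
rotations are proper (det = +1): reflections are never absorbed, so mixed
wing chirality surfaces as misfit rather than being silently corrected.

The output gauge (overall orientation, which GPA leaves undefined) is fixed
by rotating the converged consensus, together with every aligned
configuration, to best match the first specimen's original orientation; this
makes results byte-stable across runs and platforms.

Optionally the aligned shapes are orthogonally projected onto the tangent
plane at the consensus, flattening the shape sphere so that downstream linear
statistics (PCA, LDA, regression) operate in a Euclidean space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import LandmarkDataset

_CENTER_TOL = 1e-9


class DegenerateConfigurationError(ValueError):
    """All landmarks coincide; size and shape are undefined."""


def centroid_size(config: np.ndarray) -> float:
    """Centroid size: sqrt of the summed squared landmark distances from the
    centroid — the standard geometric-morphometrics size proxy.
    """
    config = np.asarray(config, dtype=float)
    if config.ndim != 2 or config.shape[0] < 2:
        raise ValueError("configuration must be a (k >= 2, d) array")
    if not np.isfinite(config).all():
        raise ValueError("configuration has non-finite coordinates")
    centered = config - config.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs == 0.0:
        raise DegenerateConfigurationError(
            "all landmarks coincide; centroid size is zero"
        )
    return cs


def _center_scale(config: np.ndarray) -> tuple[np.ndarray, float]:
    """Center a configuration and scale it to unit centroid size."""
    config = np.asarray(config, dtype=float)
    centered = config - config.mean(axis=0)
    cs = centroid_size(config)
    return centered / cs, cs


def align_pair(
    moving: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, float]:
    """Ordinary (rotation-only) Procrustes fit of one preshape onto another.

    Both inputs must already be centered and scaled to unit centroid size.
    Returns the rotated copy of ``moving`` and the minimized residual sum of
    squares.  The rotation is constrained to det = +1 via the SVD sign
    correction, so a reflected configuration keeps a strictly positive
    residual.
    """
    moving = np.asarray(moving, dtype=float)
    target = np.asarray(target, dtype=float)
    if moving.shape != target.shape:
        raise ValueError("configurations must have identical shapes")
    for name, cfg in (("moving", moving), ("target", target)):
        if np.abs(cfg.mean(axis=0)).max() > _CENTER_TOL:
            raise ValueError(f"{name} configuration is not centered")
        if abs(np.sqrt(np.sum(cfg**2)) - 1.0) > _CENTER_TOL:
            raise ValueError(f"{name} configuration is not unit centroid size")
    rotation = optimal_rotation(moving, target)
    rotated = moving @ rotation.T
    residual = float(np.sum((rotated - target) ** 2))
    return rotated, residual


def optimal_rotation(moving: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R (det=+1) minimizing ||R·moving_i − target_i||²."""
    h = target.T @ moving  # 2x2 cross-covariance
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


@dataclass
class SuperimpositionResult:
    """Output of GPA: aligned shapes, sizes, consensus and convergence trace."""

    aligned: np.ndarray  # (n, k, 2) superimposed shape coordinates
    centroid_sizes: np.ndarray  # (n,) in input units
    consensus: np.ndarray  # (k, 2), centered, unit centroid size
    iterations: int
    q_trace: list[float] = field(default_factory=list)
    projected: bool = True
    converged: bool = True

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    def shape_vectors(self) -> np.ndarray:
        """Aligned shapes flattened to (n, 2k) vectors (x1,y1,...,xk,yk)."""
        return self.aligned.reshape(self.n, -1)

    def consensus_vector(self) -> np.ndarray:
        return self.consensus.ravel()


def gpa(
    dataset: LandmarkDataset | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
    project: bool = True,
) -> SuperimpositionResult:
    """Generalized Procrustes superimposition of a landmark sample.

    Parameters
    ----------
    dataset
        LandmarkDataset or raw (n, k, 2) coordinate array.
    tol
        Convergence threshold on the decrease of the total residual
        Q = sum of squared deviations from the consensus.
    max_iter
        Iteration cap; non-convergence is recorded on the result (and warned),
        not fatal.
    project
        Apply orthogonal tangent-space projection at the consensus.
    """
    if isinstance(dataset, LandmarkDataset):
        coords = dataset.coords_array()
    else:
        coords = np.asarray(dataset, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 2:
            raise ValueError("expected an (n, k, 2) coordinate array")
    n, k, _ = coords.shape
    if n == 0:
        raise ValueError("empty dataset")
    if k < 3:
        raise ValueError("GPA requires at least 3 landmarks")

    preshapes = np.empty_like(coords)
    sizes = np.empty(n)
    for i in range(n):
        preshapes[i], sizes[i] = _center_scale(coords[i])

    aligned = preshapes.copy()
    consensus = preshapes[0].copy()
    q_trace: list[float] = []
    q_prev = np.inf
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            rotation = optimal_rotation(aligned[i], consensus)
            aligned[i] = aligned[i] @ rotation.T
        new_consensus = aligned.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        new_consensus /= np.sqrt(np.sum(new_consensus**2))
        consensus = new_consensus
        q = float(np.sum((aligned - consensus) ** 2))
        q_trace.append(q)
        if q_prev - q < tol:
            converged = True
            break
        q_prev = q
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations "
            f"(last Q decrease {q_prev - q_trace[-1]:.3e})",
            RuntimeWarning,
            stacklevel=2,
        )

    # Fix the rotational gauge: orient the consensus (and all aligned shapes
    # with it) to best match specimen 1's original orientation.
    gauge = optimal_rotation(consensus, preshapes[0])
    consensus = consensus @ gauge.T
    aligned = aligned @ gauge.T

    if project:
        vc = consensus.ravel()  # unit norm: centered, unit centroid size
        flat = aligned.reshape(n, -1)
        # v' = v_c + (I − v_c v_cᵀ)(v − v_c) = v + (1 − v_cᵀ v) v_c
        flat = flat + np.outer(1.0 - flat @ vc, vc)
        aligned = flat.reshape(n, k, 2)

    return SuperimpositionResult(
        aligned=aligned,
        centroid_sizes=sizes,
        consensus=consensus,
        iterations=iterations,
        q_trace=q_trace,
        projected=project,
        converged=converged,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two shape vectors from one superimposition."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("shape vectors must have equal length")
    return float(np.linalg.norm(a - b))


def mean_shape(vectors: np.ndarray) -> np.ndarray:
    """Coordinate-wise mean of a nonempty stack of shape vectors."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.size == 0:
        raise ValueError("cannot average an empty set of shape vectors")
    if vectors.ndim == 1:
        return vectors.copy()
    return vectors.mean(axis=0)
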