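"""Relationship-kernel algebra for multi-kernel hybrid prediction.

Builds the covariance structures of a GCA/SCA kernel model:

* marker-based realized kinship ``G = XX'/n`` on centered dosages
  (VanRaden-type, with the marker-count denominator as printed and the
  classical ``2 * sum(p_j (1 - p_j))`` denominator available as an option);
* the SCA kernel ``H`` over hybrids as the Kronecker product of the female
  and male GCA kernels, restricted to realized crosses;
* expansion of entity-level kernels to record level through incidence
  matrices, ``Z K Z'``;
* genotype-by-environment (and NIR-by-environment) interaction kernels via
  the Hadamard product with the environment-sharing indicator
  ``Z_E Z_E'`` (a Schur product of PSD matrices, hence PSD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import IncidenceMap

__all__ = [
    "RelationshipKernel",
    "vanraden_relationship",
    "sca_kronecker",
    "expand_to_records",
    "interaction_hadamard",
    "clip_psd",
]

_SYM_TOL = 1e-10
_EIG_TOL = -1e-8


@dataclass
class RelationshipKernel:
    """A labeled symmetric PSD similarity matrix over entities or records."""

    matrix: np.ndarray
    ids: list
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.ids = list(self.ids)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("kernel matrix must be square")
        if len(self.ids) != n:
            raise ValueError("ids length must match matrix dimension")
        if len(set(self.ids)) != n:
            raise ValueError("kernel ids must be unique")
        asym = np.max(np.abs(self.matrix - self.matrix.T)) if n else 0.0
        if asym > 1e-8:
            raise ValueError(f"kernel not symmetric (max asymmetry {asym:.3g})")
        # symmetrize exactly against roundoff
        self.matrix = 0.5 * (self.matrix + self.matrix.T)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def loc(self, ids: list) -> np.ndarray:
        """Submatrix for the given entity ids (order respected)."""
        pos = {e: i for i, e in enumerate(self.ids)}
        idx = np.array([pos[e] for e in ids])
        return self.matrix[np.ix_(idx, idx)]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix)[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: str = "unknown") -> "RelationshipKernel":
        return cls(frame.to_numpy(dtype=float), list(frame.index), provenance)


def clip_psd(matrix: np.ndarray, tol: float = _EIG_TOL) -> np.ndarray:
    """Clip small negative eigenvalues (> ``tol``) to zero.

    Raises if the matrix is indefinite beyond the tolerance — that signals
    a construction bug rather than roundoff.
    """
    w, V = np.linalg.eigh(0.5 * (matrix + matrix.T))
    if w[0] < tol * max(1.0, abs(w[-1])):
        raise ValueError(f"matrix is not PSD (min eigenvalue {w[0]:.3g})")
    w = np.clip(w, 0.0, None)
    return (V * w) @ V.T


def vanraden_relationship(
    dosages: pd.DataFrame | np.ndarray,
    ids: list | None = None,
    provenance: str = "genomic",
    denominator: str = "n_markers",
) -> RelationshipKernel:
    """Marker-based realized relationship matrix on centered dosages.

    ``G = X_c X_c' / d`` where ``X_c`` is the dosage matrix with each marker
    column centered on its mean.  ``denominator`` selects ``d``:

    * ``"n_markers"`` — the number of markers (the form used throughout
      this package);
    * ``"2pq"`` — the classical VanRaden scaling ``2 * sum(p_j (1 - p_j))``
      with ``p_j`` the allele frequency of marker j.
    """
    if isinstance(dosages, pd.DataFrame):
        if ids is None:
            ids = list(dosages.index)
        X = dosages.to_numpy(dtype=float)
    else:
        X = np.asarray(dosages, dtype=float)
        if ids is None:
            ids = [f"I{i + 1}" for i in range(X.shape[0])]
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("dosage matrix must be 2-D with at least one marker")
    if np.isnan(X).all(axis=0).any():
        raise ValueError("dosage matrix contains an all-missing marker")
    col_means = np.nanmean(X, axis=0)
    Xc = X - col_means
    if denominator == "n_markers":
        d = X.shape[1]
    elif denominator == "2pq":
        p = col_means / 2.0
        d = 2.0 * np.sum(p * (1.0 - p))
        if d <= 0:
            raise ValueError("all markers monomorphic: 2pq denominator is zero")
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    G = Xc @ Xc.T / d
    return RelationshipKernel(G, ids, provenance)


def sca_kronecker(
    G_f: RelationshipKernel,
    G_m: RelationshipKernel,
    hybrid_index: pd.DataFrame,
) -> RelationshipKernel:
    """SCA kernel over hybrids from the female x male Kronecker product.

    ``H[(f1,m1),(f2,m2)] = G_f[f1,f2] * G_m[m1,m2]``, restricted to the
    realized hybrids listed in ``hybrid_index`` (columns ``hybrid``,
    ``female``, ``male``).
    """
    for col in ("hybrid", "female", "male"):
        if col not in hybrid_index.columns:
            raise KeyError(f"hybrid index lacks column {col!r}")
    fpos = {e: i for i, e in enumerate(G_f.ids)}
    mpos = {e: i for i, e in enumerate(G_m.ids)}
    try:
        fi = np.array([fpos[f] for f in hybrid_index["female"]])
        mi = np.array([mpos[m] for m in hybrid_index["male"]])
    except KeyError as exc:
        raise KeyError(f"hybrid references unknown parent {exc}") from exc
    H = G_f.matrix[np.ix_(fi, fi)] * G_m.matrix[np.ix_(mi, mi)]
    return RelationshipKernel(H, list(hybrid_index["hybrid"]), "SCA")


def expand_to_records(
    kernel: RelationshipKernel,
    incidence: IncidenceMap,
    factor: str,
) -> np.ndarray:
    """Expand an entity kernel to record level: ``(Z K Z')[i,j] = K[e(i), e(j)]``.

    PSD is preserved (congruence by the 0/1 incidence matrix).
    """
    pos = {e: i for i, e in enumerate(kernel.ids)}
    labels = incidence.records[factor]
    unknown = set(labels) - set(kernel.ids)
    if unknown:
        raise KeyError(f"records map to entities absent from kernel: {sorted(unknown)}")
    idx = np.array([pos[e] for e in labels])
    return kernel.matrix[np.ix_(idx, idx)]


def interaction_hadamard(
    expanded: np.ndarray,
    incidence: IncidenceMap,
    env_factor: str = "environment",
    provenance: str = "interaction",
) -> np.ndarray:
    """G-by-E covariance: zero out kernel entries across different environments.

    ``V = (Z K Z') .* (Z_E Z_E')`` — the element-wise product of the
    record-expanded main-effect kernel with the environment-sharing
    indicator.  Entries between records in different environments vanish;
    within-environment blocks are untouched.  PSD by the Schur product
    theorem.
    """
    expanded = np.asarray(expanded, dtype=float)
    if expanded.shape[0] != incidence.n_records:
        raise ValueError(
            f"expanded kernel has {expanded.shape[0]} records but incidence map has "
            f"{incidence.n_records}"
        )
    env = incidence.indices(env_factor)
    same_env = (env[:, None] == env[None, :]).astype(float)
    return expanded * same_env
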