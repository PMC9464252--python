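"""Kernel factor construction: phi(G) for each test design.

All tests share the quadratic-form structure K = phi(G) phi(G)^T where
phi maps the n x m dosage matrix into n x g intermediate variables:

* ``collapse_max``      — gene-based variant collapsing: the per-individual
  maximum variant weight (an n x 1 burden variable).
* ``phi_linear``        — weighted linear kernel, phi = G_c diag(sqrt w).
* ``phi_local_collapse``— locally collapsing kernel: weighted dosages of
  variants hitting the same amino-acid position summed into one column,
  phi = G_c diag(sqrt w) C.
* ``phi_rbp``           — directional kernel for RBP-binding predictions,
  phi = G_c diag(sqrt w) L with L L^T = S = Q o R (cosine similarity of
  effect vectors times a Gaussian positional similarity).

G_c denotes column-mean-centered minor-allele dosages; missing dosages
are mean-imputed per variant before centering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KernelFactor",
    "EmptyGeneError",
    "KernelNumericsError",
    "DEFAULT_GAMMA",
    "collapse_max",
    "phi_linear",
    "phi_local_collapse",
    "phi_rbp",
    "concat_plof",
    "rbp_similarity",
    "position_similarity",
    "center_and_impute",
]

#: Gaussian position-similarity bandwidth: two variants 50 bp apart have
#: similarity 0.5.
DEFAULT_GAMMA = -np.log(0.5) / 50.0**2


class EmptyGeneError(ValueError):
    """Raised when a gene has no variants to build a kernel from."""


class KernelNumericsError(RuntimeError):
    """Raised when the variant-similarity matrix cannot be factorized."""


@dataclass
class KernelFactor:
    """The n x g matrix phi(G) with column provenance."""

    matrix: np.ndarray
    column_labels: list[str]
    design: str  # collapse_max | linear | local_collapse | rbp
    centered: bool = True
    has_plof_column: bool = False

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def g(self) -> int:
        return self.matrix.shape[1]

    def kernel(self) -> np.ndarray:
        """K = phi phi^T (n x n); mainly for diagnostics and small tests."""
        return self.matrix @ self.matrix.T

    def dump_tsv(self, path: str) -> None:
        """Debug dump of the dense factor with its column labels."""
        header = "\t".join(self.column_labels)
        np.savetxt(path, self.matrix, delimiter="\t", header=header, comments="")


def center_and_impute(G: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages per variant, then column-mean-center."""
    G = np.array(G, dtype=float)
    if G.ndim != 2:
        raise ValueError("G must be 2-D (samples x variants)")
    col_mean = np.nanmean(G, axis=0)
    nan_idx = np.where(np.isnan(G))
    if nan_idx[0].size:
        G[nan_idx] = np.take(col_mean, nan_idx[1])
    return G - G.mean(axis=0)


def _check_weights(w: np.ndarray, m: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (m,):
        raise ValueError(f"expected {m} weights, got shape {w.shape}")
    if np.any((w < 0) | (w > 1)):
        raise ValueError("weights must lie in [0, 1]")
    return w


def collapse_max(G: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Max-weight burden: per individual, the largest weight among carried
    variants (dosage >= 1), or 0 for non-carriers.  Returned uncentered;
    the test layer centers it."""
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[1] == 0:
        raise EmptyGeneError("collapse_max needs at least one variant")
    w = _check_weights(w, G.shape[1])
    carried = (G >= 1).astype(float)  # missing must be imputed upstream
    return (carried * w[None, :]).max(axis=1)


def _drop_zero_weight(G_c: np.ndarray, w: np.ndarray, labels: list[str]):
    keep = w > 0
    return G_c[:, keep], w[keep], [l for l, k in zip(labels, keep) if k], keep


def phi_linear(
    G: np.ndarray, w: np.ndarray, variant_ids: list[str] | None = None
) -> KernelFactor:
    """Weighted linear kernel factor phi = G_c diag(sqrt w)."""
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[1] == 0:
        raise EmptyGeneError("phi_linear needs at least one variant")
    m = G.shape[1]
    w = _check_weights(w, m)
    labels = variant_ids or [f"v{j}" for j in range(m)]
    G_c = center_and_impute(G)
    G_c, w, labels, _ = _drop_zero_weight(G_c, w, labels)
    if G_c.shape[1] == 0:
        raise EmptyGeneError("all variants carry zero weight")
    phi = G_c * np.sqrt(w)[None, :]
    return KernelFactor(phi, labels, "linear")


def phi_local_collapse(
    G: np.ndarray,
    w: np.ndarray,
    aa_positions: np.ndarray,
    signs: np.ndarray | None = None,
) -> KernelFactor:
    """Locally collapsing kernel factor phi = G_c diag(sqrt w) C.

    C is the m x g group-assignment matrix; variants mapping to the same
    amino-acid position share a column, with entry sign(v_i) (all +1 for
    unsigned effect predictions).  Singleton groups reproduce the linear
    kernel exactly.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[1] == 0:
        raise EmptyGeneError("phi_local_collapse needs at least one variant")
    m = G.shape[1]
    w = _check_weights(w, m)
    aa = np.asarray(aa_positions)
    if aa.shape != (m,) or np.any(pd_isna(aa)):
        raise ValueError("every variant needs an amino-acid position")
    if signs is None:
        signs = np.ones(m)
    signs = np.asarray(signs, dtype=float)
    if not np.all(np.isin(signs, (-1.0, 1.0))):
        raise ValueError("signs must be +1 or -1")

    G_c = center_and_impute(G)
    keep = w > 0
    G_c, w, aa, signs = G_c[:, keep], w[keep], aa[keep], signs[keep]
    if G_c.shape[1] == 0:
        raise EmptyGeneError("all variants carry zero weight")

    groups = sorted(set(aa.tolist()))
    C = np.zeros((len(aa), len(groups)))
    for j, grp in enumerate(groups):
        mask = aa == grp
        C[mask, j] = signs[mask]
    phi = (G_c * np.sqrt(w)[None, :]) @ C
    return KernelFactor(phi, [str(g) for g in groups], "local_collapse")


def pd_isna(a: np.ndarray) -> np.ndarray:
    # local helper: NaN check that tolerates integer/object arrays
    try:
        return np.isnan(np.asarray(a, dtype=float))
    except (TypeError, ValueError):
        return np.array([x is None for x in np.asarray(a, dtype=object)])


def position_similarity(positions: np.ndarray, gamma: float = DEFAULT_GAMMA) -> np.ndarray:
    """Gaussian similarity R with r_ij = exp(-gamma (x_i - x_j)^2)."""
    x = np.asarray(positions, dtype=float)
    d = x[:, None] - x[None, :]
    return np.exp(-gamma * d**2)


def rbp_similarity(
    effect_vectors: np.ndarray,
    positions: np.ndarray,
    gamma: float = DEFAULT_GAMMA,
) -> np.ndarray:
    """S = Q o R: cosine similarity of effect vectors times the Gaussian
    position similarity.  Effect vectors must be nonzero."""
    V = np.asarray(effect_vectors, dtype=float)
    norms = np.linalg.norm(V, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero effect vector: cosine similarity undefined")
    U = V / norms[:, None]
    Q = np.clip(U @ U.T, -1.0, 1.0)
    R = position_similarity(positions, gamma)
    return Q * R


def _cholesky_with_ridge(S: np.ndarray, gene_id: str = "?") -> np.ndarray:
    """Cholesky factor of S, adding an escalating ridge when S is
    numerically singular (variants sharing position and effect vector
    make S rank-deficient)."""
    m = S.shape[0]
    base = np.trace(S) / m
    ridge = 0.0
    for _ in range(6):
        try:
            return np.linalg.cholesky(S + ridge * np.eye(m))
        except np.linalg.LinAlgError:
            ridge = base * 1e-8 if ridge == 0.0 else ridge * 10.0
            if ridge > base * 1e-4:
                break
    raise KernelNumericsError(
        f"gene {gene_id}: similarity matrix not positive definite after ridge escalation"
    )


def phi_rbp(
    G: np.ndarray,
    w: np.ndarray,
    effect_vectors: np.ndarray,
    positions: np.ndarray,
    gamma: float = DEFAULT_GAMMA,
    variant_ids: list[str] | None = None,
    gene_id: str = "?",
) -> KernelFactor:
    """Directional RBP kernel factor phi = G_c diag(sqrt w) L, LL^T = S."""
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[1] == 0:
        raise EmptyGeneError("phi_rbp needs at least one variant")
    m = G.shape[1]
    w = _check_weights(w, m)
    labels = variant_ids or [f"v{j}" for j in range(m)]
    G_c = center_and_impute(G)
    keep = w > 0
    G_c = G_c[:, keep]
    w = w[keep]
    labels = [l for l, k in zip(labels, keep) if k]
    V = np.asarray(effect_vectors, dtype=float)[keep]
    x = np.asarray(positions, dtype=float)[keep]
    if G_c.shape[1] == 0:
        raise EmptyGeneError("all variants carry zero weight")
    S = rbp_similarity(V, x, gamma)
    L = _cholesky_with_ridge(S, gene_id)
    phi = (G_c * np.sqrt(w)[None, :]) @ L
    return KernelFactor(phi, labels, "rbp")


def concat_plof(phi: KernelFactor, plof_burden: np.ndarray) -> KernelFactor:
    """Append the centered pLOF burden as an extra kernel column.

    A burden with no carriers contributes nothing and is dropped;
    an empty phi with a nonzero burden yields the burden column alone.
    """
    b = np.asarray(plof_burden, dtype=float)
    if b.ndim != 1 or b.shape[0] != phi.n:
        raise ValueError("burden length must match phi's sample dimension")
    b_c = b - b.mean()
    if np.allclose(b_c, 0.0):
        out = KernelFactor(
            phi.matrix.copy(), list(phi.column_labels), phi.design, phi.centered
        )
        out.has_plof_column = False
        return out
    mat = np.column_stack([phi.matrix, b_c]) if phi.g else b_c[:, None]
    out = KernelFactor(mat, list(phi.column_labels) + ["pLOF"], phi.design)
    out.has_plof_column = True
    return out
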