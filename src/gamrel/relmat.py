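"""Dense relationship matrices: A, the gametic matrix G, K' and G-bar.

These are O(t^2)-memory reference constructions for small to moderate
pedigrees.  The generalized gametic relationship matrix

    G-bar = K' G K

is the covariance matrix of a mixed effect vector in which some
individuals appear through a single transmitting ability (the average
of their two gametic effects) and the rest through the gametic pair
itself.  Its two limiting cases are the coancestry matrix A/2 (all
transmitting abilities) and the classical gametic matrix G (all
gametic pairs).  For large pedigrees use :mod:`gamrel.ginverse`, which
builds the sparse inverse of G-bar directly.
"""

from __future__ import annotations

import numpy as np

from .pedigree import EffectIndex, Pedigree, Representation

__all__ = [
    "DENSE_SIZE_LIMIT",
    "numerator_matrix",
    "gametic_matrix",
    "build_K",
    "generalized_matrix",
    "write_matrix_tsv",
]

#: refuse dense construction above this pedigree size
DENSE_SIZE_LIMIT = 2000


def _check_size(ped: Pedigree, limit: int | None) -> None:
    limit = DENSE_SIZE_LIMIT if limit is None else limit
    if ped.t > limit:
        raise ValueError(
            f"dense construction refused for t={ped.t} > {limit}; "
            "use gamrel.ginverse for the sparse inverse"
        )


def numerator_matrix(ped: Pedigree, *, size_limit: int | None = None) -> np.ndarray:
    """Additive (numerator) relationship matrix A, t x t.

    Tabular recursion: A_ij = (A_i,sire(j) + A_i,dam(j)) / 2 for i < j,
    A_ii = 1 + F_i with F_i the parents' coancestry.
    """
    _check_size(ped, size_limit)
    t = ped.t
    A = np.zeros((t, t))
    for i in range(t):
        s, d = ped.parent_indices(i)
        F = 0.5 * A[s, d] if (s is not None and d is not None) else 0.0
        row = np.zeros(t)
        if s is not None:
            row += 0.5 * A[s]
        if d is not None:
            row += 0.5 * A[d]
        A[i, :i] = row[:i]
        A[:i, i] = row[:i]
        A[i, i] = 1.0 + F
    return A


def gametic_matrix(ped: Pedigree, *, size_limit: int | None = None) -> np.ndarray:
    """Classical gametic relationship matrix G, 2t x 2t.

    Slots are paired per individual in pedigree order (paternal then
    maternal).  A gamete inherited from a known parent p is, in
    expectation, the average of p's two gametes, so its covariance with
    any other slot is the average of the parent slots' covariances; its
    own variance is 1 and the covariance between an individual's two
    gametes equals its inbreeding coefficient (which the recursion
    produces automatically).  Founder gametes are mutually uncorrelated.
    """
    _check_size(ped, size_limit)
    t = ped.t
    n = 2 * t
    G = np.zeros((n, n))
    for i in range(t):
        s, d = ped.parent_indices(i)
        for k, parent in ((2 * i, s), (2 * i + 1, d)):
            if parent is None:
                G[k, k] = 1.0
                continue
            row = 0.5 * (G[2 * parent] + G[2 * parent + 1])
            G[k, :k] = row[:k]
            G[:k, k] = row[:k]
            G[k, k] = 1.0
    return G


def build_K(ped: Pedigree, *, size_limit: int | None = None) -> np.ndarray:
    """Transformation matrix K' (m x 2t) mapping gametes to effects.

    Each transmitting-ability row holds 1/2 at the individual's two
    gamete columns; each gametic row holds a single 1.  Rows follow the
    :class:`~gamrel.pedigree.EffectIndex` slot order, columns the
    gamete order of :func:`gametic_matrix`.
    """
    _check_size(ped, size_limit)
    eidx = EffectIndex(ped)
    K = np.zeros((eidx.m, 2 * ped.t))
    for slot in eidx.slots:
        i = ped.index[slot.individual]
        if slot.kind == "ta":
            K[slot.index, 2 * i] = 0.5
            K[slot.index, 2 * i + 1] = 0.5
        else:
            K[slot.index, 2 * i + (0 if slot.kind == "pat" else 1)] = 1.0
    return K


def generalized_matrix(ped: Pedigree, *, size_limit: int | None = None) -> np.ndarray:
    """Generalized gametic relationship matrix G-bar = K' G K (m x m)."""
    K = build_K(ped, size_limit=size_limit)
    G = gametic_matrix(ped, size_limit=size_limit)
    return K @ G @ K.T


def write_matrix_tsv(M: np.ndarray, labels, path, *, lower_only: bool = False) -> None:
    """Dump a labeled matrix as (row label, column label, value) TSV."""
    labels = list(labels)
    with open(path, "w") as fh:
        for i in range(M.shape[0]):
            jmax = i + 1 if lower_only else M.shape[1]
            for j in range(jmax):
                fh.write(f"{labels[i]}\t{labels[j]}\t{M[i, j]:.12g}\n")
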