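"""Direct sparse inversion of the generalized gametic relationship matrix.

The inverse factorizes as G-bar^-1 = (T')^-1 D^-1 T^-1 with T lower
triangular and D diagonal, so it accumulates one rank-1 contribution

    U_i = u_i u_i' * delta_i

per genetic effect.  The vector u_i carries 1 at the effect's own slot
and negative coefficients (-1/2 or -1/4) at the slots of the parent(s)
it derives from; delta_i is the inverse Mendelian-sampling variance of
the effect.  Which coefficients and which delta formula apply depends
only on the effect's :class:`~gamrel.pedigree.CaseLabel` — one of 12
configurations of (effect kind) x (parent representations).

Delta closed forms by case class (F = inbreeding coefficient):

==========================================  =======================
a-00 (transmitting ability, no parents)     2
a-0a, a-a0, a-0gg, a-gg0 (one known)        8 / (3 - F_known)
a-aa, a-agg, a-gga, a-gggg (both known)     8 / (2 - F_sire - F_dam)
g-a, g-gg (gamete, known parent)            2 / (1 - F_parent)
g-0 (founder gamete)                        1
==========================================  =======================

Each closed form equals 1 / (Gbar_ii - q' Gbar_prev q) with q the
negated parental coefficients: e.g. one known, non-inbred parent gives
a transmitting-ability sampling variance of 1/2 - 1/8 = 3/8, hence
delta = 8/3.  Note two of the rows are easy to mis-simplify: the
one-known-parent class is *not* 2/(1 - F) — the unknown parent leaves
an extra founder-gamete half in the sampling variance — and the
gametic class is 2/(1 - F), not 4/(1 - F).  The dense-inverse oracle
in the test suite pins all five forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .pedigree import (
    CaseLabel,
    EffectIndex,
    EffectSlot,
    Pedigree,
    classify_effect,
    inbreeding_coefficients,
)

__all__ = [
    "ContributionVector",
    "SparseSymmetricTriplets",
    "contribution_vector",
    "mendelian_delta",
    "build_inverse",
    "write_giv",
]

# Table of parental coefficient patterns per case; the final +1 for the
# effect's own slot is appended by contribution_vector.
_PARENT_COEFFS: dict[CaseLabel, tuple[float, ...]] = {
    CaseLabel.A_00: (),
    CaseLabel.A_0A: (-0.5,),
    CaseLabel.A_A0: (-0.5,),
    CaseLabel.A_0GG: (-0.25, -0.25),
    CaseLabel.A_GG0: (-0.25, -0.25),
    CaseLabel.A_AA: (-0.5, -0.5),
    CaseLabel.A_AGG: (-0.5, -0.25, -0.25),
    CaseLabel.A_GGA: (-0.25, -0.25, -0.5),
    CaseLabel.A_GGGG: (-0.25, -0.25, -0.25, -0.25),
    CaseLabel.G_0: (),
    CaseLabel.G_A: (-1.0,),
    CaseLabel.G_GG: (-0.5, -0.5),
}


@dataclass(frozen=True)
class ContributionVector:
    """Nonzeros of u_i: (slot index, coefficient) pairs, own slot last."""

    entries: tuple[tuple[int, float], ...]

    def __post_init__(self):
        if not (1 <= len(self.entries) <= 5):
            raise ValueError("contribution vector must have 1-5 nonzeros")


def contribution_vector(case: CaseLabel, own_slot: int, parent_slots) -> ContributionVector:
    """Nonzero pattern of u_i for one effect.

    ``parent_slots`` lists the slot indices of the parental effects the
    case refers to, ordered sire-side before dam-side (and paternal
    before maternal gamete within a gametic parent).
    """
    coeffs = _PARENT_COEFFS[case]
    parent_slots = tuple(parent_slots)
    if len(parent_slots) != len(coeffs):
        raise ValueError(
            f"case {case.value} needs {len(coeffs)} parent slot(s), got {len(parent_slots)}"
        )
    entries = tuple(zip(parent_slots, coeffs)) + ((own_slot, 1.0),)
    return ContributionVector(entries)


def mendelian_delta(case: CaseLabel, *, F_sire: float | None = None,
                    F_dam: float | None = None) -> float:
    """Inverse Mendelian-sampling variance delta for one effect.

    Supply F of the known parent(s) only: for one-known-parent
    transmitting-ability cases, pass it as whichever of ``F_sire`` /
    ``F_dam`` is known; for gametic cases pass the parent's F as
    ``F_sire``.
    """
    for F in (F_sire, F_dam):
        if F is not None and not (0.0 <= F < 1.0):
            raise ValueError(f"inbreeding coefficient {F} outside [0, 1)")
    if case is CaseLabel.A_00:
        return 2.0
    if case in (CaseLabel.A_0A, CaseLabel.A_A0, CaseLabel.A_0GG, CaseLabel.A_GG0):
        F = F_sire if F_sire is not None else F_dam
        return 8.0 / (3.0 - F)
    if case in (CaseLabel.A_AA, CaseLabel.A_AGG, CaseLabel.A_GGA, CaseLabel.A_GGGG):
        return 8.0 / (2.0 - F_sire - F_dam)
    if case in (CaseLabel.G_A, CaseLabel.G_GG):
        F = F_sire if F_sire is not None else F_dam
        return 2.0 / (1.0 - F)
    return 1.0  # g-0


class SparseSymmetricTriplets:
    """Lower-triangle triplet store for a symmetric m x m matrix."""

    def __init__(self, m: int, rows, cols, values, labels=None):
        rows = np.asarray(rows, dtype=np.int64)
        cols = np.asarray(cols, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        lo = np.minimum(rows, cols)
        hi = np.maximum(rows, cols)
        # sum duplicates, keep lower triangle, sort by (row, col)
        coo = sp.coo_matrix((values, (hi, lo)), shape=(m, m)).tocsr().tocoo()
        keep = coo.data != 0.0
        self.m = m
        self.rows = coo.row[keep]
        self.cols = coo.col[keep]
        self.values = coo.data[keep]
        self.labels = list(labels) if labels is not None else None

    @property
    def nnz_lower(self) -> int:
        return len(self.values)

    def to_csc(self) -> sp.csc_matrix:
        """Full symmetric matrix in CSC form."""
        off = self.rows != self.cols
        rows = np.concatenate([self.rows, self.cols[off]])
        cols = np.concatenate([self.cols, self.rows[off]])
        vals = np.concatenate([self.values, self.values[off]])
        return sp.csc_matrix((vals, (rows, cols)), shape=(self.m, self.m))

    def to_dense(self) -> np.ndarray:
        return self.to_csc().toarray()


def build_inverse(ped: Pedigree, *, F: dict | None = None) -> SparseSymmetricTriplets:
    """Direct construction of G-bar^-1 from the pedigree.

    Accumulates U_i = u_i u_i' delta_i for every effect slot; the order
    of accumulation is immaterial because each contribution only refers
    to slots that exist in the final layout.
    """
    eidx = EffectIndex(ped)
    if F is None:
        F = inbreeding_coefficients(ped)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for slot in eidx.slots:
        case = classify_effect(ped, slot)
        idxs, Fs, Fd = _parent_slots_and_F(ped, eidx, slot, F)
        u = contribution_vector(case, slot.index, idxs)
        delta = mendelian_delta(case, F_sire=Fs, F_dam=Fd)
        for a, ca in u.entries:
            for b, cb in u.entries:
                if a >= b:
                    rows.append(a)
                    cols.append(b)
                    vals.append(ca * cb * delta)
    return SparseSymmetricTriplets(eidx.m, rows, cols, vals, labels=eidx.labels())


def _parent_slots_and_F(ped: Pedigree, eidx: EffectIndex, slot: EffectSlot, F: dict):
    """Parent slot indices (sire side first) and known-parent F values."""
    i = ped.index[slot.individual]
    s, d = ped.parent_indices(i)
    if slot.kind == "ta":
        idxs: list[int] = []
        Fs = Fd = None
        if s is not None:
            idxs.extend(eidx.slots_of(ped.records[s].id))
            Fs = F[ped.records[s].id]
        if d is not None:
            idxs.extend(eidx.slots_of(ped.records[d].id))
            Fd = F[ped.records[d].id]
        return idxs, Fs, Fd
    parent = s if slot.kind == "pat" else d
    if parent is None:
        return [], None, None
    pid = ped.records[parent].id
    return list(eidx.slots_of(pid)), F[pid], None


def write_giv(triplets: SparseSymmetricTriplets, path, *, header: bool = True) -> None:
    """Write a GIV-style lower-triangle triplet file (1-based indices).

    Format: optional ``#`` header lines mapping slot index to
    (individual id, slot kind), then one ``row col value`` line per
    lower-triangle nonzero, sorted by row then column.
    """
    with open(path, "w") as fh:
        if header and triplets.labels is not None:
            for k, lab in enumerate(triplets.labels, start=1):
                fh.write(f"# {k} {lab}\n")
        for r, c, v in zip(triplets.rows, triplets.cols, triplets.values):
            fh.write(f"{r + 1} {c + 1} {v:.12g}\n")
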