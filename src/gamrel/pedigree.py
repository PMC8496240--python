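"""Pedigree handling for gametic and transmitting-ability effect models.

A pedigree is an ordered list of individuals, each with a sire, a dam
(``0`` = unknown) and a *representation* flag saying whether the
individual enters a mixed model through a single transmitting ability
(half its breeding value) or through a pair of gametic effects (one per
parentally derived gamete).  The representation choice is the lever that
makes the generalized gametic relationship matrix smaller than the
classical 2t x 2t gametic matrix while keeping per-gamete resolution
where it is needed (typically: phenotyped individuals).

This module owns pedigree I/O, validation and topological ordering,
inbreeding coefficients, the slot layout of the mixed-model effect
vector (``EffectIndex``) and the classification of every effect into one
of the 12 cases that drive the direct sparse inversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

UNKNOWN = 0  # reserved parent code, never a valid individual id

__all__ = [
    "UNKNOWN",
    "Representation",
    "CaseLabel",
    "PedigreeError",
    "PedigreeRecord",
    "Pedigree",
    "EffectSlot",
    "EffectIndex",
    "parse_pedigree",
    "write_pedigree",
    "inbreeding_coefficients",
    "classify_effect",
]


class PedigreeError(ValueError):
    """Invalid pedigree input (duplicate ids, cycles, bad codes ...)."""


class Representation(Enum):
    """How an individual is represented in the effect vector."""

    TRANSMITTING = 1  # single averaged gametic effect (transmitting ability)
    GAMETIC = 2       # two gametic effects (paternal, maternal)

    @classmethod
    def from_code(cls, code) -> "Representation":
        try:
            return cls(int(code))
        except (ValueError, KeyError):
            raise PedigreeError(f"unknown representation code {code!r}; expected 1 or 2")


class CaseLabel(Enum):
    """The 12 effect/parent configurations of the direct inversion.

    Prefix ``a`` marks a transmitting-ability effect, ``g`` a gametic
    effect.  The suffix encodes the representation of the parent(s):
    ``0`` unknown, ``a`` transmitting ability, ``gg`` gametic pair.  For
    a transmitting ability the sire's status comes first.
    """

    A_00 = "a-00"
    A_0A = "a-0a"
    A_A0 = "a-a0"
    A_0GG = "a-0gg"
    A_GG0 = "a-gg0"
    A_AA = "a-aa"
    A_AGG = "a-agg"
    A_GGA = "a-gga"
    A_GGGG = "a-gggg"
    G_0 = "g-0"
    G_A = "g-a"
    G_GG = "g-gg"


@dataclass(frozen=True)
class PedigreeRecord:
    id: object
    sire: object
    dam: object
    representation: Representation

    def __post_init__(self):
        if self.id == UNKNOWN:
            raise PedigreeError(f"individual id {UNKNOWN!r} is reserved for unknown parents")
        if self.id == self.sire or self.id == self.dam:
            raise PedigreeError(f"individual {self.id!r} is its own parent")


class Pedigree:
    """Validated, topologically sorted pedigree.

    Records are stored parent-before-child; ``input_order`` keeps the
    original file order for output labeling.
    """

    def __init__(self, records: Iterable[PedigreeRecord]):
        records = list(records)
        self._validate_unique(records)
        self.records: list[PedigreeRecord] = self._toposort(records)
        self.index: dict[object, int] = {r.id: i for i, r in enumerate(self.records)}
        self.input_order: list[object] = [r.id for r in records]

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _validate_unique(records: Sequence[PedigreeRecord]) -> None:
        seen = set()
        for r in records:
            if r.id in seen:
                raise PedigreeError(f"duplicate individual id {r.id!r}")
            seen.add(r.id)

    @staticmethod
    def _toposort(records: Sequence[PedigreeRecord]) -> list[PedigreeRecord]:
        # Depth = 1 + max(parent depths); stable sort by (depth, input
        # position) keeps parents before children and founders in input
        # order.  Iterative DFS with an in-progress mark detects cycles.
        by_id = {r.id: r for r in records}
        depth: dict[object, int] = {}
        state: dict[object, int] = {}  # 0 in progress, 1 done

        for root in records:
            stack = [(root.id, False)]
            while stack:
                ident, processed = stack.pop()
                rec = by_id[ident]
                parents = [p for p in (rec.sire, rec.dam) if p != UNKNOWN and p in by_id]
                if processed:
                    state[ident] = 1
                    depth[ident] = 1 + max((depth[p] for p in parents), default=-1)
                    continue
                st = state.get(ident)
                if st == 1:
                    continue
                if st == 0:
                    raise PedigreeError(f"pedigree cycle involving individual {ident!r}")
                state[ident] = 0
                stack.append((ident, True))
                for parent in dict.fromkeys(parents):
                    if state.get(parent) != 1:
                        stack.append((parent, False))
        pos = {r.id: i for i, r in enumerate(records)}
        return sorted(records, key=lambda r: (depth[r.id], pos[r.id]))

    # -- basic queries ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        """Same genealogy and representations, regardless of input order."""
        if not isinstance(other, Pedigree):
            return NotImplemented
        return set(self.records) == set(other.records)

    @property
    def t(self) -> int:
        """Pedigree size."""
        return len(self.records)

    @property
    def u(self) -> int:
        """Number of transmitting-ability individuals."""
        return sum(r.representation is Representation.TRANSMITTING for r in self.records)

    @property
    def v(self) -> int:
        """Number of gametic-pair individuals."""
        return self.t - self.u

    def record(self, ident) -> PedigreeRecord:
        return self.records[self.index[ident]]

    def parent_indices(self, i: int) -> tuple[int | None, int | None]:
        """(sire index, dam index) in sorted order; None where unknown."""
        r = self.records[i]
        s = self.index.get(r.sire) if r.sire != UNKNOWN else None
        d = self.index.get(r.dam) if r.dam != UNKNOWN else None
        return s, d


def parse_pedigree(source, *, auto_insert_parents: bool = True) -> Pedigree:
    """Read a pedigree from a 4-column table: id, sire, dam, code (1|2).

    ``source`` is a path, file object or string.  Fields are comma- or
    whitespace-separated; an optional header row is detected by a
    non-numeric representation column.  Unknown parents are coded 0.
    Parents that never appear as a row are auto-inserted as
    transmitting-ability founders (with a warning), or rejected when
    ``auto_insert_parents=False``.
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str):
        if "\n" not in source and source and Path(source).exists():
            text = Path(source).read_text()
        elif "\n" not in source and source and " " not in source and "," not in source:
            raise FileNotFoundError(source)
        else:
            text = source
    else:
        text = source.read()

    rows: list[list[str]] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = [f.strip() for f in line.split(",")] if "," in line else line.split()
        if len(fields) < 4:
            raise PedigreeError(f"line {lineno}: expected >=4 columns, got {len(fields)}")
        rows.append(fields[:4])

    if rows and not rows[0][3].strip().lstrip("+-").isdigit():
        rows = rows[1:]  # header row

    def conv(tok: str):
        tok = tok.strip()
        return int(tok) if tok.lstrip("+-").isdigit() else tok

    records = [
        PedigreeRecord(conv(i), conv(s), conv(d), Representation.from_code(c))
        for i, s, d, c in rows
    ]

    known = {r.id for r in records}
    dangling: list[object] = []
    for r in records:
        for p in (r.sire, r.dam):
            if p != UNKNOWN and p not in known:
                known.add(p)
                dangling.append(p)
    if dangling:
        if not auto_insert_parents:
            raise PedigreeError(f"parents never defined as records: {dangling!r}")
        warnings.warn(
            f"auto-inserting {len(dangling)} parent(s) without a pedigree row as "
            f"unknown-parent founders (transmitting ability): {dangling!r}",
            stacklevel=2,
        )
        records = [
            PedigreeRecord(p, UNKNOWN, UNKNOWN, Representation.TRANSMITTING) for p in dangling
        ] + records

    return Pedigree(records)


def write_pedigree(ped: Pedigree, path, *, sep: str = " ") -> None:
    """Round-trip writer: 4 columns, same dialect the parser reads."""
    with open(path, "w") as fh:
        for r in ped.records:
            fh.write(sep.join(str(x) for x in (r.id, r.sire, r.dam, r.representation.value)))
            fh.write("\n")


# ---------------------------------------------------------------------------
# Inbreeding
# ---------------------------------------------------------------------------

def inbreeding_coefficients(ped: Pedigree, *, method: str = "auto") -> dict:
    """Inbreeding coefficient F per individual.

    F equals the coancestry of the parents; individuals with an unknown
    parent get F = 0 (unknown parents are unrelated, non-inbred base
    founders).  ``method`` is ``"tabular"`` (builds the dense numerator
    matrix, quadratic memory), ``"meuwissen-luo"`` (ancestor-path
    algorithm, linear memory) or ``"auto"`` (tabular up to t=2000).
    """
    if method == "auto":
        method = "tabular" if ped.t <= 2000 else "meuwissen-luo"
    if method == "tabular":
        F = _inbreeding_tabular(ped)
    elif method == "meuwissen-luo":
        F = _inbreeding_meuwissen_luo(ped)
    else:
        raise ValueError(f"unknown inbreeding method {method!r}")
    return {r.id: F[i] for i, r in enumerate(ped.records)}


def _inbreeding_tabular(ped: Pedigree) -> np.ndarray:
    t = ped.t
    A = np.zeros((t, t))
    F = np.zeros(t)
    for i in range(t):
        s, d = ped.parent_indices(i)
        F[i] = 0.5 * A[s, d] if (s is not None and d is not None) else 0.0
        A[i, i] = 1.0 + F[i]
        row = np.zeros(t)
        if s is not None:
            row += 0.5 * A[s]
        if d is not None:
            row += 0.5 * A[d]
        A[i, :i] = row[:i]
        A[:i, i] = row[:i]
    return F


def _inbreeding_meuwissen_luo(ped: Pedigree) -> np.ndarray:
    # Ancestor-path algorithm: F_i + 1 = sum over ancestors j of
    # L_ij^2 * d_j, with L the Cholesky path coefficients and d_j the
    # Mendelian-sampling variance of j.
    t = ped.t
    F = np.zeros(t)
    sire = np.empty(t, dtype=np.int64)
    dam = np.empty(t, dtype=np.int64)
    for i in range(t):
        s, d = ped.parent_indices(i)
        sire[i] = -1 if s is None else s
        dam[i] = -1 if d is None else d

    dvec = np.zeros(t)
    L = np.zeros(t)
    for i in range(t):
        s, d = sire[i], dam[i]
        Fs = F[s] if s >= 0 else 0.0
        Fd = F[d] if d >= 0 else 0.0
        n_known = int(s >= 0) + int(d >= 0)
        dvec[i] = 0.5 - 0.25 * (Fs + Fd) if n_known == 2 else (
            0.75 - 0.25 * (Fs + Fd) if n_known == 1 else 1.0
        )
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        L[:] = 0.0
        L[i] = 1.0
        ai = 0.0
        for j in range(i, -1, -1):
            lj = L[j]
            if lj == 0.0:
                continue
            ai += lj * lj * dvec[j]
            if sire[j] >= 0:
                L[sire[j]] += 0.5 * lj
            if dam[j] >= 0:
                L[dam[j]] += 0.5 * lj
            L[j] = 0.0
        F[i] = ai - 1.0
    return F


# ---------------------------------------------------------------------------
# Effect slots and case classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSlot:
    """One entry of the generalized effect vector.

    ``kind`` is ``"ta"`` for a transmitting ability, ``"pat"`` /
    ``"mat"`` for the paternal / maternal gametic effect.
    """

    index: int
    individual: object
    kind: str  # "ta" | "pat" | "mat"


class EffectIndex:
    """Slot layout of the generalized effect vector a' = [a_u' g_v'].

    Slots follow pedigree (topological) order; a gametic individual's
    paternal slot immediately precedes its maternal slot.  Total slot
    count m = u + 2v.
    """

    def __init__(self, ped: Pedigree):
        self.ped = ped
        self.slots: list[EffectSlot] = []
        self._by_individual: dict[object, tuple[int, ...]] = {}
        for r in ped.records:
            if r.representation is Representation.TRANSMITTING:
                idx = (len(self.slots),)
                self.slots.append(EffectSlot(idx[0], r.id, "ta"))
            else:
                i0 = len(self.slots)
                self.slots.append(EffectSlot(i0, r.id, "pat"))
                self.slots.append(EffectSlot(i0 + 1, r.id, "mat"))
                idx = (i0, i0 + 1)
            self._by_individual[r.id] = idx

    @property
    def m(self) -> int:
        return len(self.slots)

    def slots_of(self, ident) -> tuple[int, ...]:
        """Slot indices of one individual: (ta,) or (pat, mat)."""
        return self._by_individual[ident]

    def labels(self) -> list[str]:
        return [f"{s.individual}:{s.kind}" for s in self.slots]


def _parent_status(ped: Pedigree, parent_idx: int | None) -> str:
    if parent_idx is None:
        return "0"
    rep = ped.records[parent_idx].representation
    return "a" if rep is Representation.TRANSMITTING else "gg"


def classify_effect(ped: Pedigree, slot: EffectSlot) -> CaseLabel:
    """Assign one of the 12 direct-inversion cases to an effect slot.

    A transmitting ability is classified by the representation of both
    parents (sire status first); a gametic effect only by the single
    parent it derives from (sire for the paternal slot, dam for the
    maternal one).
    """
    i = ped.index[slot.individual]
    s, d = ped.parent_indices(i)
    if slot.kind == "ta":
        return CaseLabel(f"a-{_parent_status(ped, s)}{_parent_status(ped, d)}")
    parent = s if slot.kind == "pat" else d
    return CaseLabel(f"g-{_parent_status(ped, parent)}")
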