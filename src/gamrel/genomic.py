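"""Genomic gametic relationship matrices from phased haplotypes.

With all individuals genotyped at p biallelic markers and phased into
2t haplotypes, stack the 0/1 allele indicators in a 2t x p matrix,
mean-center each column and form

    Gg = C C' / s,       s = sum_j p_j (1 - p_j),

the haplotype-level (gametic) analogue of the usual genomic
relationship matrix.  Individuals whose haplotypes cannot be assigned
a parental origin ("unordered") can still contribute through the
average of their two centered haplotype rows — exactly the
transmitting-ability collapse of the pedigree machinery — giving the
generalized matrix G-bar_g = K' Gg K, conformable with the
pedigree-derived G-bar.

Allele frequencies default to the column means of the current sample;
pass ``frequencies=`` for base-population frequencies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypeSet",
    "GenomicError",
    "load_haplotypes",
    "load_haplotypes_vcf",
    "write_haplotypes",
    "center_and_scale",
    "genomic_gametic_matrix",
    "generalized_genomic_matrix",
]


class GenomicError(ValueError):
    """Invalid haplotype input (unphased ordered individual, missing calls ...)."""


@dataclass
class HaplotypeSet:
    """2t x p matrix of 0/1 haplotype allele indicators.

    Rows come in pairs per individual (first = paternal for ordered
    individuals, arbitrary for unordered).  ``ordered[i]`` flags whether
    individual i's pair has known parental origin.
    """

    alleles: np.ndarray            # (2t, p) 0/1
    individuals: list              # length t
    ordered: np.ndarray            # (t,) bool
    markers: list = None           # length p marker ids
    frequencies: np.ndarray = None # (p,), column means unless supplied

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=float)
        if self.alleles.ndim != 2 or self.alleles.shape[0] % 2:
            raise GenomicError("allele matrix must be 2t x p with two rows per individual")
        if self.alleles.shape[0] != 2 * len(self.individuals):
            raise GenomicError("individual list does not match haplotype count")
        if not np.isin(self.alleles, (0.0, 1.0)).all():
            raise GenomicError("allele matrix entries must be 0 or 1")
        self.ordered = np.asarray(self.ordered, dtype=bool)
        if self.markers is None:
            self.markers = [f"m{j + 1}" for j in range(self.alleles.shape[1])]
        if self.frequencies is None:
            self.frequencies = self.alleles.mean(axis=0)
        else:
            self.frequencies = np.asarray(self.frequencies, dtype=float)

    @property
    def t(self) -> int:
        return len(self.individuals)

    @property
    def p(self) -> int:
        return self.alleles.shape[1]


def load_haplotypes(source) -> HaplotypeSet:
    """Read the haplotype TSV format.

    Header row: ``id  hap  flag  <marker ids...>``; then one row per
    haplotype: individual id, haplotype index (1 or 2), ordered flag
    (``O`` ordered / ``U`` unordered), allele calls (0/1).
    """
    from pathlib import Path

    text = Path(source).read_text() if "\n" not in str(source) else str(source)
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    markers = header[3:]
    ids, flags, rows = [], {}, []
    for ln in lines[1:]:
        f = ln.split("\t")
        ident, hap, flag = f[0], int(f[1]), f[2].upper()
        if hap == 1:
            ids.append(ident)
        elif ident != ids[-1]:
            raise GenomicError(f"haplotype rows of {ident!r} are not adjacent")
        flags[ident] = flag == "O"
        calls = f[3:]
        if len(calls) != len(markers):
            raise GenomicError(f"{ident!r} hap {hap}: {len(calls)} calls for {len(markers)} markers")
        try:
            rows.append([int(c) for c in calls])
        except ValueError:
            raise GenomicError(f"{ident!r} hap {hap}: non-0/1 allele call")
    if len(rows) != 2 * len(ids):
        raise GenomicError(f"odd haplotype count: {len(rows)} rows for {len(ids)} individuals")
    return HaplotypeSet(np.array(rows, dtype=float), ids,
                        np.array([flags[i] for i in ids]), markers)


def write_haplotypes(h: HaplotypeSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\thap\tflag\t" + "\t".join(map(str, h.markers)) + "\n")
        for i, ident in enumerate(h.individuals):
            flag = "O" if h.ordered[i] else "U"
            for hap in (0, 1):
                calls = "\t".join(str(int(a)) for a in h.alleles[2 * i + hap])
                fh.write(f"{ident}\t{hap + 1}\t{flag}\t{calls}\n")


def load_haplotypes_vcf(path, ordered_ids, *, drop_bad_markers: bool = False) -> HaplotypeSet:
    """Read phased biallelic genotypes from a VCF.

    ``ordered_ids`` is the set of individuals whose first written
    allele is paternal; their genotypes must be phased (``|``).
    Unphased genotypes are accepted, with arbitrary haplotype order,
    for all other individuals.  Multi-allelic sites and missing calls
    raise, or are dropped with a warning when ``drop_bad_markers``.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise GenomicError("reading VCF requires the cyvcf2 package") from exc

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ordered_ids = set(ordered_ids)
    cols, markers, dropped = [], [], 0
    for var in vcf:
        ok = len(var.ALT) == 1 and var.num_unknown == 0
        col = None
        if ok:
            gts = var.genotypes  # per sample: [a0, a1, phased]
            col = []
            for sample, (a0, a1, phased) in zip(samples, gts):
                if sample in ordered_ids and not phased and a0 != a1:
                    raise GenomicError(
                        f"unphased genotype for ordered individual {sample!r} at {var.ID or var.POS}"
                    )
                if a0 not in (0, 1) or a1 not in (0, 1):
                    ok = False
                    break
                col.extend((a0, a1))
        if not ok:
            if not drop_bad_markers:
                raise GenomicError(
                    f"unsupported marker at {var.CHROM}:{var.POS} (multi-allelic or missing calls)"
                )
            dropped += 1
            continue
        cols.append(col)
        markers.append(var.ID or f"{var.CHROM}:{var.POS}")
    if dropped:
        logger.warning("dropped %d unsupported marker(s)", dropped)
    alleles = np.array(cols, dtype=float).T  # (2t, p)
    ordered = np.array([s in ordered_ids for s in samples])
    return HaplotypeSet(alleles, samples, ordered, markers)


def center_and_scale(h: HaplotypeSet) -> tuple[np.ndarray, float]:
    """Column-centered allele matrix C and scaling s = sum p_j (1 - p_j)."""
    if h.p < 1:
        raise GenomicError("need at least one marker")
    pj = h.frequencies
    s = float(np.sum(pj * (1.0 - pj)))
    if s <= 0.0:
        raise GenomicError("all markers monomorphic: scaling factor s = 0")
    return h.alleles - pj, s


def genomic_gametic_matrix(h: HaplotypeSet) -> np.ndarray:
    """Haplotype-level genomic relationship matrix Gg = CC'/s (2t x 2t)."""
    C, s = center_and_scale(h)
    return (C @ C.T) / s


def _collapse_rows(h: HaplotypeSet, collapse: np.ndarray) -> np.ndarray:
    """Mixed row set: averaged pair for collapsed individuals, both rows else."""
    rows = []
    for i in range(h.t):
        if collapse[i]:
            rows.append(0.5 * (h.alleles[2 * i] + h.alleles[2 * i + 1]))
        else:
            rows.append(h.alleles[2 * i])
            rows.append(h.alleles[2 * i + 1])
    return np.array(rows)


def generalized_genomic_matrix(h: HaplotypeSet, *, collapse=None) -> np.ndarray:
    """Generalized genomic gametic matrix G-bar_g = K' Gg K (m x m).

    ``collapse`` selects the individuals represented by the average of
    their two haplotype rows (default: all unordered individuals).  An
    ordered individual may be collapsed (origin information is simply
    discarded, with a warning); an unordered one must be.
    """
    if collapse is None:
        collapse = ~h.ordered
    collapse = np.asarray(collapse, dtype=bool)
    if (~collapse & ~h.ordered).any():
        bad = [h.individuals[i] for i in np.flatnonzero(~collapse & ~h.ordered)]
        raise GenomicError(f"unordered individuals must be collapsed: {bad!r}")
    if (collapse & h.ordered).any():
        warnings.warn("collapsing ordered individuals: parental-origin information discarded",
                      stacklevel=2)
    pj = h.frequencies
    s = float(np.sum(pj * (1.0 - pj)))
    if s <= 0.0:
        raise GenomicError("all markers monomorphic: scaling factor s = 0")
    M = _collapse_rows(h, collapse) - pj
    return (M @ M.T) / s
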