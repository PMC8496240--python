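"""Synthetic pedigrees, gametic effects and phenotypes for imprinting models.

The generator emulates the structure typical of parent-of-origin data
sets: a closed multi-generation population in which the last-generation
("final") progeny carry the records while most parents are
unphenotyped.  Phenotyped individuals are represented by gametic pairs
and everyone else by a transmitting ability, unless overridden.

Genetic effects are produced by gene dropping.  Every gamete carries a
*pair* of effects — its effect under a paternal expression pattern
("as sire") and under a maternal one ("as dam") — drawn jointly so that
founder gametes have covariance Sigma = [[sigma_s2, sigma_sd],
[sigma_sd, sigma_d2]] and a transmitted gamete is the parental gamete
average plus a Mendelian-sampling draw with covariance
(1 - F_parent) Sigma / 2.  The phenotype of individual i is

    y_i = fixed part + g_i,pat(as sire) + g_i,mat(as dam)
          + litter effect + residual,

so the population covariance of the stacked effect vectors is
Sigma (x) G with G the classical gametic relationship matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree, PedigreeRecord, Representation, UNKNOWN

__all__ = [
    "SimulationConfig",
    "simulate_pedigree",
    "gene_drop",
    "simulate_phenotypes",
    "simulate_haplotypes",
    "simulate_dataset",
]


@dataclass
class SimulationConfig:
    n_founders: int = 40
    n_generations: int = 5
    n_matings: int = 20            # matings per generation
    litter_mean: float = 4.0       # Poisson mean, floored at 1
    mating: str = "random"         # "random" | "sib-avoidance"
    phenotyped_fraction: float = 1.0  # fraction of final-generation progeny
    gametic_if_phenotyped: bool = True
    sigma_s2: float = 1.0
    sigma_d2: float = 1.0
    sigma_sd: float = 0.5
    sigma_e2: float = 1.0
    sigma_c2: float = 0.0          # litter variance
    mu: float = 10.0
    generation_effects: bool = True  # generation enters as a fixed factor
    seed: int = 0

    def __post_init__(self):
        if min(self.n_founders, self.n_generations + 1, self.n_matings) <= 0:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.phenotyped_fraction <= 1.0):
            raise ValueError("phenotyped_fraction must lie in [0, 1]")
        sig = self.Sigma
        if np.any(np.linalg.eigvalsh(sig) < -1e-12):
            raise ValueError("gametic covariance matrix must be PSD")

    @property
    def Sigma(self) -> np.ndarray:
        return np.array([[self.sigma_s2, self.sigma_sd],
                         [self.sigma_sd, self.sigma_d2]])

    def rng(self, stage: str) -> np.random.Generator:
        """Independent sub-stream per simulation stage."""
        import zlib

        stage_key = zlib.crc32(stage.encode()) % 2**31
        return np.random.default_rng(np.random.SeedSequence((self.seed, stage_key)))


def simulate_pedigree(cfg: SimulationConfig) -> tuple[Pedigree, pd.DataFrame]:
    """Generate a closed random-mating pedigree.

    Returns the pedigree and a metadata frame (id, generation, sex,
    litter, phenotyped).  Representation: gametic pair for phenotyped
    individuals, transmitting ability otherwise (per
    ``gametic_if_phenotyped``).
    """
    rng = cfg.rng("pedigree")
    rows = []  # (id, sire, dam, gen, sex, litter)
    next_id = 1
    males, females = [], []
    parents_of = {}
    for _ in range(cfg.n_founders):
        sex = "M" if rng.random() < 0.5 else "F"
        rows.append((next_id, UNKNOWN, UNKNOWN, 0, sex, 0))
        (males if sex == "M" else females).append(next_id)
        next_id += 1
    if not males or not females:  # force at least one of each
        ident, s, d, g, _, lit = rows[0]
        rows[0] = (ident, s, d, g, "M" if not males else "F", lit)
        males, females = [r[0] for r in rows if r[4] == "M"], [r[0] for r in rows if r[4] == "F"]

    litter = 0
    for gen in range(1, cfg.n_generations + 1):
        new_m, new_f = [], []
        for _ in range(cfg.n_matings):
            for _try in range(100):
                sire = males[rng.integers(len(males))]
                dam = females[rng.integers(len(females))]
                if cfg.mating != "sib-avoidance" or parents_of.get(sire) != parents_of.get(dam) \
                        or parents_of.get(sire) is None:
                    break
            else:
                raise ValueError("infeasible mating constraints (sib-avoidance)")
            litter += 1
            size = max(1, int(rng.poisson(cfg.litter_mean)))
            for _ in range(size):
                sex = "M" if rng.random() < 0.5 else "F"
                rows.append((next_id, sire, dam, gen, sex, litter))
                parents_of[next_id] = (sire, dam)
                (new_m if sex == "M" else new_f).append(next_id)
                next_id += 1
        males = new_m if new_m else males
        females = new_f if new_f else females

    meta = pd.DataFrame(rows, columns=["id", "sire", "dam", "generation", "sex", "litter"])
    # records come from final progeny: non-founders that never reproduce
    parents = set(meta["sire"]) | set(meta["dam"])
    final = (meta["generation"] > 0) & ~meta["id"].isin(parents)
    meta["phenotyped"] = final & (rng.random(len(meta)) < cfg.phenotyped_fraction)

    records = []
    for row in meta.itertuples(index=False):
        gametic = row.phenotyped if cfg.gametic_if_phenotyped else False
        rep = Representation.GAMETIC if gametic else Representation.TRANSMITTING
        records.append(PedigreeRecord(int(row.id), int(row.sire), int(row.dam), rep))
    return Pedigree(records), meta


def gene_drop(ped: Pedigree, Sigma, rng, *, F: dict | None = None) -> pd.DataFrame:
    """Drop bivariate gametic effects through the pedigree.

    Returns one row per gamete: individual id, origin (pat/mat),
    effect_s, effect_d, and the Mendelian-sampling part of each.
    """
    from .pedigree import inbreeding_coefficients

    Sigma = np.asarray(Sigma, dtype=float)
    if np.any(np.linalg.eigvalsh(Sigma) < -1e-12):
        raise ValueError("Sigma must be PSD")
    if F is None:
        F = inbreeding_coefficients(ped)
    chol = np.linalg.cholesky(Sigma + 1e-14 * np.eye(2))
    eff = {}  # id -> (2, 2) array: rows pat/mat, cols (s, d)
    out = []
    for i, rec in enumerate(ped.records):
        s, d = ped.parent_indices(i)
        g = np.empty((2, 2))
        for k, parent in ((0, s), (1, d)):
            z = chol @ rng.standard_normal(2)
            if parent is None:
                ms = z
                g[k] = ms
            else:
                pid = ped.records[parent].id
                ms = np.sqrt(0.5 * (1.0 - F[pid])) * z
                g[k] = 0.5 * (eff[pid][0] + eff[pid][1]) + ms
            out.append((rec.id, "pat" if k == 0 else "mat", g[k, 0], g[k, 1], ms[0], ms[1]))
        eff[rec.id] = g
    return pd.DataFrame(out, columns=["id", "origin", "effect_s", "effect_d", "ms_s", "ms_d"])


def simulate_phenotypes(ped: Pedigree, effects: pd.DataFrame, cfg: SimulationConfig,
                        meta: pd.DataFrame) -> pd.DataFrame:
    """Phenotypes for all individuals flagged in ``meta.phenotyped``.

    y = mu + generation effect + paternal-gamete effect as sire +
    maternal-gamete effect as dam + litter effect + residual.
    """
    rng = cfg.rng("phenotypes")
    es = effects.set_index(["id", "origin"])
    gen_eff = {}
    if cfg.generation_effects:
        gens = sorted(meta["generation"].unique())
        gen_eff = {g: rng.normal(0.0, 1.0) if g != gens[0] else 0.0 for g in gens}
    lit_eff = {}
    recs = []
    for row in meta[meta["phenotyped"]].itertuples(index=False):
        g = row.generation
        if row.litter not in lit_eff:
            lit_eff[row.litter] = (rng.normal(0.0, np.sqrt(cfg.sigma_c2))
                                   if cfg.sigma_c2 > 0 else 0.0)
        y = (cfg.mu + gen_eff.get(g, 0.0)
             + es.loc[(row.id, "pat"), "effect_s"]
             + es.loc[(row.id, "mat"), "effect_d"]
             + lit_eff[row.litter]
             + rng.normal(0.0, np.sqrt(cfg.sigma_e2)))
        recs.append((row.id, float(y), g, row.litter))
    return pd.DataFrame(recs, columns=["id", "y", "generation", "litter"])


def simulate_haplotypes(ped: Pedigree, n_markers: int, rng, *, maf_low: float = 0.05,
                        maf_high: float = 0.5):
    """Gene-drop 0/1 marker haplotypes through the pedigree.

    Founder haplotypes are drawn per marker at frequencies uniform in
    [maf_low, maf_high]; a transmitted haplotype picks each marker
    allele from one of the parent's two haplotypes independently
    (recombination-free per-marker transmission).  Founders are flagged
    unordered, non-founders ordered.  Returns a
    :class:`~gamrel.genomic.HaplotypeSet`.
    """
    from .genomic import HaplotypeSet

    freq = rng.uniform(maf_low, maf_high, size=n_markers)
    haps = {}
    rows = []
    ordered = []
    for i, rec in enumerate(ped.records):
        s, d = ped.parent_indices(i)
        pair = np.empty((2, n_markers))
        for k, parent in ((0, s), (1, d)):
            if parent is None:
                pair[k] = (rng.random(n_markers) < freq).astype(float)
            else:
                ph = haps[ped.records[parent].id]
                pick = rng.integers(2, size=n_markers)
                pair[k] = ph[pick, np.arange(n_markers)]
        haps[rec.id] = pair
        rows.extend((pair[0], pair[1]))
        ordered.append(s is not None or d is not None)
    # base-population frequencies are known here; supplying them avoids the
    # small negative bias that sample-frequency centering puts on the mean
    # off-diagonal relationship
    return HaplotypeSet(np.array(rows), [r.id for r in ped.records], np.array(ordered),
                        frequencies=freq)


def simulate_dataset(cfg: SimulationConfig):
    """Pedigree + effects + phenotypes in one call (shared config seed)."""
    ped, meta = simulate_pedigree(cfg)
    effects = gene_drop(ped, cfg.Sigma, cfg.rng("effects"))
    pheno = simulate_phenotypes(ped, effects, cfg, meta)
    return ped, meta, effects, pheno
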