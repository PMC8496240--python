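"""Parent-of-origin mixed models: BLUP, REML and the imprinting test.

The general model is

    y = X beta + Zs as + Zd ad (+ Zc c) + eps,

where ``as`` / ``ad`` hold each individual's genetic effects under a
paternal / maternal expression pattern (gametic effects or
transmitting abilities, per the pedigree's representation flags), with

    Var[as; ad] = [[s2_s, s_sd], [s_sd, s2_d]] (x) G-bar,

an optional i.i.d. group (litter) effect c with variance s2_c, and
heteroskedastic residuals.  Observations enter through one of two row
types:

* gametic rows (individuals represented by a gametic pair): coefficient
  1 on the own paternal slot in ``as`` and the own maternal slot in
  ``ad``; residual variance s2_e (weight 1);
* reduced rows (final progeny): the phenotype is regressed on the
  parents' effects — 1 on a parent's transmitting-ability slot or
  (1/2, 1/2) on its gametic pair — and the parents' Mendelian-sampling
  contributions fold into the residual.  The residual variance is
  s2_e / w_i with the precision weight

      w_i = s2_e / (0.5 (1 - F_sire) s2_s + 0.5 (1 - F_dam) s2_d + s2_e).

Residual convention: the weights are defined as the inverse variance
ratios above, Var(eps_i) = s2_e / w_i, and diag(w_i) is the precision
multiplier in the mixed-model equations.

Variance components are estimated by REML: a derivative-free simplex
search on (log s2_s, log s2_d, atanh r, log s2_e[, log s2_c]), wrapped
in an outer loop that recomputes the reduced-row weights from the
current estimates until the restricted log-likelihood stabilizes.  The
Mendelian null (no imprinting) constrains s2_s = s2_d = s_sd — a
single additive gametic variance — and the imprinting-vs-Mendelian
comparison is an approximate restricted likelihood-ratio test against
a chi-square with (by default) 2 degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.sparse.linalg import splu
from scipy.stats import chi2

from .ginverse import SparseSymmetricTriplets, build_inverse
from .pedigree import EffectIndex, Pedigree, Representation, inbreeding_coefficients

logger = logging.getLogger(__name__)

__all__ = [
    "ModelError",
    "VarianceComponents",
    "ObservationEquation",
    "Design",
    "MMESystem",
    "REMLResult",
    "residual_weight",
    "build_design",
    "assemble_and_solve",
    "reml_loglik",
    "fit_reml",
    "rlrt",
    "derived_parameters",
    "hessian_standard_errors",
]


class ModelError(ValueError):
    """Invalid model specification or data."""


# ---------------------------------------------------------------------------
# Variance components
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VarianceComponents:
    sigma_s2: float
    sigma_d2: float
    sigma_sd: float
    sigma_e2: float
    sigma_c2: float | None = None

    def __post_init__(self):
        if min(self.sigma_s2, self.sigma_d2, self.sigma_e2) <= 0:
            raise ModelError("sigma_s2, sigma_d2 and sigma_e2 must be positive")
        if self.sigma_sd ** 2 > self.sigma_s2 * self.sigma_d2 * (1 + 1e-12):
            raise ModelError("gametic covariance matrix is not PSD")
        if self.sigma_c2 is not None and self.sigma_c2 <= 0:
            raise ModelError("sigma_c2 must be positive (or None)")

    @property
    def Sigma(self) -> np.ndarray:
        return np.array([[self.sigma_s2, self.sigma_sd],
                         [self.sigma_sd, self.sigma_d2]])

    @property
    def sigma_i2(self) -> float:
        """Imprinting variance: var of (effect as sire - effect as dam)."""
        return self.sigma_s2 + self.sigma_d2 - 2.0 * self.sigma_sd

    @property
    def r(self) -> float:
        """Correlation between the two expression patterns."""
        return self.sigma_sd / np.sqrt(self.sigma_s2 * self.sigma_d2)

    def alpha(self) -> tuple[float, float, float]:
        """(a1, a2, a3) with [[a1,a2],[a2,a3]] = s2_e * Sigma^-1."""
        det = self.sigma_s2 * self.sigma_d2 - self.sigma_sd ** 2
        if det <= 0:
            raise ModelError("gametic covariance matrix is singular")
        f = self.sigma_e2 / det
        return f * self.sigma_d2, -f * self.sigma_sd, f * self.sigma_s2


def residual_weight(kind: str, F_sire: float, F_dam: float, vc: VarianceComponents) -> float:
    """Residual precision weight w_i of one observation equation."""
    if kind == "gametic":
        return 1.0
    num = 0.5 * (1.0 - F_sire) * vc.sigma_s2 + 0.5 * (1.0 - F_dam) * vc.sigma_d2 + vc.sigma_e2
    return vc.sigma_e2 / num


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObservationEquation:
    row: int
    id: object
    kind: str             # "gametic" | "reduced" | "mixed-sire-ta" | "mixed-dam-ta"
    F_sire: float | None  # None for gametic rows
    F_dam: float | None

    def weight(self, vc: VarianceComponents) -> float:
        if self.kind == "gametic":
            return 1.0
        return residual_weight("reduced", self.F_sire, self.F_dam, vc)


@dataclass
class Design:
    """Assembled model matrices plus the (possibly pruned) pedigree."""

    ped: Pedigree
    eidx: EffectIndex
    F: dict
    X: np.ndarray
    Zs: sp.csr_matrix
    Zd: sp.csr_matrix
    Zc: sp.csr_matrix | None
    y: np.ndarray
    equations: list[ObservationEquation]
    x_labels: list[str]
    group_labels: list | None = None
    n_pruned: int = 0

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def has_reduced(self) -> bool:
        return any(e.kind != "gametic" for e in self.equations)

    def weights(self, vc: VarianceComponents | None) -> np.ndarray:
        """Per-row precision weights; vc=None means equal weights (all 1)."""
        if vc is None:
            return np.ones(self.n)
        w = np.array([e.weight(vc) for e in self.equations])
        if np.any(w <= 0):
            raise ModelError("non-positive residual weight")
        return w


def _fixed_design(phen: pd.DataFrame, factors, covariates):
    """Intercept + treatment-coded factors (first level = reference) + covariates."""
    n = len(phen)
    cols = [np.ones(n)]
    labels = ["intercept"]
    for f in factors:
        for lev in pd.unique(phen[f])[1:]:
            cols.append((phen[f] == lev).to_numpy(dtype=float))
            labels.append(f"{f}[{lev}]")
    for c in covariates:
        cols.append(phen[c].to_numpy(dtype=float))
        labels.append(c)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        aliased, kept = [], []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, kept + [j]]) == len(kept) + 1:
                kept.append(j)
            else:
                aliased.append(labels[j])
        raise ModelError(f"fixed-effect design is rank deficient; aliased columns: {aliased}")
    return X, labels


def _reduced_coeff(slots):
    return [(slots[0], 1.0)] if len(slots) == 1 else [(slots[0], 0.5), (slots[1], 0.5)]


def build_design(ped: Pedigree, phenotypes: pd.DataFrame, *, response: str = "y",
                 factors=(), covariates=(), group: str | None = None,
                 equations: str = "auto", F: dict | None = None) -> Design:
    """Turn a pedigree plus phenotype table into model matrices.

    ``equations`` selects the observation-row policy:

    * ``"auto"``: gametic rows for individuals represented by a gametic
      pair, reduced rows for the rest;
    * ``"gametic"``: force gametic rows (every phenotyped individual
      must carry a gametic-pair representation);
    * ``"reduced"``: reduced rows for all phenotyped final progeny
      (individuals without offspring), which are then pruned from the
      effect set; remaining phenotyped individuals get gametic rows.
    """
    if equations not in ("auto", "gametic", "reduced"):
        raise ModelError(f"unknown equation policy {equations!r}")
    if len(phenotypes) == 0:
        raise ModelError("no records: empty phenotype table")
    phen = phenotypes.reset_index(drop=True)
    ids = list(phen["id"])
    missing = [i for i in ids if i not in ped.index]
    if missing:
        raise ModelError(f"phenotyped individuals not in pedigree: {missing[:5]!r}")

    # parent links survive pruning
    links = {r.id: (r.sire, r.dam) for r in ped.records}

    n_pruned = 0
    if equations == "reduced":
        has_offspring = set()
        for r in ped.records:
            has_offspring.update((r.sire, r.dam))
        final = {i for i in ids if i not in has_offspring}
        keep = [r for r in ped.records if r.id not in final]
        n_pruned = ped.t - len(keep)
        if n_pruned:
            logger.info("pruned %d phenotyped final progeny from the effect set", n_pruned)
            ped = Pedigree(keep)

    if F is None:
        F = inbreeding_coefficients(ped)
    eidx = EffectIndex(ped)

    rows_s, rows_d = [], []
    eqs: list[ObservationEquation] = []
    for row, ident in enumerate(ids):
        in_ped = ident in ped.index
        gametic_row = in_ped and ped.record(ident).representation is Representation.GAMETIC
        if equations == "gametic" and not gametic_row:
            raise ModelError(
                f"equations='gametic' but individual {ident!r} has no gametic-pair representation"
            )
        if gametic_row:
            pat, mat = eidx.slots_of(ident)
            rows_s.append([(pat, 1.0)])
            rows_d.append([(mat, 1.0)])
            eqs.append(ObservationEquation(row, ident, "gametic", None, None))
            continue
        sire, dam = links[ident]
        if sire not in ped.index or dam not in ped.index:
            raise ModelError(f"cannot form a reduced equation for {ident!r}: unknown parent")
        ss, ds = eidx.slots_of(sire), eidx.slots_of(dam)
        rows_s.append(_reduced_coeff(ss))
        rows_d.append(_reduced_coeff(ds))
        kind = ("reduced" if len(ss) == 1 and len(ds) == 1 else
                "mixed-sire-ta" if len(ss) == 1 else
                "mixed-dam-ta" if len(ds) == 1 else "reduced")
        eqs.append(ObservationEquation(row, ident, kind, F[sire], F[dam]))

    n, m = len(ids), eidx.m

    def to_csr(rows):
        data, ri, ci = [], [], []
        for i, ents in enumerate(rows):
            for j, val in ents:
                ri.append(i)
                ci.append(j)
                data.append(val)
        return sp.csr_matrix((data, (ri, ci)), shape=(n, m))

    X, labels = _fixed_design(phen, factors, covariates)
    Zc = None
    group_labels = None
    if group is not None:
        group_labels = list(pd.unique(phen[group]))
        gi = {g: k for k, g in enumerate(group_labels)}
        Zc = sp.csr_matrix((np.ones(n), (np.arange(n), [gi[g] for g in phen[group]])),
                           shape=(n, len(group_labels)))
    y = phen[response].to_numpy(dtype=float)
    return Design(ped, eidx, F, X, to_csr(rows_s), to_csr(rows_d), Zc, y,
                  eqs, labels, group_labels, n_pruned)


# ---------------------------------------------------------------------------
# Mixed-model equations and restricted likelihood
# ---------------------------------------------------------------------------

@dataclass
class MMESystem:
    """Solved mixed-model equations at a fixed set of variance components."""

    beta: np.ndarray
    a_s: np.ndarray
    a_d: np.ndarray
    c: np.ndarray | None
    logL: float
    vc: VarianceComponents
    x_labels: list[str]
    design: Design

    def solutions(self) -> pd.DataFrame:
        """Per-individual predictions.

        ``ahat_s`` / ``ahat_d`` are transmitting abilities as sire /
        dam (gametic pairs averaged); ``imprinting_deviation`` is their
        difference.
        """
        eidx = self.design.eidx
        recs = []
        for rec in self.design.ped.records:
            slots = list(eidx.slots_of(rec.id))
            ts = float(np.mean(self.a_s[slots]))
            td = float(np.mean(self.a_d[slots]))
            kind = "ta" if len(slots) == 1 else "gametic-pair"
            recs.append((rec.id, kind, ts, td, ts - td))
        return pd.DataFrame(recs, columns=["id", "kind", "ahat_s", "ahat_d",
                                           "imprinting_deviation"])


def _sym_splu(M: sp.csc_matrix):
    return splu(M, permc_spec="MMD_AT_PLUS_A", diag_pivot_thresh=0.0,
                options={"SymmetricMode": True})


class _Workspace:
    """Caches everything reusable across likelihood evaluations."""

    def __init__(self, design: Design, ginv: SparseSymmetricTriplets):
        if ginv.m != design.eidx.m:
            raise ModelError(
                f"G-bar inverse dimension {ginv.m} does not match effect count {design.eidx.m}"
            )
        self.design = design
        self.Ginv = ginv.to_csc()
        lu = _sym_splu(self.Ginv)
        self.logdet_Gbar = -float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        X = sp.csr_matrix(design.X)
        tail = [design.Zc] if design.Zc is not None else []
        self.T = {
            "imprinting": sp.hstack([X, design.Zs, design.Zd] + tail, format="csr"),
            "mendelian": sp.hstack([X, design.Zs + design.Zd] + tail, format="csr"),
        }
        self.p = design.X.shape[1]
        self.m = design.eidx.m
        self.q = design.Zc.shape[1] if design.Zc is not None else 0
        self._w = np.ones(design.n)
        self._cross: dict[str, tuple] = {}

    def use_weights(self, vc_for_w: VarianceComponents | None) -> None:
        w = self.design.weights(vc_for_w)
        if not np.array_equal(w, self._w) or not self._cross:
            self._w = w
            self._cross = {}

    def _products(self, model: str):
        if model not in self._cross:
            T = self.T[model]
            w = self._w
            TtWT = (T.T @ sp.diags(w) @ T).tocsc()
            TtWy = T.T @ (w * self.design.y)
            self._cross[model] = (TtWT, TtWy)
        return self._cross[model]

    def _penalty(self, vc: VarianceComponents, model: str) -> sp.csc_matrix:
        if model == "imprinting":
            a1, a2, a3 = vc.alpha()
            pen = sp.bmat([[a1 * self.Ginv, a2 * self.Ginv],
                           [a2 * self.Ginv, a3 * self.Ginv]], format="csc")
        else:
            pen = (vc.sigma_e2 / vc.sigma_s2) * self.Ginv
        blocks = [sp.csc_matrix((self.p, self.p)), pen]
        if self.q:
            blocks.append((vc.sigma_e2 / vc.sigma_c2) * sp.eye(self.q, format="csc"))
        return sp.block_diag(blocks, format="csc")

    def solve(self, vc: VarianceComponents, model: str = "imprinting"):
        """(theta_hat, restricted logL) at vc with the current weights."""
        design = self.design
        TtWT, TtWy = self._products(model)
        M = (TtWT + self._penalty(vc, model)).tocsc()
        lu = _sym_splu(M)
        theta = lu.solve(TtWy)
        logdet_M = float(np.sum(np.log(np.abs(lu.U.diagonal()))))

        n, m, q = design.n, self.m, self.q
        se2 = vc.sigma_e2
        w = self._w
        log_R = n * np.log(se2) - float(np.sum(np.log(w)))
        if model == "imprinting":
            log_G = m * np.log(vc.sigma_s2 * vc.sigma_d2 - vc.sigma_sd ** 2) \
                + 2 * self.logdet_Gbar
        else:
            log_G = m * np.log(vc.sigma_s2) + self.logdet_Gbar
        if q:
            log_G += q * np.log(vc.sigma_c2)
        log_C = logdet_M - M.shape[0] * np.log(se2)
        yWy = float(np.dot(design.y, w * design.y))
        yPy = (yWy - float(np.dot(theta, TtWy))) / se2
        nstar = n - self.p
        logL = -0.5 * (nstar * np.log(2 * np.pi) + log_R + log_G + log_C + yPy)
        return theta, float(logL)


def assemble_and_solve(design: Design, ginv: SparseSymmetricTriplets,
                       vc: VarianceComponents, *, model: str = "imprinting",
                       weights_from="vc") -> MMESystem:
    """Solve the mixed-model equations (BLUE/BLUP) at fixed components.

    ``weights_from`` controls the residual weights of reduced rows: the
    default uses ``vc`` itself; pass another
    :class:`VarianceComponents` to freeze weights elsewhere, or ``None``
    for equal weights.
    """
    ws = _Workspace(design, ginv)
    ws.use_weights(vc if isinstance(weights_from, str) else weights_from)
    theta, logL = ws.solve(vc, model)
    p, m, q = ws.p, ws.m, ws.q
    beta = theta[:p]
    if model == "imprinting":
        a_s, a_d = theta[p:p + m], theta[p + m:p + 2 * m]
        c = theta[p + 2 * m:] if q else None
    else:
        a_s = a_d = theta[p:p + m]
        c = theta[p + m:] if q else None
    return MMESystem(beta, a_s, a_d, c, logL, vc, design.x_labels, design)


def reml_loglik(design: Design, ginv: SparseSymmetricTriplets, vc: VarianceComponents,
                *, model: str = "imprinting", weights_from="vc") -> float:
    """Restricted log-likelihood at ``vc`` (weights from ``weights_from``)."""
    ws = _Workspace(design, ginv)
    ws.use_weights(vc if isinstance(weights_from, str) else weights_from)
    return ws.solve(vc, model)[1]


# ---------------------------------------------------------------------------
# REML fitting
# ---------------------------------------------------------------------------

@dataclass
class REMLResult:
    vc: VarianceComponents
    logL: float
    converged: bool
    n_outer: int
    n_eval: int
    trace: list = field(default_factory=list)
    model: str = "imprinting"


def _pack(vc: VarianceComponents, model: str, with_c: bool) -> np.ndarray:
    if model == "imprinting":
        x = [np.log(vc.sigma_s2), np.log(vc.sigma_d2),
             np.arctanh(np.clip(vc.r, -0.999999, 0.999999)), np.log(vc.sigma_e2)]
    else:
        x = [np.log(vc.sigma_s2), np.log(vc.sigma_e2)]
    if with_c:
        x.append(np.log(vc.sigma_c2))
    return np.array(x)


def _unpack(x: np.ndarray, model: str, with_c: bool) -> VarianceComponents:
    c2 = float(np.exp(x[-1])) if with_c else None
    if model == "imprinting":
        s2, d2 = np.exp(x[0]), np.exp(x[1])
        r = np.tanh(x[2])
        return VarianceComponents(float(s2), float(d2), float(r * np.sqrt(s2 * d2)),
                                  float(np.exp(x[3])), c2)
    a2 = float(np.exp(x[0]))
    return VarianceComponents(a2, a2, a2, float(np.exp(x[1])), c2)


def fit_reml(design: Design, ginv: SparseSymmetricTriplets | None = None, *,
             model: str = "imprinting", start: VarianceComponents | None = None,
             tol_inner: float = 1e-8, tol_outer: float = 1e-6,
             max_outer: int = 50, max_inner_iter: int = 4000) -> REMLResult:
    """Maximize the restricted likelihood over the variance components.

    With reduced observation rows present, the residual weights depend
    on the unknown components: the fit starts from equal weights,
    maximizes, recomputes the weights from the estimates, and repeats
    until the restricted log-likelihood changes by less than
    ``tol_outer``.  A non-converged search returns the best point found
    with ``converged=False`` and a warning.
    """
    if model not in ("imprinting", "mendelian"):
        raise ModelError(f"unknown model {model!r}")
    if ginv is None:
        ginv = build_inverse(design.ped, F=design.F)
    ws = _Workspace(design, ginv)
    with_c = design.Zc is not None

    vy = float(np.var(design.y))
    if start is None:
        c2 = 0.1 * vy if with_c else None
        rem = 0.9 * vy if with_c else vy
        start = VarianceComponents(0.25 * rem, 0.25 * rem, 0.05 * rem, 0.5 * rem, c2)

    n_eval = 0

    def objective(x):
        nonlocal n_eval
        n_eval += 1
        # keep the search inside a numerically safe region: variances
        # within e^+-30 and |r| < tanh(8) ~ 1 - 2e-7
        if np.any(np.abs(x) > 30.0) or (model == "imprinting" and abs(x[2]) > 8.0):
            return np.inf
        try:
            logL = ws.solve(_unpack(x, model, with_c), model)[1]
        except (ModelError, FloatingPointError, RuntimeError):
            return np.inf
        return -logL if np.isfinite(logL) else np.inf

    vc = start
    logL = -np.inf
    prev_logL = None
    converged = False
    n_outer = 0
    trace: list = []
    weights_vc: VarianceComponents | None = None  # equal weights at the start
    for n_outer in range(1, max_outer + 1):
        ws.use_weights(weights_vc)
        res = minimize(objective, _pack(vc, model, with_c), method="Nelder-Mead",
                       options={"fatol": tol_inner, "xatol": 1e-6,
                                "maxiter": max_inner_iter, "maxfev": max_inner_iter})
        vc = _unpack(res.x, model, with_c)
        logL = -float(res.fun)
        trace.append((n_outer, logL, vc))
        if not design.has_reduced:
            converged = bool(res.success)
            break
        if prev_logL is not None and abs(logL - prev_logL) < tol_outer:
            converged = bool(res.success)
            break
        prev_logL = logL
        weights_vc = vc
    if not converged:
        warnings.warn("REML search did not fully converge; returning best point",
                      stacklevel=2)
    return REMLResult(vc, logL, converged, n_outer, n_eval, trace, model)


def rlrt(logL_imprinting: float, logL_mendelian: float, df: int = 2,
         *, slack: float = 1e-6) -> tuple[float, float]:
    """Restricted likelihood-ratio test of imprinting vs the Mendelian null.

    Returns (statistic, p-value): statistic = 2 (logL_imp - logL_men),
    referred to a chi-square with ``df`` degrees of freedom.
    """
    stat = 2.0 * (logL_imprinting - logL_mendelian)
    if stat < 0:
        if stat < -2.0 * slack:
            warnings.warn(f"negative RLRT statistic {stat:.3g} clipped to 0", stacklevel=2)
        stat = 0.0
    return stat, float(chi2.sf(stat, df))


def derived_parameters(vc: VarianceComponents) -> dict:
    """Derived genetic parameters on the phenotypic-variance scale.

    sigma_p2 = s2_s + s2_d + s2_c + s2_e; h2 = (s2_s + s2_d)/sigma_p2;
    i2 = sigma_i2/(s2_s + s2_d); c2 = s2_c/sigma_p2.
    """
    c2 = vc.sigma_c2 or 0.0
    sp2 = vc.sigma_s2 + vc.sigma_d2 + c2 + vc.sigma_e2
    gen = vc.sigma_s2 + vc.sigma_d2
    return {
        "sigma_i2": vc.sigma_i2,
        "r": vc.r if gen > 0 else float("nan"),
        "i2": vc.sigma_i2 / gen if gen > 0 else float("nan"),
        "h2": gen / sp2,
        "c2": c2 / sp2,
        "sigma_p2": sp2,
    }


def hessian_standard_errors(design: Design, ginv: SparseSymmetricTriplets,
                            result: REMLResult, *, rel_step: float = 1e-3) -> dict:
    """Approximate standard errors from the numerical Hessian of logL.

    Central finite differences on the untransformed components at the
    REML estimates (weights frozen there); the observed information is
    inverted and the square roots of its diagonal returned.
    """
    vc = result.vc
    with_c = vc.sigma_c2 is not None
    names = (["sigma_s2", "sigma_d2", "sigma_sd", "sigma_e2"]
             if result.model == "imprinting" else ["sigma_s2", "sigma_e2"])
    if with_c:
        names = names + ["sigma_c2"]
    x0 = np.array([getattr(vc, nm) for nm in names])
    ws = _Workspace(design, ginv)
    ws.use_weights(vc if design.has_reduced else None)

    def f(x):
        kw = dict(zip(names, x))
        if result.model == "mendelian":
            kw["sigma_d2"] = kw["sigma_sd"] = kw["sigma_s2"]
        kw.setdefault("sigma_c2", vc.sigma_c2)
        try:
            return ws.solve(VarianceComponents(**kw), result.model)[1]
        except ModelError:
            return -np.inf

    k = len(x0)
    h = rel_step * np.maximum(np.abs(x0), 1e-8)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            def fx(di, dj):
                x = x0.copy()
                x[i] += di * h[i]
                x[j] += dj * h[j]
                return f(x)
            H[i, j] = H[j, i] = (fx(1, 1) - fx(1, -1) - fx(-1, 1) + fx(-1, -1)) \
                / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(-H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return dict(zip(names, se))
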