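"""Design matrices and Gibbs samplers for the animal model.

The model is ``y = X beta + Z a + e`` with fixed effects for contemporary
group (one indicator column per group, no intercept), a linear
heterozygosity covariate and a linear (mean-centered) age-at-calving
covariate; ``a`` is the additive genetic effect of every pedigree member
with covariance ``A sigma2_a``.  Variance components are sampled by a
single-site Gibbs sampler: each location effect from its scalar normal full
conditional, the variances from scaled inverse chi-square conditionals, and
in the bivariate (LOW/HIGH as two traits) model the 2x2 genetic covariance
matrix from an inverse-Wishart conditional.  The residual covariance across
classes is fixed at zero: no animal has records in both classes, so it is
inestimable, mirroring standard multiple-trait missing-record treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve

from . import _kernels
from .pedigree import RelationshipStructure
from .preprocess import HIGH, LOW, PreparedDataset

__all__ = [
    "ChainConfig", "GibbsPriors", "Design", "PosteriorDraws",
    "build_design", "mme_solve", "gibbs_single_trait", "gibbs_bivariate",
]


@dataclass
class ChainConfig:
    """Gibbs chain bookkeeping.

    A cycle ``c`` (1-indexed) is retained iff ``c > burnin`` and
    ``(c - burnin) % thin == 0``, so ``floor((cycles - burnin)/thin)``
    draws are kept.  The study-scale default (600,000 / 60,000 / 20)
    retains 27,000 draws.
    """

    cycles: int = 600_000
    burnin: int = 60_000
    thin: int = 20
    seed: int = 0
    start_sigma2_a: float | None = None
    start_sigma2_e: float | None = None

    def __post_init__(self) -> None:
        if self.burnin >= self.cycles:
            raise ValueError("burnin must be smaller than cycles")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.cycles - self.burnin) // self.thin


@dataclass
class GibbsPriors:
    """Prior hyperparameters for the variance conditionals.

    Defaults follow the flat-variance convention: degrees of freedom -2 and
    scale 0 for every scalar variance (prior density constant in sigma^2),
    and likewise ``g0_df = -2`` with zero scale for the 2x2 genetic
    covariance matrix.  The matrix density is then ``|G0|^{-1/2}``, which is
    exactly the choice whose marginals on the two genetic variances are flat
    after the covariance is integrated over its admissible range — the
    coherent multivariate analogue of the scalar convention.  Two nearby
    choices misbehave: ``g0_df = -3`` ("flat on G0") has an increasing
    improper marginal ``sqrt(va*vb)`` on the variances that inflates weakly
    informed variance posteriors, and any positive ``g0_df`` with a small
    scale concentrates mass on singular matrices and pins the genetic
    correlation at |rg| = 1.
    """

    nu_a: float = -2.0
    s_a: float = 0.0
    nu_e: float = -2.0
    s_e: float = 0.0
    g0_df: float = -2.0
    g0_scale: float = 0.0


@dataclass
class Design:
    """Record-level design for one (sub)analysis."""

    X: sparse.csr_matrix
    Z: sparse.csr_matrix
    y: np.ndarray
    fixed_names: list[str]
    animal_order: list[str]
    record_animals: list[str]
    subset: str
    W: sparse.csr_matrix = field(init=False)
    C: sparse.csr_matrix = field(init=False)   # W'W
    rhs: np.ndarray = field(init=False)        # W'y

    def __post_init__(self) -> None:
        self.W = sparse.hstack([self.X, self.Z], format="csr")
        self.C = (self.W.T @ self.W).tocsr()
        self.C.sort_indices()
        self.rhs = np.asarray(self.W.T @ self.y).ravel()

    @property
    def n_records(self) -> int:
        return self.X.shape[0]

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def n_animals(self) -> int:
        return self.Z.shape[1]

    def phenotypic_variance(self) -> float:
        """Variance of y after OLS removal of the fixed effects.

        Default chain start values are derived from this (raw var(y) is
        dominated by the contemporary-group spread and would start the
        variance chains far above any plausible value).
        """
        resid = self.y - self.X @ np.linalg.lstsq(
            self.X.toarray(), self.y, rcond=None
        )[0]
        return float(np.var(resid))


@dataclass
class PosteriorDraws:
    """Retained variance-component draws plus posterior-mean locations.

    ``draws`` has one row per retained cycle.  ``beta_mean`` / ``a_mean``
    (or the per-trait variants for the bivariate model) are running means
    of the location effects over retained cycles — the EBV source.
    """

    draws: pd.DataFrame
    model: str                     # GENERAL | LOW | HIGH | BIVARIATE
    chain: ChainConfig
    animal_order: list[str]
    beta_mean: dict[str, np.ndarray] = field(default_factory=dict)
    a_mean: dict[str, np.ndarray] = field(default_factory=dict)
    location_draws: np.ndarray | None = None


def build_design(prep: PreparedDataset, structure: RelationshipStructure,
                 subset: str = "ALL") -> Design:
    """Design matrices for the records of one subset (ALL, LOW or HIGH).

    X holds one indicator column per contemporary group present in the
    subset, the heterozygosity covariate, and age at calving centered at the
    subset mean; Z maps records to pedigree positions, so every pedigree
    member (parents without records included) has a breeding-value slot.
    """
    ret = prep.retained
    if subset == "ALL":
        rec = ret
    elif subset in (LOW, HIGH):
        rec = ret[ret["sd_class"] == subset]
    else:
        raise ValueError(f"subset must be ALL, {LOW} or {HIGH}, got {subset!r}")
    if len(rec) == 0:
        raise ValueError(f"no retained records in subset {subset!r}")

    cgs = sorted(rec["cg_id"].unique())
    cg_pos = {c: k for k, c in enumerate(cgs)}
    n, ncg = len(rec), len(cgs)
    rows = np.arange(n)
    X = sparse.lil_matrix((n, ncg + 2))
    for r, cg in zip(rows, rec["cg_id"]):
        X[r, cg_pos[cg]] = 1.0
    X[:, ncg] = rec["htz"].to_numpy(float)[:, None]
    age = rec["age_months"].to_numpy(float)
    X[:, ncg + 1] = (age - age.mean())[:, None]

    index = structure.index
    animals = rec["animal"].tolist()
    missing = [a for a in animals if a not in index]
    if missing:
        raise ValueError(f"records for animals absent from pedigree: {missing[:5]}")
    cols = np.array([index[a] for a in animals])
    Z = sparse.csr_matrix(
        (np.ones(n), (rows, cols)), shape=(n, len(structure.order))
    )
    return Design(
        X=X.tocsr(), Z=Z, y=rec["mp305"].to_numpy(float),
        fixed_names=[f"cg:{c}" for c in cgs] + ["htz", "age"],
        animal_order=list(structure.order), record_animals=animals,
        subset=subset,
    )


def mme_solve(design: Design, Ainv: sparse.spmatrix,
              sigma2_a: float, sigma2_e: float) -> tuple[np.ndarray, np.ndarray]:
    """Henderson's mixed-model equations at fixed variance components.

    Solves ``[X'X, X'Z; Z'X, Z'Z + Ainv*lam] (beta, a) = (X'y, Z'y)`` with
    ``lam = sigma2_e / sigma2_a``, returning the BLUE of beta and BLUP of a.
    Serves as the deterministic oracle for the sampler's location
    conditionals.
    """
    lam = sigma2_e / sigma2_a
    p = design.n_fixed
    C = (design.C + sparse.block_diag(
        [sparse.csr_matrix((p, p)), Ainv * lam])).tocsc()
    with warnings.catch_warnings():
        # singularity is detected below via the residual check
        warnings.simplefilter("ignore", sparse.linalg.MatrixRankWarning)
        sol = spsolve(C, design.rhs)
    resid = C @ sol - design.rhs
    scale = max(1.0, float(np.abs(design.rhs).max()))
    if not np.all(np.isfinite(sol)) or np.abs(resid).max() > 1e-6 * scale:
        raise np.linalg.LinAlgError(
            "mixed-model equations are singular; check the contemporary-group "
            "columns of X for collinearity"
        )
    return sol[:p], sol[p:]


def _check_df(label: str, df_value: float) -> None:
    if df_value <= 0:
        raise ValueError(f"degrees of freedom for {label} is {df_value} <= 0; "
                         "adjust priors or data size")


def _csr_parts(m: sparse.csr_matrix):
    return m.indptr, m.indices, m.data


def gibbs_single_trait(design: Design, Ainv: sparse.csr_matrix,
                       chain: ChainConfig,
                       priors: GibbsPriors | None = None,
                       update_variances: bool = True,
                       keep_location_draws: bool = False) -> PosteriorDraws:
    """Single-trait Gibbs sampler for (beta, a, sigma2_a, sigma2_e).

    Per cycle: every location effect is drawn from its scalar normal full
    conditional (single-site pass in pedigree order after the fixed
    effects); then ``sigma2_a`` from a scaled inverse chi-square with scale
    ``a' Ainv a + nu_a * s_a`` and df ``q + nu_a``, and ``sigma2_e`` with
    scale ``e'e + nu_e * s_e`` and df ``n + nu_e``.  Deterministic given
    ``chain.seed``.  With ``update_variances=False`` the variances stay at
    their start values (location-conditional testing mode).
    """
    priors = priors or GibbsPriors()
    n, p, q = design.n_records, design.n_fixed, design.n_animals
    _check_df("sigma2_a", q + priors.nu_a)
    _check_df("sigma2_e", n + priors.nu_e)
    Ainv = Ainv.tocsr()
    Ainv.sort_indices()

    vary = design.phenotypic_variance()
    s2a = chain.start_sigma2_a or 0.4 * vary
    s2e = chain.start_sigma2_e or 0.6 * vary
    rng = np.random.default_rng(chain.seed)
    theta = np.zeros(p + q)

    nkeep = chain.n_retained
    out = np.empty((nkeep, 2))
    theta_sum = np.zeros(p + q)
    loc_draws = np.empty((nkeep, p + q)) if keep_location_draws else None
    kept = 0
    Ci, Cj, Cv = _csr_parts(design.C)
    Ai, Aj, Av = _csr_parts(Ainv)
    Wi, Wj, Wv = _csr_parts(design.W)

    for c in range(1, chain.cycles + 1):
        normals = rng.standard_normal(p + q)
        _kernels.sweep_single(Ci, Cj, Cv, design.rhs, Ai, Aj, Av,
                              theta, p, s2e / s2a, s2e, normals)
        a = theta[p:]
        if update_variances:
            aqa = _kernels.quad_form(Ai, Aj, Av, a, a)
            sse = _kernels.residual_sse(Wi, Wj, Wv, design.y, theta)
            s2a = (aqa + priors.nu_a * priors.s_a) / rng.chisquare(q + priors.nu_a)
            s2e = (sse + priors.nu_e * priors.s_e) / rng.chisquare(n + priors.nu_e)
            if not (np.isfinite(s2a) and np.isfinite(s2e)):
                raise RuntimeError(f"non-finite variance draw at cycle {c}")
        if c > chain.burnin and (c - chain.burnin) % chain.thin == 0:
            out[kept, 0] = s2a
            out[kept, 1] = s2e
            theta_sum += theta
            if keep_location_draws:
                loc_draws[kept] = theta
            kept += 1

    draws = pd.DataFrame(out[:kept], columns=["sigma2_a", "sigma2_e"])
    mean = theta_sum / max(kept, 1)
    result = PosteriorDraws(
        draws=draws, model="GENERAL" if design.subset == "ALL" else design.subset,
        chain=chain, animal_order=design.animal_order,
        beta_mean={"general": mean[:p]}, a_mean={"general": mean[p:]},
    )
    if keep_location_draws:
        result.location_draws = loc_draws[:kept]
    return result


def _log_prior_chol(L: np.ndarray, priors: GibbsPriors) -> float:
    """Log density of the genetic Cholesky factor under the G0 prior.

    The inverse-Wishart prior IW(g0_scale * I, g0_df) on ``G0 = L L'``
    (density ``|G0|^{-(g0_df+3)/2}`` times the exponential term) induces,
    via the Jacobian ``|dG/dL| = 4 L11^2 L22``, the density
    ``p(L) ∝ L11^{-(g0_df+1)} L22^{-(g0_df+2)} exp(-g0_scale*tr(G0^-1)/2)``.
    Used in the Metropolis acceptance of the interweaving step.
    """
    l11, l22 = L[0, 0], L[1, 1]
    out = (-(priors.g0_df + 1.0) * np.log(l11)
           - (priors.g0_df + 2.0) * np.log(l22))
    if priors.g0_scale > 0:
        G = L @ L.T
        out -= 0.5 * priors.g0_scale * np.trace(np.linalg.inv(G))
    return out


def _asis_genetic_scale(rng, designs, thetas, ps, G0, s2e, priors):
    """Interweaving (ASIS) update of the genetic covariance and BV vectors.

    Re-expresses the breeding values as ``a_low = L11*u1``,
    ``a_high = L21*u1 + L22*u2`` with ``G0 = LL'`` and ``(u1, u2)`` held
    fixed (they are ancillary: distributed N(0, I (x) A) whatever L is), then
    redraws the Cholesky entries as regression coefficients of the records
    on u — a conditional informed purely by data, which restores mixing of
    the genetic correlation when the standard conditional is pinned near
    |rg| = 1 (every animal has a record in at most one class, so the
    inverse-Wishart conditional alone barely feels the data there).  The
    Gaussian likelihood proposal is accepted on the induced-prior ratio,
    leaving the posterior invariant.  Returns the updated G0 and writes the
    rescaled breeding values back into ``thetas``.
    """
    L = np.linalg.cholesky(G0)
    if L[0, 0] < 1e-10 or L[1, 1] < 1e-10:
        return G0
    a_low = thetas[0][ps[0]:]
    a_high = thetas[1][ps[1]:]
    u1 = a_low / L[0, 0]
    u2 = (a_high - L[1, 0] * u1) / L[1, 1]

    # record-level fixed-effect fits and ancillary covariates
    covs = []
    resids = []
    for t, u_cols in ((0, (u1,)), (1, (u1, u2))):
        d = designs[t]
        fixed_fit = d.X @ thetas[t][: ps[t]]
        rec_idx = d.Z.indices  # one animal per record row
        covs.append(np.column_stack([u[rec_idx] for u in u_cols]))
        resids.append(d.y - fixed_fit)

    # trait LOW: scalar regression residual = L11 * u1 + e
    U, r = covs[0], resids[0]
    prec = float(U[:, 0] @ U[:, 0]) / s2e[0]
    mean = float(U[:, 0] @ r) / s2e[0] / prec
    l11_new = mean + rng.standard_normal() / np.sqrt(prec)
    # trait HIGH: bivariate regression residual = L21 * u1 + L22 * u2 + e
    U, r = covs[1], resids[1]
    P = (U.T @ U) / s2e[1]
    m = np.linalg.solve(P, U.T @ r / s2e[1])
    Lp = np.linalg.cholesky(np.linalg.inv(P))
    l21_new, l22_new = m + Lp @ rng.standard_normal(2)

    if l11_new <= 0 or l22_new <= 0:
        return G0
    L_new = np.array([[l11_new, 0.0], [l21_new, l22_new]])
    log_acc = _log_prior_chol(L_new, priors) - _log_prior_chol(L, priors)
    if np.log(rng.random()) >= log_acc:
        return G0
    thetas[0][ps[0]:] = l11_new * u1
    thetas[1][ps[1]:] = l21_new * u1 + l22_new * u2
    return L_new @ L_new.T


def _sample_invwishart_2x2(rng: np.random.Generator, df: float,
                           scale: np.ndarray) -> np.ndarray:
    """Draw from the 2x2 inverse-Wishart via the Bartlett decomposition."""
    sinv = np.linalg.inv(scale)
    L = np.linalg.cholesky(sinv)
    A = np.array([
        [np.sqrt(rng.chisquare(df)), 0.0],
        [rng.standard_normal(), np.sqrt(rng.chisquare(df - 1.0))],
    ])
    T = L @ A
    W = T @ T.T
    return np.linalg.inv(W)


def gibbs_bivariate(design_low: Design, design_high: Design,
                    Ainv: sparse.csr_matrix, chain: ChainConfig,
                    priors: GibbsPriors | None = None,
                    start_G0: np.ndarray | None = None) -> PosteriorDraws:
    """Bivariate Gibbs sampler treating LOW and HIGH yields as two traits.

    Every pedigree member carries a breeding-value pair ``(a_low, a_high)``
    with prior precision ``G0^{-1} (Kronecker) Ainv``; G0 is drawn from an
    inverse-Wishart with scale ``[a_t' Ainv a_u] + g0_scale * I`` and df
    ``q + g0_df``, followed by an interweaving (ASIS) rescaling move that
    keeps the genetic-correlation chain mobile (see
    :func:`_asis_genetic_scale`); residual variances are sampled
    independently per trait (residual covariance fixed at zero).
    Deterministic given ``chain.seed``.
    """
    priors = priors or GibbsPriors()
    both = set(design_low.record_animals) & set(design_high.record_animals)
    if both:
        raise ValueError(
            f"animals with records in both SD classes: {sorted(both)[:5]} — "
            "each animal must appear in exactly one class"
        )
    if design_low.animal_order != design_high.animal_order:
        raise ValueError("LOW and HIGH designs must share the pedigree order")
    q = design_low.n_animals
    designs = (design_low, design_high)
    ns = [d.n_records for d in designs]
    ps = [d.n_fixed for d in designs]
    for n_t in ns:
        _check_df("sigma2_e", n_t + priors.nu_e)
    _check_df("G0", q + priors.g0_df - 1.0)
    Ainv = Ainv.tocsr()
    Ainv.sort_indices()
    Ai, Aj, Av = _csr_parts(Ainv)

    rng = np.random.default_rng(chain.seed)
    varys = [d.phenotypic_variance() for d in designs]
    if start_G0 is None:
        G0 = np.diag([0.4 * v for v in varys])
    else:
        G0 = np.array(start_G0, float)
    s2e = [chain.start_sigma2_e or 0.6 * v for v in varys]
    thetas = [np.zeros(p + q) for p in ps]

    nkeep = chain.n_retained
    out = np.empty((nkeep, 5))
    sums = [np.zeros(p + q) for p in ps]
    kept = 0
    Cparts = [_csr_parts(d.C) for d in designs]
    Wparts = [_csr_parts(d.W) for d in designs]
    prior_scale_eye = priors.g0_scale * np.eye(2)

    for c in range(1, chain.cycles + 1):
        Ginv = np.linalg.inv(G0)
        for t in (0, 1):
            u = 1 - t
            d = designs[t]
            normals = rng.standard_normal(ps[t] + q)
            _kernels.sweep_bivariate_trait(
                *Cparts[t], d.rhs, Ai, Aj, Av,
                thetas[t], thetas[u][ps[u]:], ps[t], 1.0 / s2e[t],
                Ginv[t, t], Ginv[t, u], normals,
            )
        a0 = thetas[0][ps[0]:]
        a1 = thetas[1][ps[1]:]
        S = np.empty((2, 2))
        S[0, 0] = _kernels.quad_form(Ai, Aj, Av, a0, a0)
        S[1, 1] = _kernels.quad_form(Ai, Aj, Av, a1, a1)
        S[0, 1] = S[1, 0] = _kernels.quad_form(Ai, Aj, Av, a0, a1)
        G0 = _sample_invwishart_2x2(rng, q + priors.g0_df, S + prior_scale_eye)
        G0 = _asis_genetic_scale(rng, designs, thetas, ps, G0, s2e, priors)
        for t in (0, 1):
            sse = _kernels.residual_sse(*Wparts[t], designs[t].y, thetas[t])
            s2e[t] = (sse + priors.nu_e * priors.s_e) / rng.chisquare(
                ns[t] + priors.nu_e
            )
        if not np.all(np.isfinite([G0[0, 0], G0[1, 1], s2e[0], s2e[1]])):
            raise RuntimeError(f"non-finite variance draw at cycle {c}")
        if c > chain.burnin and (c - chain.burnin) % chain.thin == 0:
            out[kept] = (G0[0, 0], G0[1, 1], G0[0, 1], s2e[0], s2e[1])
            for t in (0, 1):
                sums[t] += thetas[t]
            kept += 1

    draws = pd.DataFrame(out[:kept], columns=[
        "sigma2_a_low", "sigma2_a_high", "sigma_a_lh",
        "sigma2_e_low", "sigma2_e_high",
    ])
    means = [s / max(kept, 1) for s in sums]
    return PosteriorDraws(
        draws=draws, model="BIVARIATE", chain=chain,
        animal_order=design_low.animal_order,
        beta_mean={"low": means[0][: ps[0]], "high": means[1][: ps[1]]},
        a_mean={"low": means[0][ps[0]:], "high": means[1][ps[1]:]},
    )
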