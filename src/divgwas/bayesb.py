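"""Bayesian multiple-marker regression (BayesB) for one or two traits.

Model, per trait vector y_t:

    y_t = X_t b_t + W_t c_t + Z_t u_t + sum_j z_j (delta_jt alpha_jt) + e_t

with fixed effects b (month, sex, parity; flat prior), common-litter effects
c ~ N(0, I (x) C), pedigree polygenic effects u ~ N(0, A (x) U), residuals
e ~ N(0, I (x) R) ordered by individual, and sparse marker effects: each
locus j carries an indicator configuration delta_j.  Bivariately a locus can
hit neither trait, either one, or both ("four possible combinations"); the
default prior mass is 0.9982 on the joint null and 0.0006 on each of the
other three configurations; univariately the exclusion probability is
0.9988.  All (co)variance matrices have inverse-Wishart priors; nonzero
effects are N(0, G_j) with locus-specific G_j (classic BayesB) or a shared G
(BayesC-like), selectable via ``locus_variance_mode``.

Marker covariates are column-centered before sampling; missing phenotypes
are handled by residual augmentation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _gibbs
from .genotypes import GenotypeData
from .pedigree import Pedigree, build_numerator_relationship

logger = logging.getLogger(__name__)

__all__ = [
    "ModelError",
    "ModelSpec",
    "PriorSpec",
    "MCMCConfig",
    "PosteriorSamples",
    "config_probs_from_joint_null",
    "run_mcmc",
    "run_univariate",
    "ppa_per_snp",
    "default_priors",
]

DEFAULT_PI00 = 0.9982  # bivariate joint-null mass
DEFAULT_PI_UNI = 0.9988  # univariate exclusion probability


def config_probs_from_joint_null(pi00: float = DEFAULT_PI00) -> tuple:
    """Four-configuration prior mass from the joint-null probability.

    The remaining mass 1 - pi00 is split equally over the three non-null
    configurations ((1,0), (0,1), (1,1)); with pi00 = 0.9982 each gets
    0.0006.
    """
    if not (0 < pi00 < 1):
        raise ModelError("joint-null probability must be in (0, 1)")
    q = (1.0 - pi00) / 3.0
    return (pi00, q, q, q)


class ModelError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Design and data for one run; t = Y.shape[1] in {1, 2}.

    ``litter`` / ``animal`` are integer codes (-1 = term absent for that
    record); ``A`` is the numerator relationship matrix over the coded
    animals.  Missing phenotypes are NaN in ``Y``.
    """

    Y: np.ndarray  # (n, t)
    X: np.ndarray  # (n, p) full-rank fixed-effect design
    Z: np.ndarray  # (n, k) dosages
    litter: np.ndarray | None = None  # (n,) codes
    animal: np.ndarray | None = None  # (n,) codes into A
    A: np.ndarray | None = None  # (m, m)
    snp_ids: list | None = None

    @property
    def n_traits(self) -> int:
        return self.Y.shape[1]

    def validate(self) -> None:
        Y = np.asarray(self.Y, dtype=float)
        if Y.ndim != 2 or Y.shape[1] not in (1, 2):
            raise ModelError("Y must be (n, t) with t in {1, 2}")
        n = Y.shape[0]
        for name, arr in (("X", self.X), ("Z", self.Z)):
            if np.asarray(arr).shape[0] != n:
                raise ModelError(f"{name} rows must match phenotype length")
        for t in range(Y.shape[1]):
            col = Y[:, t]
            obs = col[~np.isnan(col)]
            if n > 0 and (obs.size == 0 or (obs.size > 1 and np.var(obs) == 0.0)):
                raise ModelError(f"trait {t + 1} has zero variance (constant phenotype)")
        if n > 0 and self.X.shape[1] > 0:
            if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
                raise ModelError("fixed-effect design X is rank-deficient")
        if (self.animal is None) != (self.A is None):
            raise ModelError("animal codes and A must be supplied together")
        if self.A is not None and np.max(np.abs(self.A - self.A.T)) > 1e-8:
            raise ModelError("A must be symmetric")

    @classmethod
    def from_tables(cls, phenotypes: pd.DataFrame, genotypes: GenotypeData,
                    pedigree: Pedigree | None = None,
                    traits=("trait1", "trait2"),
                    fixed=("month", "sex", "parity"),
                    litter_col: str | None = "litter") -> "ModelSpec":
        """Assemble a ModelSpec from phenotype/genotype/pedigree tables.

        Genotyped animals with a phenotype record enter the model; the first
        fixed factor keeps all its dummy levels (absorbing the intercept),
        later factors drop their first level.
        """
        df = phenotypes.set_index("animal")
        common = [a for a in genotypes.animal_ids if a in df.index]
        if not common:
            raise ModelError("no animal is both genotyped and phenotyped")
        g = genotypes.subset(
            animal_rows=[genotypes.animal_ids.index(a) for a in common]
        )
        df = df.loc[common]
        for tr in traits:
            if tr not in df.columns:
                raise ModelError(f"trait {tr!r} absent from phenotype table")
        Y = df[list(traits)].to_numpy(dtype=float)
        blocks = []
        for i, f in enumerate(fixed):
            dmy = pd.get_dummies(df[f].astype("category"), drop_first=(i > 0))
            blocks.append(dmy.to_numpy(dtype=float))
        X = np.hstack(blocks) if blocks else np.ones((len(df), 1))
        litter = None
        if litter_col is not None and litter_col in df.columns:
            litter = pd.Categorical(df[litter_col]).codes.astype(np.int64)
        animal = A = None
        if pedigree is not None:
            A = build_numerator_relationship(pedigree)
            animal = pedigree.index_of(common)
        return cls(Y=Y, X=X, Z=g.dosages.astype(float), litter=litter,
                   animal=animal, A=A, snp_ids=g.snp_map["snp_id"].tolist())


@dataclass
class PriorSpec:
    """Prior (co)variance matrices and inclusion mass.

    ``nu_*`` default to p + 2 (p = trait count) so each prior mean equals the
    supplied matrix.  ``pi`` is (pi00, pi10, pi01, pi11) bivariately or
    (pi_excluded, pi_included) univariately.
    """

    R0: np.ndarray
    C0: np.ndarray | None = None
    U0: np.ndarray | None = None
    G0: np.ndarray | None = None
    nu_R: float | None = None
    nu_C: float | None = None
    nu_U: float | None = None
    nu_G: float | None = None
    pi: tuple | None = None

    def resolved(self, t: int) -> "PriorSpec":
        def mat(M, name):
            if M is None:
                raise ModelError(f"prior matrix {name} is required for this model")
            M = np.atleast_2d(np.asarray(M, dtype=float))
            if M.shape != (t, t):
                raise ModelError(f"prior matrix {name} must be {t}x{t}, got {M.shape}")
            if np.any(np.linalg.eigvalsh((M + M.T) / 2) <= 0):
                raise ModelError(f"prior matrix {name} must be positive definite")
            return (M + M.T) / 2

        pi = self.pi
        if pi is None:
            pi = (config_probs_from_joint_null() if t == 2
                  else (DEFAULT_PI_UNI, 1.0 - DEFAULT_PI_UNI))
        pi = tuple(float(x) for x in pi)
        if len(pi) != 2**t:
            raise ModelError(f"pi must have {2**t} entries for t={t}")
        if any(x < 0 for x in pi) or abs(sum(pi) - 1.0) > 1e-9:
            raise ModelError("inclusion prior masses must be >= 0 and sum to 1")
        nu = [x if x is not None else t + 2.0
              for x in (self.nu_R, self.nu_C, self.nu_U, self.nu_G)]
        return PriorSpec(
            R0=mat(self.R0, "R0"),
            C0=mat(self.C0, "C0") if self.C0 is not None else None,
            U0=mat(self.U0, "U0") if self.U0 is not None else None,
            G0=mat(self.G0, "G0"),
            nu_R=float(nu[0]), nu_C=float(nu[1]), nu_U=float(nu[2]), nu_G=float(nu[3]),
            pi=pi,
        )


def default_priors(model: ModelSpec, pi: tuple | None = None,
                   h2_prior: float = 0.35, c2_prior: float = 0.10,
                   marker_frac: float = 0.10, rg_prior: float = 0.3) -> PriorSpec:
    """Data-scaled default priors for a pipeline run.

    Splits the sample phenotypic (co)variance into polygenic (``h2_prior``),
    litter (``c2_prior``), marker (``marker_frac``, spread over the expected
    number of included loci under the inclusion prior) and residual parts.
    Stand-in for externally estimated components when none are supplied.
    """
    t = model.n_traits
    Yobs = np.ma.masked_invalid(model.Y)
    Sy = np.atleast_2d(np.ma.cov(Yobs, rowvar=False).filled(0.0))
    if t == 1:
        Sy = np.atleast_2d(np.ma.var(Yobs).item())
    d = np.sqrt(np.diag(Sy))
    corr = np.eye(t) + rg_prior * (np.ones((t, t)) - np.eye(t))
    pi_res = pi
    if pi_res is None:
        pi_res = (config_probs_from_joint_null() if t == 2
                  else (DEFAULT_PI_UNI, 1.0 - DEFAULT_PI_UNI))
    incl = 1.0 - pi_res[0]
    k = max(model.Z.shape[1], 1)
    var_z = model.Z.var(axis=0).mean() if model.Z.size else 0.5
    g_scale = marker_frac / (max(incl, 1e-6) * k * max(var_z, 1e-12))
    res_frac = max(1.0 - h2_prior - c2_prior - marker_frac, 0.05)

    def scaled(frac, use_corr=True):
        base = (corr if use_corr else np.eye(t))
        return frac * base * np.outer(d, d)

    return PriorSpec(
        R0=scaled(res_frac, use_corr=False) + 1e-8 * np.eye(t),
        C0=scaled(c2_prior, use_corr=False) + 1e-8 * np.eye(t),
        U0=scaled(h2_prior) + 1e-8 * np.eye(t),
        G0=scaled(g_scale) + 1e-12 * np.eye(t),
        pi=pi_res,
    )


@dataclass
class MCMCConfig:
    n_iter: int = 470_000
    burn_in: int = 70_000
    thin: int = 40
    seed: int = 0
    locus_variance_mode: str = "per-locus"  # or "shared"

    def validate(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ModelError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ModelError("thin must be >= 1")
        if self.locus_variance_mode not in ("per-locus", "shared"):
            raise ModelError("locus_variance_mode must be 'per-locus' or 'shared'")

    @property
    def n_saved(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorSamples:
    """Thinned MCMC draws of all model unknowns.

    ``alpha`` is the masked marker effect (zero wherever ``delta`` is zero);
    ``resid`` stores the residual vector of each saved draw so that
    y - Xb - Wc - Zu - Z alpha reproduces it exactly (complete records).
    """

    alpha: np.ndarray  # (S, k, t)
    delta: np.ndarray  # (S, k, t) uint8
    b: np.ndarray  # (S, p, t)
    litter_effects: np.ndarray  # (S, L, t)
    u: np.ndarray  # (S, m, t)
    R: np.ndarray  # (S, t, t)
    C: np.ndarray
    U: np.ndarray
    G: np.ndarray
    resid: np.ndarray  # (S, n, t)
    meta: dict = field(default_factory=dict)

    @property
    def n_saved(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_traits(self) -> int:
        return self.alpha.shape[2]

    def save(self, path) -> None:
        """Columnar archive (.npz) plus a JSON manifest alongside."""
        from pathlib import Path

        path = Path(path)
        np.savez_compressed(
            path, alpha=self.alpha, delta=self.delta, b=self.b,
            litter_effects=self.litter_effects, u=self.u, R=self.R, C=self.C,
            U=self.U, G=self.G, resid=self.resid,
        )
        manifest = dict(self.meta)
        manifest["n_saved"] = int(self.n_saved)
        manifest["n_traits"] = int(self.n_traits)
        with open(path.with_suffix(".manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        from pathlib import Path

        path = Path(path)
        z = np.load(path)
        meta = {}
        mpath = path.with_suffix(".manifest.json")
        if mpath.exists():
            meta = json.loads(mpath.read_text())
        return cls(alpha=z["alpha"], delta=z["delta"], b=z["b"],
                   litter_effects=z["litter_effects"], u=z["u"], R=z["R"],
                   C=z["C"], U=z["U"], G=z["G"], resid=z["resid"], meta=meta)


def _csr(codes: np.ndarray | None, n_groups: int):
    if codes is None or n_groups == 0:
        return np.zeros(1, dtype=np.int64), np.zeros(0, dtype=np.int64)
    order = np.argsort(codes, kind="stable")
    valid = order[codes[order] >= 0]
    counts = np.bincount(codes[valid], minlength=n_groups)
    ptr = np.zeros(n_groups + 1, dtype=np.int64)
    np.cumsum(counts, out=ptr[1:])
    return ptr, valid.astype(np.int64)


def run_mcmc(model: ModelSpec, prior: PriorSpec, mcmc: MCMCConfig) -> PosteriorSamples:
    """Single-site Gibbs sampler over all model unknowns.

    Deterministic given ``mcmc.seed``.  Returns floor((n_iter - burn_in) /
    thin) saved draws.
    """
    model.validate()
    mcmc.validate()
    t = model.n_traits
    pr = prior.resolved(t)

    Y = np.asarray(model.Y, dtype=float)
    n = Y.shape[0]
    miss = np.isnan(Y)
    ET = np.where(miss, 0.0, Y).T.copy()
    missT = miss.T.astype(np.uint8).copy()

    X = np.asarray(model.X, dtype=float)
    XT = np.ascontiguousarray(X.T)
    xtx = (X * X).sum(axis=0)

    Z = np.asarray(model.Z, dtype=float)
    k = Z.shape[1]
    if n > 0 and k > 0:
        Z = Z - Z.mean(axis=0, keepdims=True)  # center; intercept is in X
    ZT = np.ascontiguousarray(Z.T)
    zz = (Z * Z).sum(axis=0) if n > 0 else np.zeros(k)

    if model.litter is not None:
        L = int(model.litter.max()) + 1 if model.litter.size else 0
        lit_ptr, lit_rows = _csr(model.litter.astype(np.int64), L)
        if pr.C0 is None:
            raise ModelError("litter term present but C0 prior missing")
    else:
        L = 0
        lit_ptr, lit_rows = _csr(None, 0)

    if model.animal is not None:
        A = np.asarray(model.A, dtype=float)
        m = A.shape[0]
        jitter = 0.0
        while True:
            try:
                Ainv = np.linalg.inv(A + jitter * np.eye(m))
                break
            except np.linalg.LinAlgError:  # pragma: no cover
                jitter = 1e-8 if jitter == 0 else jitter * 10
        an_ptr, an_rows = _csr(model.animal.astype(np.int64), m)
        if pr.U0 is None:
            raise ModelError("polygenic term present but U0 prior missing")
    else:
        m = 0
        Ainv = np.zeros((0, 0))
        an_ptr, an_rows = _csr(None, 0)

    S = mcmc.n_saved
    p = X.shape[1]
    out = dict(
        alpha_s=np.zeros((S, k, t)),
        delta_s=np.zeros((S, k, t), dtype=np.uint8),
        b_s=np.zeros((S, p, t)),
        c_s=np.zeros((S, L, t)),
        u_s=np.zeros((S, m, t)),
        R_s=np.zeros((S, t, t)),
        C_s=np.zeros((S, t, t)),
        U_s=np.zeros((S, t, t)),
        G_s=np.zeros((S, t, t)),
        E_s=np.zeros((S, n, t)),
    )
    seed = int(mcmc.seed) % (2**31)
    per_locus = mcmc.locus_variance_mode == "per-locus"
    C0 = pr.C0 if pr.C0 is not None else np.eye(t)
    U0 = pr.U0 if pr.U0 is not None else np.eye(t)
    lp = np.log(np.maximum(np.asarray(pr.pi), 1e-300))

    logger.info(
        "gibbs: t=%d n=%d p=%d L=%d m=%d k=%d iters=%d burn=%d thin=%d mode=%s",
        t, n, p, L, m, k, mcmc.n_iter, mcmc.burn_in, mcmc.thin, mcmc.locus_variance_mode,
    )
    if t == 1:
        _gibbs.kernel_uni(
            seed, mcmc.n_iter, mcmc.burn_in, mcmc.thin,
            np.ascontiguousarray(ET[0]), np.ascontiguousarray(missT[0]),
            XT, xtx, lit_ptr, lit_rows, an_ptr, an_rows, Ainv, ZT, zz,
            pr.R0[0, 0], pr.nu_R, C0[0, 0], pr.nu_C, U0[0, 0], pr.nu_U,
            pr.G0[0, 0], pr.nu_G, lp[0], lp[1], per_locus,
            out["alpha_s"], out["delta_s"], out["b_s"], out["c_s"], out["u_s"],
            out["R_s"], out["C_s"], out["U_s"], out["G_s"], out["E_s"],
        )
    else:
        _gibbs.kernel_biv(
            seed, mcmc.n_iter, mcmc.burn_in, mcmc.thin,
            np.ascontiguousarray(ET), np.ascontiguousarray(missT),
            XT, xtx, lit_ptr, lit_rows, an_ptr, an_rows, Ainv, ZT, zz,
            pr.R0, pr.nu_R, C0, pr.nu_C, U0, pr.nu_U, pr.G0, pr.nu_G,
            lp, per_locus,
            out["alpha_s"], out["delta_s"], out["b_s"], out["c_s"], out["u_s"],
            out["R_s"], out["C_s"], out["U_s"], out["G_s"], out["E_s"],
        )
    for name in ("R_s", "C_s", "U_s", "G_s"):
        arr = out[name]
        if not np.all(np.isfinite(arr)):
            raise RuntimeError(
                f"divergent sampler: non-finite values in {name}; "
                f"dump: {arr[~np.isfinite(arr).all(axis=(1, 2))][:3]!r}"
            )
    meta = dict(
        seed=seed, n_iter=mcmc.n_iter, burn_in=mcmc.burn_in, thin=mcmc.thin,
        locus_variance_mode=mcmc.locus_variance_mode, n_traits=t, n_records=n,
        n_snps=k, pi=list(pr.pi), snp_ids=model.snp_ids,
    )
    return PosteriorSamples(
        alpha=out["alpha_s"], delta=out["delta_s"], b=out["b_s"],
        litter_effects=out["c_s"], u=out["u_s"], R=out["R_s"], C=out["C_s"],
        U=out["U_s"], G=out["G_s"], resid=out["E_s"], meta=meta,
    )


def run_univariate(model: ModelSpec, prior: PriorSpec, mcmc: MCMCConfig) -> PosteriorSamples:
    """Univariate BayesB (two-category indicator, pi default 0.9988)."""
    if model.n_traits != 1:
        raise ModelError("run_univariate requires a single-trait ModelSpec")
    return run_mcmc(model, prior, mcmc)


def ppa_per_snp(samples: PosteriorSamples) -> np.ndarray:
    """Posterior probability of association per SNP and trait.

    Fraction of saved draws in which the SNP is in the model with a nonzero
    effect.
    """
    if samples.n_saved < 1:
        raise ModelError("need at least one saved draw")
    return samples.delta.mean(axis=0)
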