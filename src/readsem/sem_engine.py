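"""Stage 2: maximum-likelihood structural equation estimation.

The model is expressed in RAM notation over t = p + 1 variables (the 13
observed constructs plus latent g).  A holds directed coefficients
(g-loadings on the broad abilities, broad-ability -> reading-skill paths,
and the reading-skill cascade), S holds the exogenous variance of g (fixed
at 1 for identification) and one free residual variance per observed
variable, and F filters the observed rows.  The implied covariance is

    Sigma(theta) = F (I - A)^-1 S (I - A)^-T F^T.

The input is the pooled correlation matrix treated as the covariance
matrix of standardized variables (means 0, SDs 1).  The discrepancy
function is the normal-theory ML fit function

    F_ML = ln|Sigma| - ln|S_obs| + tr(S_obs Sigma^-1) - p,

minimized by L-BFGS-B with an analytic gradient, residual variances
bounded at zero (Heywood cases are flagged).  chi2 = (N - 1) * F_min.
Standard errors come from the inverse expected information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import optimize, stats

from readsem.consensus import BROAD_ABILITIES, CASCADE_EDGES, CONSTRUCTS, READING_SKILLS


class SemError(ValueError):
    pass


@dataclass(frozen=True)
class SemModelSpec:
    """Structural model definition.

    ``loadings``: observed indicators of latent g (free loadings, g
    variance fixed to 1).  ``paths``: directed edges among observed
    variables.  Every observed variable gets a free residual variance; no
    residual covariances.
    """

    observed: tuple[str, ...]
    loadings: tuple[str, ...]
    paths: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        unknown = [v for v in self.loadings if v not in self.observed]
        unknown += [v for e in self.paths for v in e if v not in self.observed]
        if unknown:
            raise SemError(f"unknown variables in spec: {sorted(set(unknown))}")
        if self._has_cycle():
            raise SemError("structural path graph contains a cycle")

    def _has_cycle(self) -> bool:
        import networkx as nx

        graph = nx.DiGraph(list(self.paths))
        return not nx.is_directed_acyclic_graph(graph)

    @property
    def param_names(self) -> tuple[str, ...]:
        names = [f"lambda[{v}]" for v in self.loadings]
        names += [f"beta[{src}->{dst}]" for src, dst in self.paths]
        names += [f"theta[{v}]" for v in self.observed]
        return tuple(names)

    @property
    def n_free(self) -> int:
        return len(self.loadings) + len(self.paths) + len(self.observed)

    @property
    def df(self) -> int:
        p = len(self.observed)
        return p * (p + 1) // 2 - self.n_free

    def to_dict(self) -> dict:
        return {
            "observed": list(self.observed),
            "loadings": list(self.loadings),
            "paths": [list(e) for e in self.paths],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SemModelSpec":
        return cls(
            observed=tuple(data["observed"]),
            loadings=tuple(data["loadings"]),
            paths=tuple((str(a), str(b)) for a, b in data["paths"]),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "SemModelSpec":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls.from_dict(data)


def default_model_spec(gv_paths: bool = True) -> SemModelSpec:
    """The integrated cognitive-reading model.

    Latent g loads on all eight broad abilities; every broad ability
    predicts every reading skill (``gv_paths=False`` removes the five
    Gv -> reading paths); the reading skills form the developmental
    cascade PD -> LD -> DS -> RF -> RC with all forward edges.
    """
    paths = [
        (b, s)
        for b in BROAD_ABILITIES
        for s in READING_SKILLS
        if gv_paths or b != "Gv"
    ]
    paths += list(CASCADE_EDGES)
    return SemModelSpec(
        observed=CONSTRUCTS, loadings=BROAD_ABILITIES, paths=tuple(paths)
    )


@dataclass
class SemFit:
    spec: SemModelSpec
    estimates: dict[str, float]
    se: dict[str, float]
    fmin: float
    chi2: float
    df: int
    p_value: float
    baseline_chi2: float
    baseline_df: int
    cfi: float
    tli: float | None
    rmsea: float | None
    srmr: float
    N_used: int
    converged: bool
    heywood: tuple[str, ...] = ()
    implied: np.ndarray | None = None

    @property
    def loadings(self) -> dict[str, float]:
        return {
            name.split("[")[1][:-1]: val
            for name, val in self.estimates.items()
            if name.startswith("lambda[")
        }

    @property
    def path_coefficients(self) -> dict[tuple[str, str], float]:
        out = {}
        for name, val in self.estimates.items():
            if name.startswith("beta["):
                src, dst = name[5:-1].split("->")
                out[(src, dst)] = val
        return out

    def to_dict(self) -> dict:
        return {
            "model": self.spec.to_dict(),
            "estimates": self.estimates,
            "se": self.se,
            "fit": {
                "fmin": self.fmin,
                "chi2": self.chi2,
                "df": self.df,
                "p": self.p_value,
                "baseline_chi2": self.baseline_chi2,
                "baseline_df": self.baseline_df,
                "cfi": self.cfi,
                "tli": self.tli,
                "rmsea": self.rmsea,
                "srmr": self.srmr,
                "N": self.N_used,
                "converged": self.converged,
                "heywood": list(self.heywood),
            },
        }


def _ram_matrices(spec: SemModelSpec, theta: np.ndarray):
    """Build A and S (t x t, t = p + 1 with g last) from the parameter vector."""
    p = len(spec.observed)
    t = p + 1
    g = p  # latent index
    idx = {v: i for i, v in enumerate(spec.observed)}
    nl, npth = len(spec.loadings), len(spec.paths)
    A = np.zeros((t, t))
    for pos, v in enumerate(spec.loadings):
        A[idx[v], g] = theta[pos]
    for pos, (src, dst) in enumerate(spec.paths):
        A[idx[dst], idx[src]] = theta[nl + pos]
    S = np.zeros((t, t))
    S[g, g] = 1.0  # g variance fixed for identification
    for pos, v in enumerate(spec.observed):
        S[idx[v], idx[v]] = theta[nl + npth + pos]
    return A, S


def implied_matrix(spec: SemModelSpec, theta: np.ndarray) -> np.ndarray:
    """Model-implied covariance among the observed variables (RAM algebra)."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.n_free,):
        raise SemError(
            f"parameter vector has length {theta.shape}, expected {spec.n_free}"
        )
    p = len(spec.observed)
    A, S = _ram_matrices(spec, theta)
    eye = np.eye(A.shape[0])
    try:
        E = np.linalg.solve(eye - A, eye)
    except np.linalg.LinAlgError as err:
        raise SemError("(I - A) is singular; cyclic specification?") from err
    sigma_full = E @ S @ E.T
    return sigma_full[:p, :p]


def _fml_and_grad(theta, spec, S_obs):
    p = len(spec.observed)
    n_struct = len(spec.loadings) + len(spec.paths)
    if not np.all(np.isfinite(theta)):
        return 1e12, np.zeros_like(theta)
    A, S = _ram_matrices(spec, theta)
    t = A.shape[0]
    eye = np.eye(t)
    E = np.linalg.solve(eye - A, eye)
    sigma_full = E @ S @ E.T
    sigma = sigma_full[:p, :p]
    # Cholesky guards positive definiteness: a positive determinant alone
    # does not, and inverting a near-singular matrix can silently push the
    # discrepancy to large negative garbage
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        # implied matrix not PD (residual variances on the zero bound):
        # steer the line search back by rewarding larger residuals
        grad = np.zeros_like(theta)
        grad[n_struct:] = -1.0
        return 1e10, grad
    diag_chol = np.diag(chol)
    if np.min(diag_chol) < 1e-10:
        grad = np.zeros_like(theta)
        grad[n_struct:] = -1.0
        return 1e10, grad
    logdet = 2.0 * float(np.sum(np.log(diag_chol)))
    half = np.linalg.solve(chol, np.eye(p))
    sigma_inv = half.T @ half
    _, logdet_obs = np.linalg.slogdet(S_obs)
    f = logdet - logdet_obs + float(np.sum(S_obs * sigma_inv)) - p
    if not np.isfinite(f):
        grad = np.zeros_like(theta)
        grad[n_struct:] = -1.0
        return 1e10, grad
    # gradient: dF = tr(W dSigma), W = Sigma^-1 - Sigma^-1 S_obs Sigma^-1
    W = sigma_inv - sigma_inv @ S_obs @ sigma_inv
    U = np.zeros((t, t))
    U[:p, :p] = W
    ESE = E @ S @ E.T
    Z = ESE @ U @ E  # dF/dA[k,l] = 2 * Z[l,k]
    M = E.T @ U @ E  # dF/dS[k,k] = M[k,k]
    idx = {v: i for i, v in enumerate(spec.observed)}
    g = p
    nl, npth = len(spec.loadings), len(spec.paths)
    grad = np.empty_like(theta)
    for pos, v in enumerate(spec.loadings):
        grad[pos] = 2.0 * Z[g, idx[v]]
    for pos, (src, dst) in enumerate(spec.paths):
        grad[nl + pos] = 2.0 * Z[idx[src], idx[dst]]
    for pos, v in enumerate(spec.observed):
        grad[nl + npth + pos] = M[idx[v], idx[v]]
    return f, grad


def _start_values(spec: SemModelSpec, rng: np.random.Generator, jitter: float):
    theta = np.concatenate(
        [
            np.full(len(spec.loadings), 0.5),
            np.full(len(spec.paths), 0.1),
            np.full(len(spec.observed), 0.5),
        ]
    )
    if jitter > 0:
        theta = theta + rng.uniform(-jitter, jitter, size=theta.size)
        theta[-len(spec.observed):] = np.clip(theta[-len(spec.observed):], 0.05, None)
    return theta


def baseline_fit(S_obs: np.ndarray, N: int) -> tuple[float, int]:
    """Independence baseline: all covariances zero, variances free.

    For that model the ML solution sets Sigma = diag(S_obs), so
    F_min = -ln|R_obs| when the input has unit diagonal.
    """
    p = S_obs.shape[0]
    d = np.diag(S_obs)
    _, logdet_obs = np.linalg.slogdet(S_obs)
    fmin = float(np.sum(np.log(d)) - logdet_obs)
    chi2_b = (N - 1) * fmin
    df_b = p * (p - 1) // 2
    return chi2_b, df_b


def fit_indices(
    chi2: float,
    df: int,
    baseline_chi2: float,
    baseline_df: int,
    N: int,
    S_obs: np.ndarray | None = None,
    sigma_hat: np.ndarray | None = None,
):
    """CFI, TLI, RMSEA and (if matrices supplied) SRMR.

    TLI and RMSEA are undefined at df = 0 and returned as None.
    """
    d = max(chi2 - df, 0.0)
    d_b = max(baseline_chi2 - baseline_df, 0.0)
    cfi = 1.0 - (d / max(d_b, d, np.finfo(float).tiny)) if max(d_b, d) > 0 else 1.0
    if df > 0 and baseline_df > 0:
        denom = baseline_chi2 / baseline_df - 1.0
        tli = (baseline_chi2 / baseline_df - chi2 / df) / denom if denom != 0 else None
        rmsea = float(np.sqrt(d / (df * (N - 1))))
    else:
        tli = None
        rmsea = None
    srmr = np.nan
    if S_obs is not None and sigma_hat is not None:
        p = S_obs.shape[0]
        resid = S_obs - sigma_hat
        tri = resid[np.tril_indices(p)]
        srmr = float(np.sqrt(np.mean(tri**2)))
    return cfi, tli, rmsea, srmr


def _expected_information(spec, theta, sigma_inv, N):
    """Expected Fisher information of theta, via finite-difference dSigma."""
    n = theta.size
    eps = 1e-6
    derivs = []
    for i in range(n):
        tp = theta.copy()
        tp[i] += eps
        tm = theta.copy()
        tm[i] -= eps
        derivs.append((implied_matrix(spec, tp) - implied_matrix(spec, tm)) / (2 * eps))
    info = np.empty((n, n))
    for i in range(n):
        wi = sigma_inv @ derivs[i]
        for j in range(i, n):
            info[i, j] = info[j, i] = 0.5 * (N - 1) * np.trace(wi @ sigma_inv @ derivs[j])
    return info


def fit_ml(
    S_obs: np.ndarray,
    spec: SemModelSpec,
    N: int,
    n_restarts: int = 4,
    seed: int = 0,
    compute_se: bool = True,
) -> SemFit:
    """Fit the model to a correlation (standardized covariance) matrix.

    ``N`` is the effective sample size (e.g. the median of per-pair total
    Ns from Stage 1); it scales chi2 and the standard errors but not the
    estimates.  Multi-start L-BFGS-B; residual variances bounded at zero
    and flagged as Heywood when they land on the bound.
    """
    S_obs = np.asarray(S_obs, dtype=float)
    p = len(spec.observed)
    if S_obs.shape != (p, p):
        raise SemError(f"input matrix is {S_obs.shape}, model expects ({p}, {p})")
    if np.linalg.eigvalsh(S_obs).min() < -1e-10:
        raise SemError("input matrix is not positive semidefinite")

    # standardized coefficients: generous box keeps the line search from
    # overflowing on the non-PD penalty plateau
    n_struct = len(spec.loadings) + len(spec.paths)
    bounds = [(-10.0, 10.0)] * n_struct + [(0.0, 10.0)] * p
    rng = np.random.default_rng(seed)
    best = None
    converged = False
    for restart in range(n_restarts + 1):
        x0 = _start_values(spec, rng, jitter=0.0 if restart == 0 else 0.25)
        res = optimize.minimize(
            _fml_and_grad,
            x0=x0,
            args=(spec, S_obs),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 5000, "maxls": 60},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        converged = converged or bool(res.success)
        if restart == 0 and res.success and res.fun < 1e-12:
            break  # perfect fit from the default start

    # polish from the best point: ill-conditioned inputs leave a narrow
    # valley that benefits from a second pass with tighter tolerances
    polish = optimize.minimize(
        _fml_and_grad,
        x0=best.x,
        args=(spec, S_obs),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"ftol": 1e-16, "gtol": 1e-12, "maxiter": 5000, "maxls": 100},
    )
    if polish.fun <= best.fun:
        best = polish
        converged = converged or bool(polish.success)

    theta = best.x
    fmin = max(float(best.fun), 0.0)
    sigma_hat = implied_matrix(spec, theta)
    chi2 = (N - 1) * fmin
    df = spec.df
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan
    chi2_b, df_b = baseline_fit(S_obs, N)
    cfi, tli, rmsea, srmr = fit_indices(chi2, df, chi2_b, df_b, N, S_obs, sigma_hat)

    resid_block = theta[n_struct:]
    heywood = tuple(
        v for v, th in zip(spec.observed, resid_block) if th <= 1e-10
    )

    se: dict[str, float] = {}
    if compute_se:
        try:
            sigma_inv = np.linalg.inv(sigma_hat)
            info = _expected_information(spec, theta, sigma_inv, N)
            cov = np.linalg.pinv(info)
            se_vec = np.sqrt(np.clip(np.diag(cov), 0, None))
            se = dict(zip(spec.param_names, se_vec.tolist()))
        except np.linalg.LinAlgError:
            se = {}

    return SemFit(
        spec=spec,
        estimates=dict(zip(spec.param_names, theta.tolist())),
        se=se,
        fmin=fmin,
        chi2=float(chi2),
        df=df,
        p_value=p_value,
        baseline_chi2=float(chi2_b),
        baseline_df=df_b,
        cfi=float(cfi),
        tli=tli,
        rmsea=rmsea,
        srmr=srmr,
        N_used=int(N),
        converged=converged,
        heywood=heywood,
        implied=sigma_hat,
    )


def compare_nested(fit_full: SemFit, fit_restricted: SemFit):
    """Likelihood-ratio comparison of nested fits: dchi2, ddf, p.

    The restricted model's free parameters must be a subset of the full
    model's (same observed variables).
    """
    full_names = set(fit_full.spec.param_names)
    restr_names = set(fit_restricted.spec.param_names)
    if not restr_names <= full_names or fit_full.spec.observed != fit_restricted.spec.observed:
        raise SemError("models are not nested")
    d_chi2 = fit_restricted.chi2 - fit_full.chi2
    d_df = fit_restricted.df - fit_full.df
    p = float(stats.chi2.sf(max(d_chi2, 0.0), d_df)) if d_df > 0 else np.nan
    return d_chi2, d_df, p
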