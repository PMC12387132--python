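"""Stage 1: three-level random-effects pooling of Fisher-z correlations.

Each construct pair is meta-analyzed separately.  The model for the
Fisher-transformed correlation i in matrix (cluster) j is

    z_ij = mu + u_j + e_ij + eps_ij,

with u_j ~ N(0, tau2_between) the matrix-level random effect (correlations
from the same matrix share the same examinees), e_ij ~ N(0, tau2_within)
the correlation-level random effect, and eps_ij ~ N(0, v_ij) the known
sampling error with v_ij = 1/(N_ij - 3).  mu and the two variance
components are estimated by restricted maximum likelihood; the marginal
covariance of each cluster is compound-symmetric plus a known diagonal, so
the likelihood is evaluated with rank-one (Woodbury) updates.

Heterogeneity is summarized by Cochran's Q under fixed-effect inverse
variance weights and I2 = max(0, (Q - df)/Q).  Pooled estimates are
back-transformed to Pearson r for reporting and assembled into the 13x13
meta-analytic matrix with unit diagonal; if pooling leaves the matrix
indefinite it is projected to the nearest correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.correlation_tools import corr_nearest

from readsem.consensus import CONSTRUCTS
from readsem.corr_db import CorrelationRecord


class MetaPoolError(ValueError):
    pass


def fisher_z(r):
    """Fisher z-transform, z = arctanh(r).  Requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise MetaPoolError("Fisher z requires |r| < 1")
    return np.arctanh(r)


def inv_fisher(z):
    """Inverse Fisher transform, r = tanh(z)."""
    return np.tanh(np.asarray(z, dtype=float))


def sampling_variance(N):
    """Sampling variance of a Fisher-z correlation, v = 1/(N - 3)."""
    N = np.asarray(N, dtype=float)
    if np.any(N < 4):
        raise MetaPoolError("sampling variance requires N >= 4")
    return 1.0 / (N - 3.0)


@dataclass
class MetaCorrelation:
    """Pooled result for one construct pair."""

    pair: tuple[str, str]
    k: int
    m: int
    total_N: int
    mu_z: float
    se_mu: float
    tau2_between: float
    tau2_within: float
    Q: float
    df_Q: int
    p_Q: float
    I2: float
    r_pooled: float
    ci95_r: tuple[float, float]
    converged: bool = True
    tau2_estimable: bool = True


@dataclass
class MetaMatrix:
    """Assembled pooled correlation matrix over the 13 constructs."""

    labels: tuple[str, ...]
    R: np.ndarray
    pair_N: np.ndarray
    overall_N: int
    psd_repaired: bool
    min_eigenvalue_before: float
    pooled: dict[tuple[str, str], MetaCorrelation] = field(default_factory=dict)


def _cluster_stats(z, v, cluster_index, n_clusters, tau2_b, tau2_w):
    """Per-cluster restricted-likelihood building blocks via Woodbury.

    With d_i = v_i + tau2_w and V_j = diag(d) + tau2_b * 11', returns the
    summed log|V_j|, and per-cluster a_j = 1'V_j^-1 1, b_j = 1'V_j^-1 z,
    c_j = z'V_j^-1 z.
    """
    d = v + tau2_w
    inv_d = 1.0 / d
    a0 = np.bincount(cluster_index, weights=inv_d, minlength=n_clusters)
    b0 = np.bincount(cluster_index, weights=z * inv_d, minlength=n_clusters)
    c0 = np.bincount(cluster_index, weights=z * z * inv_d, minlength=n_clusters)
    s = 1.0 + tau2_b * a0
    logdet = float(np.sum(np.log(d)) + np.sum(np.log(s)))
    a = a0 / s
    b = b0 / s
    c = c0 - tau2_b * b0 * b0 / s
    return logdet, a, b, c


def _neg_restricted_ll(theta, z, v, cluster_index, n_clusters):
    tau2_b, tau2_w = max(theta[0], 0.0), max(theta[1], 0.0)
    logdet, a, b, c = _cluster_stats(z, v, cluster_index, n_clusters, tau2_b, tau2_w)
    W = a.sum()
    mu = b.sum() / W
    quad = c.sum() - 2.0 * mu * b.sum() + mu * mu * a.sum()
    return 0.5 * (logdet + np.log(W) + quad)


def _records_to_arrays(records):
    z = fisher_z(np.array([rec.r for rec in records]))
    v = sampling_variance(np.array([rec.N for rec in records]))
    matrix_ids = [rec.matrix_id for rec in records]
    uniq, cluster_index = np.unique(matrix_ids, return_inverse=True)
    return z, v, cluster_index, len(uniq)


def _total_n(records) -> int:
    # each matrix's examinees counted once per pair, however many subtest
    # pairs it contributes
    per_matrix: dict[str, int] = {}
    for rec in records:
        per_matrix[rec.matrix_id] = max(per_matrix.get(rec.matrix_id, 0), rec.N)
    return int(sum(per_matrix.values()))


def heterogeneity(records: list[CorrelationRecord]):
    """Cochran's Q with fixed-effect inverse-variance weights, df, p, I2.

    I2 = max(0, (Q - df)/Q), the proportion of variability attributable to
    true heterogeneity rather than sampling error.  Requires k >= 2.
    """
    if len(records) < 2:
        raise MetaPoolError("heterogeneity requires at least 2 correlations")
    z, v, _, _ = _records_to_arrays(records)
    w = 1.0 / v
    zbar = np.sum(w * z) / np.sum(w)
    Q = float(np.sum(w * (z - zbar) ** 2))
    df = len(z) - 1
    p = float(stats.chi2.sf(Q, df))
    I2 = max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    return Q, df, p, I2


def fit_three_level(
    records: list[CorrelationRecord],
    pair: tuple[str, str] | None = None,
    n_restarts: int = 4,
    seed: int = 0,
) -> MetaCorrelation:
    """REML fit of the three-level model to one construct pair's records.

    Variance components are bounded below by zero; the optimizer starts
    from method-of-moments values plus seeded random restarts and keeps
    the best restricted likelihood.  With a single correlation the pooled
    mean is that correlation, its SE the sampling SE, and the variance
    components are reported as zero with ``tau2_estimable=False``.
    """
    if not records:
        raise MetaPoolError("no records for pair")
    if pair is None:
        pair = records[0].bucket or ("?", "?")
    k = len(records)
    z, v, cluster_index, m = _records_to_arrays(records)
    total_N = _total_n(records)

    if k == 1:
        mu = float(z[0])
        se = float(np.sqrt(v[0]))
        lo, hi = mu - 1.959963984540054 * se, mu + 1.959963984540054 * se
        return MetaCorrelation(
            pair=pair, k=1, m=1, total_N=total_N, mu_z=mu, se_mu=se,
            tau2_between=0.0, tau2_within=0.0, Q=np.nan, df_Q=0, p_Q=np.nan,
            I2=np.nan, r_pooled=float(inv_fisher(mu)),
            ci95_r=(float(inv_fisher(lo)), float(inv_fisher(hi))),
            converged=True, tau2_estimable=False,
        )

    # method-of-moments style starting value: excess dispersion split evenly
    w = 1.0 / v
    zbar = np.sum(w * z) / np.sum(w)
    excess = max(np.sum(w * (z - zbar) ** 2) - (k - 1), 0.0) / max(np.sum(w), 1.0)
    rng = np.random.default_rng(seed)
    starts = [(excess / 2, excess / 2), (0.0, 0.0)]
    scale = max(excess, 0.01)
    for _ in range(n_restarts):
        starts.append(tuple(rng.uniform(0, 2 * scale, size=2)))

    best = None
    converged = False
    for start in starts:
        res = optimize.minimize(
            _neg_restricted_ll,
            x0=np.asarray(start, dtype=float),
            args=(z, v, cluster_index, m),
            method="L-BFGS-B",
            bounds=[(0.0, None), (0.0, None)],
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        converged = converged or bool(res.success)

    tau2_b, tau2_w = float(best.x[0]), float(best.x[1])
    logdet, a, b, c = _cluster_stats(z, v, cluster_index, m, tau2_b, tau2_w)
    W = a.sum()
    mu = float(b.sum() / W)
    se = float(1.0 / np.sqrt(W))
    crit = 1.959963984540054
    lo, hi = mu - crit * se, mu + crit * se
    Q, df, p, I2 = heterogeneity(records)
    return MetaCorrelation(
        pair=pair, k=k, m=m, total_N=total_N, mu_z=mu, se_mu=se,
        tau2_between=tau2_b, tau2_within=tau2_w,
        Q=Q, df_Q=df, p_Q=p, I2=I2,
        r_pooled=float(inv_fisher(mu)),
        ci95_r=(float(inv_fisher(lo)), float(inv_fisher(hi))),
        converged=converged, tau2_estimable=True,
    )


def pool_pairs(
    records: list[CorrelationRecord], seed: int = 0
) -> dict[tuple[str, str], MetaCorrelation]:
    """Group bucketed records by construct pair and pool each pair."""
    groups: dict[tuple[str, str], list[CorrelationRecord]] = {}
    for rec in records:
        if rec.bucket is None:
            raise MetaPoolError("records must be bucketed before pooling")
        groups.setdefault(rec.bucket, []).append(rec)
    return {
        pair: fit_three_level(recs, pair=pair, seed=seed)
        for pair, recs in sorted(groups.items())
    }


def assemble_meta_matrix(
    pooled: dict[tuple[str, str], MetaCorrelation],
    labels: tuple[str, ...] = CONSTRUCTS,
    psd_repair: bool = True,
) -> MetaMatrix:
    """Assemble the pooled correlation matrix with unit diagonal.

    Requires a pooled estimate for every off-diagonal construct pair.  The
    overall sample size is the median of the per-pair total Ns.  If the
    assembled matrix has a negative eigenvalue it is projected to the
    nearest correlation matrix (flagged in the result).
    """
    p = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    missing = []
    R = np.eye(p)
    pair_N = np.zeros((p, p))
    totals = []
    for i in range(p):
        for j in range(i + 1, p):
            key = tuple(sorted((labels[i], labels[j])))
            mc = pooled.get(key)
            if mc is None:
                missing.append(key)
                continue
            R[i, j] = R[j, i] = mc.r_pooled
            pair_N[i, j] = pair_N[j, i] = mc.total_N
            totals.append(mc.total_N)
    if missing:
        raise MetaPoolError(
            "missing pooled estimates for pairs: "
            + ", ".join("-".join(k) for k in missing)
        )
    overall_N = int(round(float(np.median(totals))))
    min_eig = float(np.linalg.eigvalsh(R).min())
    repaired = False
    if min_eig < 0 and psd_repair:
        R = np.asarray(corr_nearest(R, threshold=1e-12))
        R = (R + R.T) / 2.0
        np.fill_diagonal(R, 1.0)
        repaired = True
    return MetaMatrix(
        labels=tuple(labels), R=R, pair_N=pair_N, overall_N=overall_N,
        psd_repaired=repaired, min_eigenvalue_before=min_eig, pooled=dict(pooled),
    )


def heterogeneity_table(pooled: dict[tuple[str, str], MetaCorrelation]) -> pd.DataFrame:
    """Long-format summary of every pooled pair (one row per pair)."""
    rows = []
    for pair, mc in sorted(pooled.items()):
        rows.append(
            {
                "pair": "-".join(pair),
                "k": mc.k,
                "m": mc.m,
                "total_N": mc.total_N,
                "mu_z": mc.mu_z,
                "se": mc.se_mu,
                "tau2_between": mc.tau2_between,
                "tau2_within": mc.tau2_within,
                "Q": mc.Q,
                "df": mc.df_Q,
                "p": mc.p_Q,
                "I2": mc.I2,
                "r": mc.r_pooled,
                "ci_lo": mc.ci95_r[0],
                "ci_hi": mc.ci95_r[1],
            }
        )
    return pd.DataFrame(rows)


def meta_matrix_frame(mm: MetaMatrix) -> pd.DataFrame:
    return pd.DataFrame(mm.R, index=list(mm.labels), columns=list(mm.labels))
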