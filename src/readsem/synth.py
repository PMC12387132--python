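"""Synthetic correlation-database generator and recovery experiments.

The real input to the pipeline is a proprietary database of subtest-level
correlations extracted from test-battery technical manuals.  This module
emulates its statistical structure so the full Stage-1 -> Stage-2 pipeline
can be validated by parameter recovery: many correlation matrices
(clusters) each contributing several subtest-pair correlations, per-matrix
sample sizes spanning roughly 18-2901, incomplete coverage of the 13x13
construct grid, and between/within-matrix heterogeneity on the Fisher-z
scale.

Two sampling modes:

``independent_z``
    Per matrix j a cluster shift u_j ~ N(0, tau2_between) on the z scale;
    per subtest-pair record an additional e ~ N(0, tau2_within); observed
    z ~ N(z_pop + u_j + e, 1/(N_j - 3)).  Mirrors exactly the three-level
    model that Stage 1 assumes; joint positive-definiteness across pairs
    within a matrix is not enforced (pair-wise pooling never uses it).

``wishart``
    Per matrix the population matrix over the constructs present is
    perturbed on the z scale, repaired to the nearest correlation matrix,
    and a sample correlation matrix is drawn at N_j; every simulated
    matrix is then internally consistent (PSD).

The generator defaults are the study conditions the pipeline is meant to
face: the reference loadings/paths as the population model, tau2_between =
0.02 and tau2_within = 0.01 (which at typical per-matrix sample sizes put
I2 near 0.9), log-uniform N in [18, 2901], and roughly half the constructs
observed per matrix with 1-3 subtests each.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.correlation_tools import corr_nearest

from readsem import corr_db, effects, meta_pool, sem_engine
from readsem.consensus import (
    BROAD_ABILITIES,
    CONSTRUCTS,
    READING_SKILLS,
    reference_b_matrix,
    reference_lambda,
)
from readsem.corr_db import CorrelationRecord


class SynthError(ValueError):
    pass


def population_sigma(lam: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Model-implied 13x13 population correlation matrix.

    ``lam`` holds the eight g-loadings (broads order), ``B`` the 13x13
    direct-path matrix.  Residual variances are solved so every construct
    has unit total variance; parameters implying an explained variance
    above 1 are inadmissible.
    """
    lam = np.asarray(lam, dtype=float)
    B = np.asarray(B, dtype=float)
    n = len(CONSTRUCTS)
    if lam.shape != (len(BROAD_ABILITIES),) or B.shape != (n, n):
        raise SynthError("parameter dimensions do not match the construct set")
    lam_map = dict(zip(BROAD_ABILITIES, lam))
    C = effects._implied_correlations(CONSTRUCTS, lam_map, B)
    # admissibility: each endogenous equation's explained variance <= 1
    for i in range(n):
        beta = B[i]
        if np.any(beta):
            preds = np.nonzero(beta)[0]
            expl = float(beta[preds] @ C[np.ix_(preds, preds)] @ beta[preds])
            if expl > 1.0 + 1e-10:
                raise SynthError(
                    f"inadmissible parameters: explained variance "
                    f"{expl:.3f} > 1 for {CONSTRUCTS[i]}"
                )
    for b, l in lam_map.items():
        if abs(l) > 1:
            raise SynthError(f"inadmissible loading |{l}| > 1 for {b}")
    return C


@dataclass
class SynthConfig:
    """Generator configuration; the seed fully determines the output."""

    lam: np.ndarray = field(default_factory=reference_lambda)
    B: np.ndarray = field(default_factory=reference_b_matrix)
    tau2_between: float = 0.02
    tau2_within: float = 0.01
    n_matrices: int = 300
    max_subtests_per_construct: int = 3
    N_range: tuple[int, int] = (18, 2901)
    coverage: float = 0.5
    within_construct_r: float = 0.65
    poor_indicator_rate: float = 0.05
    clinical_rate: float = 0.03
    cross_version_rate: float = 0.01
    mode: str = "independent_z"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in {"independent_z", "wishart"}:
            raise SynthError(f"unknown mode {self.mode!r}")
        if self.tau2_between < 0 or self.tau2_within < 0:
            raise SynthError("variance parameters must be >= 0")
        if not (0 < self.coverage <= 1):
            raise SynthError("coverage must be in (0, 1]")
        if self.n_matrices < 1:
            raise SynthError("need at least one matrix")


@dataclass
class SynthTruth:
    """Generating values stored alongside a simulated database."""

    sigma: np.ndarray
    lam: np.ndarray
    B: np.ndarray
    tau2_between: float
    tau2_within: float
    config: SynthConfig

    def population_r(self, pair: tuple[str, str]) -> float:
        idx = {c: i for i, c in enumerate(CONSTRUCTS)}
        a, b = pair
        if a == b:
            return self.config.within_construct_r
        return float(self.sigma[idx[a], idx[b]])


def _matrix_layout(rng: np.random.Generator, cfg: SynthConfig):
    """Constructs present in one matrix and subtest counts per construct."""
    present = rng.random(len(CONSTRUCTS)) < cfg.coverage
    counts = np.zeros(len(CONSTRUCTS), dtype=int)
    counts[present] = rng.integers(1, cfg.max_subtests_per_construct + 1,
                                   size=int(present.sum()))
    if counts.sum() < 2:  # force at least one correlation
        ids = rng.choice(len(CONSTRUCTS), size=2, replace=False)
        counts[ids] = np.maximum(counts[ids], 1)
    return counts


def _z_pop(cfg: SynthConfig, sigma: np.ndarray, i: int, j: int) -> float:
    if i == j:
        return float(np.arctanh(cfg.within_construct_r))
    return float(np.arctanh(sigma[i, j]))


def simulate_database(
    cfg: SynthConfig,
) -> tuple[corr_db.CorrelationDatabase, SynthTruth]:
    """Simulate a full correlation database under the configured model.

    Each matrix gets its own deterministic substream derived from the
    master seed, so changing ``n_matrices`` never reshuffles earlier
    matrices.  A small fraction of matrices are marked clinical, a small
    fraction of subtests poor indicators, and a small fraction of records
    flagged as same-subtest cross-version pairs, so the inclusion filters
    have work to do; those contaminated records carry the same generating
    values and their removal is neutral to the truth.
    """
    sigma = population_sigma(cfg.lam, cfg.B)
    truth = SynthTruth(
        sigma=sigma, lam=np.asarray(cfg.lam, float), B=np.asarray(cfg.B, float),
        tau2_between=cfg.tau2_between, tau2_within=cfg.tau2_within, config=cfg,
    )
    master = np.random.SeedSequence(cfg.seed)
    matrix_seeds = master.spawn(cfg.n_matrices)

    records: list[CorrelationRecord] = []
    classifications: dict[str, corr_db.SubtestClassification] = {}
    matrices: dict[str, corr_db.MatrixMeta] = {}

    log_lo, log_hi = np.log(cfg.N_range[0]), np.log(cfg.N_range[1])
    for j in range(cfg.n_matrices):
        rng = np.random.default_rng(matrix_seeds[j])
        matrix_id = f"m{j:04d}"
        battery = f"battery{j:04d}"
        N_j = int(round(np.exp(rng.uniform(log_lo, log_hi))))
        clinical = rng.random() < cfg.clinical_rate
        matrices[matrix_id] = corr_db.MatrixMeta(
            matrix_id=matrix_id,
            battery=battery,
            sample_kind="clinical" if clinical else
            ("concurrent_validity" if rng.random() < 0.2 else "normative"),
            group_label=f"group{j % 6}",
            default_N=N_j,
        )
        counts = _matrix_layout(rng, cfg)
        subtests: list[tuple[str, int]] = []  # (subtest_id, construct index)
        for ci, count in enumerate(counts):
            for s in range(count):
                sid = f"{battery}_{CONSTRUCTS[ci]}_{s}"
                quality = "poor" if rng.random() < cfg.poor_indicator_rate else "good"
                classifications[sid] = corr_db.SubtestClassification(
                    subtest_id=sid, battery=battery,
                    broad_code=CONSTRUCTS[ci], narrow_code=CONSTRUCTS[ci],
                    indicator_quality=quality,
                )
                subtests.append((sid, ci))

        if cfg.mode == "independent_z":
            u_j = rng.normal(0.0, np.sqrt(cfg.tau2_between))
            sd_obs = 1.0 / np.sqrt(N_j - 3)
            for a in range(len(subtests)):
                for b in range(a + 1, len(subtests)):
                    sid_a, ci_a = subtests[a]
                    sid_b, ci_b = subtests[b]
                    z_true = (
                        _z_pop(cfg, sigma, ci_a, ci_b)
                        + u_j
                        + rng.normal(0.0, np.sqrt(cfg.tau2_within))
                    )
                    z_obs = rng.normal(z_true, sd_obs)
                    records.append(
                        CorrelationRecord(
                            matrix_id=matrix_id,
                            subtest_a=sid_a, subtest_b=sid_b,
                            N=N_j, r=float(np.tanh(z_obs)),
                            same_subtest_cross_version=(
                                rng.random() < cfg.cross_version_rate
                            ),
                        )
                    )
        else:  # wishart mode: internally consistent sample matrices
            ns = len(subtests)
            pop = np.eye(ns)
            u_j = rng.normal(0.0, np.sqrt(cfg.tau2_between))
            for a in range(ns):
                for b in range(a + 1, ns):
                    z = (
                        _z_pop(cfg, sigma, subtests[a][1], subtests[b][1])
                        + u_j
                        + rng.normal(0.0, np.sqrt(cfg.tau2_within))
                    )
                    pop[a, b] = pop[b, a] = np.tanh(z)
            if np.linalg.eigvalsh(pop).min() < 1e-8:
                pop = np.asarray(corr_nearest(pop, threshold=1e-7))
                np.fill_diagonal(pop, 1.0)
            L = np.linalg.cholesky(pop + 1e-12 * np.eye(ns))
            X = rng.standard_normal((N_j, ns)) @ L.T
            samp = np.corrcoef(X, rowvar=False)
            for a in range(ns):
                for b in range(a + 1, ns):
                    r = float(np.clip(samp[a, b], -0.9999, 0.9999))
                    records.append(
                        CorrelationRecord(
                            matrix_id=matrix_id,
                            subtest_a=subtests[a][0], subtest_b=subtests[b][0],
                            N=N_j, r=r,
                            same_subtest_cross_version=(
                                rng.random() < cfg.cross_version_rate
                            ),
                        )
                    )

    if not records:
        raise SynthError("configuration produced no records")
    return corr_db.CorrelationDatabase(records, classifications, matrices), truth


def write_database(
    db: corr_db.CorrelationDatabase, truth: SynthTruth, outdir: str | Path
) -> None:
    """Emit the three CSV schemas that corr_db reads, plus a truth JSON."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "matrix_id": r.matrix_id,
                "subtest_a": r.subtest_a,
                "subtest_b": r.subtest_b,
                "n": r.N,
                "r": r.r,
                "same_subtest_cross_version": r.same_subtest_cross_version,
            }
            for r in db.records
        ]
    ).to_csv(outdir / "records.csv", index=False)
    pd.DataFrame(
        [
            {
                "subtest_id": c.subtest_id,
                "battery": c.battery,
                "broad": c.broad_code,
                "narrow": c.narrow_code,
                "quality": c.indicator_quality,
            }
            for c in db.classifications.values()
        ]
    ).to_csv(outdir / "classifications.csv", index=False)
    pd.DataFrame(
        [
            {
                "matrix_id": m.matrix_id,
                "battery": m.battery,
                "sample_kind": m.sample_kind,
                "group_label": m.group_label,
                "default_n": m.default_N,
                "supersedes_matrix_ids": ";".join(m.supersedes_matrix_ids),
            }
            for m in db.matrices.values()
        ]
    ).to_csv(outdir / "matrices.csv", index=False)
    (outdir / "truth.json").write_text(
        json.dumps(
            {
                "lambda": truth.lam.tolist(),
                "B": truth.B.tolist(),
                "sigma": truth.sigma.tolist(),
                "tau2_between": truth.tau2_between,
                "tau2_within": truth.tau2_within,
                "seed": truth.config.seed,
            },
            indent=1,
        )
    )


def run_pipeline(
    db: corr_db.CorrelationDatabase,
    gv_paths: bool = False,
    seed: int = 0,
    compute_se: bool = False,
):
    """corr_db -> meta_pool -> sem_engine -> effects on one database."""
    kept, _ = corr_db.apply_inclusion_filters(db)
    bucketed, _ = corr_db.bucket_pairs(kept, db.classifications)
    pooled = meta_pool.pool_pairs(bucketed, seed=seed)
    off_diag = {p: mc for p, mc in pooled.items() if p[0] != p[1]}
    mm = meta_pool.assemble_meta_matrix(off_diag)
    spec = sem_engine.default_model_spec(gv_paths=gv_paths)
    fit = sem_engine.fit_ml(mm.R, spec, N=mm.overall_N, seed=seed,
                            compute_se=compute_se)
    table = effects.effects_from_fit(fit)
    return mm, fit, table


@dataclass
class RecoveryReport:
    """Bias / RMSE of pipeline estimates against generating values."""

    replicates: int
    n_failed: int
    pooled_r_bias: pd.Series
    pooled_r_rmse: pd.Series
    tau2_between_mean: float
    tau2_within_mean: float
    loading_bias: pd.Series
    loading_rmse: pd.Series
    path_bias: pd.Series
    path_rmse: pd.Series

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            ("pooled_r |bias| (max over pairs)", float(self.pooled_r_bias.abs().max())),
            ("pooled_r RMSE (max over pairs)", float(self.pooled_r_rmse.max())),
            ("tau2_between mean estimate", self.tau2_between_mean),
            ("tau2_within mean estimate", self.tau2_within_mean),
            ("loading |bias| (max)", float(self.loading_bias.abs().max())),
            ("loading RMSE (max)", float(self.loading_rmse.max())),
            ("path |bias| (max)", float(self.path_bias.abs().max())),
            ("path RMSE (max)", float(self.path_rmse.max())),
        ]
        return pd.DataFrame(rows, columns=["quantity", "value"])


def recovery_experiment(cfg: SynthConfig, replicates: int = 50) -> RecoveryReport:
    """Simulate, run the full pipeline, and score recovery per replicate.

    Stage failures in a replicate are recorded, not fatal.  Pooled-r bias
    and RMSE are reported per off-diagonal construct pair; loadings and
    structural paths against the generating values.
    """
    rep_seeds = np.random.SeedSequence(cfg.seed).spawn(replicates)
    pairs = [
        (CONSTRUCTS[i], CONSTRUCTS[j])
        for i in range(len(CONSTRUCTS))
        for j in range(i + 1, len(CONSTRUCTS))
    ]
    idx = {c: i for i, c in enumerate(CONSTRUCTS)}
    lam_truth = dict(zip(BROAD_ABILITIES, np.asarray(cfg.lam, float)))
    B_truth = np.asarray(cfg.B, float)

    r_err: dict[tuple[str, str], list[float]] = {p: [] for p in pairs}
    tau_b, tau_w = [], []
    lam_err: dict[str, list[float]] = {b: [] for b in BROAD_ABILITIES}
    path_err: dict[tuple[str, str], list[float]] = {}
    n_failed = 0

    for rep, seq in enumerate(rep_seeds):
        rep_cfg = SynthConfig(
            **{**cfg.__dict__, "seed": int(seq.generate_state(1)[0] % (2**31))}
        )
        try:
            db, truth = simulate_database(rep_cfg)
            mm, fit, _ = run_pipeline(db, gv_paths=False, seed=rep_cfg.seed)
        except Exception:
            n_failed += 1
            continue
        for p in pairs:
            est = mm.R[idx[p[0]], idx[p[1]]]
            r_err[p].append(est - truth.population_r(p))
        mcs = [mc for mc in mm.pooled.values() if mc.tau2_estimable]
        tau_b.append(float(np.mean([mc.tau2_between for mc in mcs])))
        tau_w.append(float(np.mean([mc.tau2_within for mc in mcs])))
        for b, est in fit.loadings.items():
            lam_err[b].append(est - lam_truth[b])
        for (src, dst), est in fit.path_coefficients.items():
            path_err.setdefault((src, dst), []).append(
                est - B_truth[idx[dst], idx[src]]
            )

    def series(err_map, fmt=lambda k: k):
        keys = sorted(err_map)
        bias = pd.Series({fmt(k): float(np.mean(err_map[k])) for k in keys if err_map[k]})
        rmse = pd.Series(
            {fmt(k): float(np.sqrt(np.mean(np.square(err_map[k])))) for k in keys if err_map[k]}
        )
        return bias, rmse

    join = lambda k: "-".join(k) if isinstance(k, tuple) else k
    r_bias, r_rmse = series(r_err, join)
    l_bias, l_rmse = series(lam_err)
    p_bias, p_rmse = series(path_err, join)
    return RecoveryReport(
        replicates=replicates,
        n_failed=n_failed,
        pooled_r_bias=r_bias,
        pooled_r_rmse=r_rmse,
        tau2_between_mean=float(np.mean(tau_b)) if tau_b else np.nan,
        tau2_within_mean=float(np.mean(tau_w)) if tau_w else np.nan,
        loading_bias=l_bias,
        loading_rmse=l_rmse,
        path_bias=p_bias,
        path_rmse=p_rmse,
    )
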