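"""Direct / indirect / total effect decomposition, R2, and effect bands.

For an acyclic standardized path matrix B (``B[i, j]`` = direct path
j -> i) the total-effect matrix is T = (I - B)^-1 - I: entry (i, j) sums
the coefficient products over every directed path j -> ... -> i.  Indirect
effects are T - B, so total = direct + indirect holds exactly.  Latent g
has no direct path to any reading skill; its effect is wholly indirect,
g -> skill = sum_b lambda_b * T[b -> skill].

R2 for an outcome is beta' Phi beta, where beta collects the outcome's
direct predictors' coefficients and Phi is the model-implied correlation
matrix among those predictors; under the model the broad abilities
intercorrelate only through g (corr(b_i, b_j) = lambda_i lambda_j), and
correlations involving upstream reading skills follow recursively from
the structural equations.

Standardized coefficients are graded with Keith's interpretive bands:
|c| < 0.05 negligible, 0.05-0.09 small, 0.10-0.24 moderate, > 0.24 large
(applied to the value rounded half-up to two decimals).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx
import numpy as np
import pandas as pd


class EffectsError(ValueError):
    pass


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero at the given decimals (report convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def band(coefficient: float) -> str:
    """Keith interpretive band for a standardized coefficient (by magnitude)."""
    c = abs(round_half_up(coefficient, 2))
    if c < 0.05:
        return "negligible"
    if c < 0.10:
        return "small"
    if c <= 0.24:
        return "moderate"
    return "large"


def total_effect_matrix(B: np.ndarray) -> np.ndarray:
    """T = (I - B)^-1 - I for acyclic B."""
    B = np.asarray(B, dtype=float)
    n = B.shape[0]
    if _is_cyclic(B):
        raise EffectsError("path matrix is cyclic")
    return np.linalg.solve(np.eye(n) - B, np.eye(n)) - np.eye(n)


def _is_cyclic(B: np.ndarray) -> bool:
    graph = nx.DiGraph()
    graph.add_nodes_from(range(B.shape[0]))
    rows, cols = np.nonzero(B)
    graph.add_edges_from(zip(cols.tolist(), rows.tolist()))
    return not nx.is_directed_acyclic_graph(graph)


def enumerate_paths(
    B: np.ndarray, source: int, target: int
) -> list[tuple[tuple[int, ...], float]]:
    """Every directed path source -> ... -> target with its product.

    Exhaustive DFS over the weighted DAG; the sum of the products equals
    the matrix-algebra total effect T[target, source].  Serves as the
    independent oracle for :func:`total_effect_matrix`.
    """
    B = np.asarray(B, dtype=float)
    if _is_cyclic(B):
        raise EffectsError("path matrix is cyclic")
    out: list[tuple[tuple[int, ...], float]] = []
    children = {j: np.nonzero(B[:, j])[0].tolist() for j in range(B.shape[0])}

    def walk(node: int, path: list[int], product: float) -> None:
        if node == target and len(path) > 1:
            out.append((tuple(path), product))
            return
        for nxt in children[node]:
            walk(nxt, path + [nxt], product * B[nxt, node])

    walk(source, [source], 1.0)
    return out


@dataclass
class EffectsTable:
    """Table-style effect decomposition for the integrated model."""

    predictors: tuple[str, ...]
    outcomes: tuple[str, ...]
    direct: pd.DataFrame
    indirect: pd.DataFrame
    total: pd.DataFrame
    g_indirect: pd.Series
    r2: pd.Series

    def bands(self) -> pd.DataFrame:
        return self.total.map(band)

    def to_frame(self) -> pd.DataFrame:
        """Render the 'direct (indirect, total)' report layout."""
        def cell(p, o):
            d, i, t = (
                self.direct.loc[p, o],
                self.indirect.loc[p, o],
                self.total.loc[p, o],
            )
            if np.isnan(d) and np.isnan(t):
                return "-"
            if abs(i) < 5e-13:  # pure direct effect
                return f"{round_half_up(d):.2f}"
            return (
                f"{round_half_up(d):.2f} ({round_half_up(i):.2f}, "
                f"{round_half_up(t):.2f})"
            )

        body = pd.DataFrame(
            {o: [cell(p, o) for p in self.predictors] for o in self.outcomes},
            index=list(self.predictors),
        )
        body.loc["Indirect Effect of g"] = [
            f"{round_half_up(self.g_indirect[o]):.2f}" for o in self.outcomes
        ]
        body.loc["R2"] = [f"{round_half_up(self.r2[o]):.2f}" for o in self.outcomes]
        return body


def _implied_correlations(
    labels: tuple[str, ...], lam: dict[str, float], B: np.ndarray
) -> np.ndarray:
    """Model-implied correlation matrix among the observed constructs.

    Broad-ability intercorrelations are lambda_i lambda_j; downstream
    variables follow from the structural equations with residual variances
    completing each variable to unit variance.
    """
    n = len(labels)
    order = _topological_order(B)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                C[i, j] = 1.0
            elif labels[i] in lam and labels[j] in lam:
                C[i, j] = lam[labels[i]] * lam[labels[j]]
    for node in order:
        beta = B[node]
        if not np.any(beta):
            continue
        cov = C @ beta  # cov(node, every variable) from the equation
        C[node, :] = cov
        C[:, node] = cov
        C[node, node] = 1.0  # residual completes to unit variance
    return C


def _topological_order(B: np.ndarray) -> list[int]:
    graph = nx.DiGraph()
    graph.add_nodes_from(range(B.shape[0]))
    rows, cols = np.nonzero(B)
    graph.add_edges_from(zip(cols.tolist(), rows.tolist()))
    if not nx.is_directed_acyclic_graph(graph):
        raise EffectsError("path matrix is cyclic")
    return list(nx.topological_sort(graph))


def r_squared(
    outcome: str,
    labels: tuple[str, ...],
    lam: dict[str, float],
    B: np.ndarray,
) -> float:
    """Variance in ``outcome`` explained by its direct predictors.

    beta' Phi beta with Phi the model-implied correlation matrix among the
    predictors.  An outcome with no predictors has R2 = 0.
    """
    idx = {lab: i for i, lab in enumerate(labels)}
    if outcome not in idx:
        raise EffectsError(f"unknown outcome {outcome!r}")
    i = idx[outcome]
    beta = np.asarray(B, dtype=float)[i]
    if not np.any(beta):
        return 0.0
    C = _implied_correlations(tuple(labels), lam, np.asarray(B, dtype=float))
    preds = np.nonzero(beta)[0]
    phi = C[np.ix_(preds, preds)]
    b = beta[preds]
    return float(b @ phi @ b)


def decompose_effects(
    lam: dict[str, float],
    B: np.ndarray,
    labels: tuple[str, ...],
    outcomes: tuple[str, ...],
) -> EffectsTable:
    """Full effect decomposition for the integrated model.

    ``lam`` maps each broad ability to its g-loading; ``B`` is the
    standardized direct-path matrix over ``labels`` (``B[i, j]`` = path
    j -> i); ``outcomes`` selects the report columns (the reading skills).
    """
    B = np.asarray(B, dtype=float)
    labels = tuple(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    T = total_effect_matrix(B)
    indirect = T - B

    def connected(p, o):
        return p != o and (T[idx[o], idx[p]] != 0 or B[idx[o], idx[p]] != 0)

    predictors = tuple(
        lab for lab in labels if any(connected(lab, o) for o in outcomes)
    )

    def frame(M):
        data = {}
        for o in outcomes:
            data[o] = [
                M[idx[o], idx[p]] if connected(p, o) else np.nan
                for p in predictors
            ]
        return pd.DataFrame(data, index=list(predictors))

    direct_df = frame(B)
    indirect_df = frame(indirect)
    total_df = frame(T)

    g_ind = pd.Series(
        {
            o: float(
                sum(lam[b] * T[idx[o], idx[b]] for b in lam if b in idx)
            )
            for o in outcomes
        }
    )
    r2 = pd.Series({o: r_squared(o, labels, lam, B) for o in outcomes})
    return EffectsTable(
        predictors=predictors,
        outcomes=tuple(outcomes),
        direct=direct_df,
        indirect=indirect_df,
        total=total_df,
        g_indirect=g_ind,
        r2=r2,
    )


def effects_from_fit(fit) -> EffectsTable:
    """Decompose a fitted model's standardized solution."""
    from readsem.consensus import READING_SKILLS

    labels = fit.spec.observed
    idx = {v: i for i, v in enumerate(labels)}
    B = np.zeros((len(labels), len(labels)))
    for (src, dst), val in fit.path_coefficients.items():
        B[idx[dst], idx[src]] = val
    return decompose_effects(fit.loadings, B, labels, READING_SKILLS)
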