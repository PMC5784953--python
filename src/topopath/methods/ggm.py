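"""Decomposable Gaussian-graphical-model pathway tests.

The pathway DAG is moralized and triangulated; the resulting clique/separator
sequence supports the closed-form maximum-likelihood estimate of a covariance
matrix constrained to the graph: the concentration matrix is assembled as

.. math:: K = \\sum_C [S_C^{-1}]^0 - \\sum_S [S_S^{-1}]^0

(clique/separator marginal inverses padded with zeros), and
:math:`\\log\\det\\hat\\Sigma = \\sum_C \\log\\det S_C - \\sum_S \\log\\det S_S`.

Both tests proceed in two steps.  Step 1 tests equality of the two groups'
constrained covariances with a likelihood-ratio statistic; step 2 tests mean
equality with a Hotelling-type :math:`T^2` using the pooled constrained
concentration when step 1 accepts, or a Behrens-Fisher variant otherwise.
Both p-values come from sample-label permutation; all permutations are
evaluated in one batched linear-algebra pass.

*TopologyGSA* uses raw MLE covariances and therefore needs more samples per
group than the largest clique.  *Clipper* shrinks off-diagonal covariance
entries toward zero (James-Stein / Schafer-Strimmer intensity), so it remains
applicable when cliques are larger than the sample count.
"""

from __future__ import annotations

import numpy as np

from ..degs import ExpressionDataset
from ..pathways import CliqueDecomposition, PathwayGraph, decompose_to_cliques
from .base import (
    NOT_TESTABLE,
    MethodConfig,
    PathwayResult,
    base_result,
    node_expression,
    permutation_p,
)


def shrinkage_intensity(Xc: np.ndarray) -> float:
    """Schafer-Strimmer shrinkage intensity toward the diagonal target.

    ``Xc`` is row-centered (p x n).  Returns lambda in [0, 1].
    """
    p, n = Xc.shape
    Sn = Xc @ Xc.T
    M2 = (Xc**2) @ (Xc**2).T
    return float(_intensity_from_moments(Sn[None], M2[None], n)[0])


def _intensity_from_moments(Sn: np.ndarray, M2: np.ndarray, n: int) -> np.ndarray:
    """Batched intensity from sums of (squared) centered outer products."""
    b, p, _ = Sn.shape
    if n < 3 or p < 2:
        return np.zeros(b)
    var_s = n / (n - 1.0) ** 3 * (M2 - Sn**2 / n)
    s_unb = Sn / (n - 1.0)
    off = ~np.eye(p, dtype=bool)
    num = var_s[:, off].sum(axis=1)
    den = (s_unb[:, off] ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return np.clip(lam, 0.0, 1.0)


class _DecomposableModel:
    """Pre-indexed clique/separator machinery for one pathway."""

    def __init__(self, decomp: CliqueDecomposition, nodes: list[str]):
        pos = {g: i for i, g in enumerate(nodes)}
        self.p = len(nodes)
        self.cliques = [np.array(sorted(pos[g] for g in c), dtype=int) for c in decomp.cliques]
        self.separators = [
            np.array(sorted(pos[g] for g in s), dtype=int) for s in decomp.separators if s
        ]
        self.max_clique_size = decomp.max_clique_size

    def fit(self, S: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Constrained MLE for a (b, p, p) stack of covariance estimates.

        Returns (K, logdet, ok_mask); entries with a singular clique or
        separator marginal get ok=False.
        """
        b = S.shape[0]
        K = np.zeros_like(S)
        logdet = np.zeros(b)
        ok = np.ones(b, dtype=bool)
        for sign_, idx in [(1.0, i) for i in self.cliques] + [(-1.0, i) for i in self.separators]:
            sub = S[:, idx[:, None], idx[None, :]]
            sgn, ld = np.linalg.slogdet(sub)
            good = sgn > 0
            ok &= good
            sub = np.where(good[:, None, None], sub, np.eye(len(idx))[None])
            inv = np.linalg.inv(sub)
            K[:, idx[:, None], idx[None, :]] += sign_ * inv
            logdet += np.where(good, sign_ * ld, np.nan)
        return K, logdet, ok


def _group_moments(X: np.ndarray, idx: np.ndarray):
    """Per-permutation group moments for a (b, n_g) column-index stack.

    Returns (means (b,p), Sn (b,p,p) sums of centered outer products,
    M2 (b,p,p) sums of squared centered products).
    """
    Xg = X[:, idx]              # (p, b, n_g)
    Xg = np.moveaxis(Xg, 0, 1)  # (b, p, n_g)
    m = Xg.mean(axis=2)
    Xc = Xg - m[:, :, None]
    Sn = Xc @ np.swapaxes(Xc, 1, 2)
    M2 = (Xc**2) @ np.swapaxes(Xc**2, 1, 2)
    return m, Sn, M2


def _apply_shrinkage(S: np.ndarray, lam: np.ndarray) -> np.ndarray:
    out = S * (1.0 - lam[:, None, None])
    diag = np.arange(S.shape[1])
    out[:, diag, diag] = S[:, diag, diag]
    return out


def _run_two_step(
    method: str,
    data: ExpressionDataset,
    graph: PathwayGraph,
    cfg: MethodConfig,
    shrink: float | None,
    require_samples: bool,
) -> PathwayResult:
    measured = set(data.genes)
    common = base_result(method, graph, measured)
    nodes, X = node_expression(data, graph, measured)
    if len(nodes) < 2:
        return PathwayResult(**common, status=NOT_TESTABLE)
    sd = X.std(axis=1)
    if (sd <= 0).any():
        keep = sd > 0
        nodes = [g for g, k in zip(nodes, keep) if k]
        X = X[keep]
        if len(nodes) < 2:
            return PathwayResult(**common, status=NOT_TESTABLE)

    decomp = decompose_to_cliques(graph, set(nodes))
    model = _DecomposableModel(decomp, list(nodes))
    if require_samples and min(data.n1, data.n2) <= model.max_clique_size:
        return PathwayResult(
            **common,
            status=NOT_TESTABLE,
            extras={"max_clique_size": model.max_clique_size},
        )

    idx1 = data.group_columns(1)
    idx2 = data.group_columns(2)
    n1, n2 = len(idx1), len(idx2)
    n = n1 + n2
    rng = cfg.rng()
    n_perm = cfg.n_permutations
    # row 0 = observed labelling, rows 1.. = permutations
    perms = np.empty((n_perm + 1, n), dtype=int)
    perms[0] = np.concatenate([idx1, idx2])
    for b in range(1, n_perm + 1):
        perms[b] = rng.permutation(n)

    m1, Sn1, M21 = _group_moments(X, perms[:, :n1])
    m2, Sn2, M22 = _group_moments(X, perms[:, n1:])
    S1 = Sn1 / n1
    S2 = Sn2 / n2
    Sp = (Sn1 + Sn2) / n
    if shrink is not None:
        if shrink >= 0:
            lam1 = lam2 = lamp = np.full(n_perm + 1, float(shrink))
        else:
            lam1 = _intensity_from_moments(Sn1, M21, n1)
            lam2 = _intensity_from_moments(Sn2, M22, n2)
            lamp = _intensity_from_moments(Sn1 + Sn2, M21 + M22, n)
        S1 = _apply_shrinkage(S1, lam1)
        S2 = _apply_shrinkage(S2, lam2)
        Sp = _apply_shrinkage(Sp, lamp)

    K1, ld1, ok1 = model.fit(S1)
    K2, ld2, ok2 = model.fit(S2)
    Kp, ldp, okp = model.fit(Sp)
    ok = ok1 & ok2 & okp
    if not ok[0]:
        return PathwayResult(**common, status=NOT_TESTABLE)

    lrt = n * ldp - n1 * ld1 - n2 * ld2
    d = m2 - m1
    t2_pooled = (n1 * n2 / n) * np.einsum("bp,bpq,bq->b", d, Kp, d)
    Sig1 = np.linalg.inv(K1)
    Sig2 = np.linalg.inv(K2)
    V = Sig1 / n1 + Sig2 / n2
    t2_bf = np.einsum("bp,bp->b", d, np.linalg.solve(V, d[..., None])[..., 0])
    # singular permutations count as arbitrarily extreme (conservative)
    for arr in (lrt, t2_pooled, t2_bf):
        arr[~ok] = np.inf

    p_var = permutation_p(lrt[1:], float(lrt[0]))
    equal_var = p_var >= cfg.variance_alpha
    stats_arr = t2_pooled if equal_var else t2_bf
    p_mean = permutation_p(stats_arr[1:], float(stats_arr[0]))
    return PathwayResult(
        **common,
        statistic=float(stats_arr[0]),
        p_value=p_mean,
        extras={
            "p_variance": p_var,
            "equal_variance": bool(equal_var),
            "max_clique_size": model.max_clique_size,
            "lrt": float(lrt[0]),
        },
    )


def topology_gsa(
    data: ExpressionDataset,
    graph: PathwayGraph,
    degs=None,
    cfg: MethodConfig | None = None,
) -> PathwayResult:
    """Two-step decomposable-GGM test with raw MLE covariances.

    Not testable unless both groups have more samples than the largest
    clique of the moralized, triangulated pathway graph.
    """
    cfg = cfg or MethodConfig()
    return _run_two_step("topologygsa", data, graph, cfg, shrink=None, require_samples=True)


def clipper(
    data: ExpressionDataset,
    graph: PathwayGraph,
    degs=None,
    cfg: MethodConfig | None = None,
) -> PathwayResult:
    """Two-step decomposable-GGM test with shrinkage covariance estimation."""
    cfg = cfg or MethodConfig()
    if not cfg.clipper_shrinkage:
        shrink: float | None = 0.0
    elif cfg.clipper_shrinkage_intensity is not None:
        shrink = float(cfg.clipper_shrinkage_intensity)
    else:
        shrink = -1.0  # estimate per covariance
    return _run_two_step("clipper", data, graph, cfg, shrink=shrink, require_samples=False)
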