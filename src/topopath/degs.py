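"""Per-gene differential expression: log fold changes and the empirical-Bayes
moderated t-test.

The moderated t-test stabilises per-gene variance estimates by shrinking them
toward a common prior: the gene-wise residual variances :math:`s_g^2` (with
:math:`d_g` degrees of freedom) are modelled as scaled inverse-chi-square
draws around a prior variance :math:`s_0^2` with :math:`d_0` prior degrees of
freedom.  The posterior variance

.. math:: \\tilde s_g^2 = \\frac{d_0 s_0^2 + d_g s_g^2}{d_0 + d_g}

replaces :math:`s_g^2` in the two-sample t statistic, which is then referred
to a t distribution with :math:`d_0 + d_g` degrees of freedom.  The
hyper-parameters are fitted by moment matching on :math:`\\log s_g^2`
(Fisher-log-chi-square moments, trigamma inversion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats


@dataclass
class ExpressionDataset:
    """Log2 expression matrix (genes x samples) with two-group labels."""

    X: np.ndarray
    genes: pd.Index
    samples: pd.Index
    y: np.ndarray  # per-sample group label in {1, 2}

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.genes = pd.Index(self.genes)
        self.samples = pd.Index(self.samples)
        if self.X.shape != (len(self.genes), len(self.samples)):
            raise ValueError("matrix shape does not match gene/sample index")
        if not self.genes.is_unique:
            dup = self.genes[self.genes.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup}")
        if not np.isfinite(self.X).all():
            raise ValueError("expression matrix contains missing/non-finite values")
        if not set(np.unique(self.y)) <= {1, 2}:
            raise ValueError("group labels must be 1 or 2")

    @property
    def n1(self) -> int:
        return int((self.y == 1).sum())

    @property
    def n2(self) -> int:
        return int((self.y == 2).sum())

    def group_columns(self, group: int) -> np.ndarray:
        return np.flatnonzero(self.y == group)

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(self.X.copy(), self.genes, self.samples, self.y.copy())


@dataclass
class DEGResult:
    """Moderated-t result table plus (optionally) a called DEG set."""

    table: pd.DataFrame  # columns: logFC, t, p, constant (bool)
    d0: float
    s0_sq: float
    theta: float | None = None
    deg_set: frozenset = field(default_factory=frozenset)

    @property
    def p_values(self) -> pd.Series:
        return self.table["p"]

    @property
    def logfc(self) -> pd.Series:
        return self.table["logFC"]

    def with_threshold(self, theta: float) -> "DEGResult":
        return call_degs(self, theta)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s_sq: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching fit of (d0, s0^2) from gene-wise variances.

    Works on z = log(s_g^2): E[z] and Var[z] have closed forms in terms of
    digamma/trigamma functions of d_g/2 and d0/2.  Returns d0 = inf when the
    observed spread of log-variances is no larger than expected under a
    single common variance.
    """
    ok = s_sq > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s_sq[ok])) if ok.any() else 1.0
    z = np.log(s_sq[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    n = len(e)
    e_mean = e.mean()
    e_var = np.var(e, ddof=1)
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    else:
        d0 = 2.0 * _trigamma_inverse(float(excess))
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t(data: ExpressionDataset, d0_override: float | None = None) -> DEGResult:
    """Empirical-Bayes moderated two-sample t-test for every gene.

    Parameters
    ----------
    data : ExpressionDataset
    d0_override : float, optional
        Force the prior degrees of freedom (``0`` recovers the ordinary
        pooled t-test; ``inf`` fully pools variances).
    """
    i1 = data.group_columns(1)
    i2 = data.group_columns(2)
    n1, n2 = len(i1), len(i2)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least two samples")
    X1, X2 = data.X[:, i1], data.X[:, i2]
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    logfc = m2 - m1
    df = n1 + n2 - 2
    ss = ((X1 - m1[:, None]) ** 2).sum(axis=1) + ((X2 - m2[:, None]) ** 2).sum(axis=1)
    s_sq = ss / df
    constant = (s_sq <= 1e-300) & (np.abs(logfc) <= 1e-300)

    if d0_override is not None:
        d0 = float(d0_override)
        _, s0_sq = fit_variance_prior(s_sq[~constant], df) if d0 > 0 else (0.0, 1.0)
        if d0 == 0:
            s0_sq = 1.0  # irrelevant: no shrinkage
    else:
        d0, s0_sq = fit_variance_prior(s_sq[~constant], df)

    if np.isinf(d0):
        s_tilde_sq = np.full_like(s_sq, s0_sq)
        df_total = np.inf
    else:
        s_tilde_sq = (d0 * s0_sq + df * s_sq) / (d0 + df)
        df_total = d0 + df

    se = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # all-constant rows are not testable
    t = np.where(constant, 0.0, t)
    p = np.where(constant, 1.0, p)

    table = pd.DataFrame(
        {"logFC": logfc, "t": t, "p": p, "constant": constant}, index=data.genes
    )
    return DEGResult(table=table, d0=float(d0), s0_sq=float(s0_sq))


def call_degs(result: DEGResult, theta: float = 0.05) -> DEGResult:
    """Call differentially expressed genes at the strict threshold p < theta."""
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must lie in (0, 1)")
    degs = frozenset(result.table.index[result.table["p"].to_numpy() < theta])
    return DEGResult(
        table=result.table, d0=result.d0, s0_sq=result.s0_sq, theta=theta, deg_set=degs
    )
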