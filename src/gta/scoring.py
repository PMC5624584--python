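"""Expression scoring and the payoff function of the subnetwork game.

Per gene, a Gaussian density is fitted to each phenotype class and the
per-sample log-likelihood ratio (LLR) between the two classes is taken as
the gene's feature vector:

    LLR_i(x_ij) = ln[ f_i1(x_ij) / f_i2(x_ij) ]

The discriminative strength of gene *i* is the Welch (unequal-variance)
two-sample t-statistic of its LLR values between the two classes,
written t(i) below. On a candidate subnetwork G_s, each player chooses a
strategy s ∈ {join=1, leave=0}; with V_join the joined set and E_join the
edges induced on it, the payoff of player *i* is

    PF(i) = α·t(i) + β·LS(i) + γ·DE(G_join) − δ·(|V_join| − 1)

where LS(i) sums the t-scores of i's joined neighbours (0 for a leaving
player), and DE is the weighted edge density of the joined subgraph,
Σ w(e) / C(|V_join|, 2), shared by every player regardless of strategy.
Defaults α=1.24, β=1, γ=1, δ=2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from gta.errors import GTAError
from gta.io import ExpressionProfile

#: floor on the per-class standard deviation — keeps the LLR of a constant
#: gene finite without perturbing any non-degenerate fit
SD_FLOOR = 1e-6

#: below this variance a class's LLR values are treated as constant
DEGENERATE_VAR = 1e-12


@dataclass(frozen=True)
class PayoffParams:
    """Weights of the payoff function (dimensionless)."""

    alpha: float = 1.24
    beta: float = 1.0
    gamma: float = 1.0
    delta: float = 2.0


@dataclass
class GeneScoreTable:
    """Per-gene LLR vectors (natural-log units) and their Welch t-scores.

    ``llr`` is a genes × samples DataFrame aligned with the profile's
    sample order; ``tscore`` is a Series over the same genes, finite for
    every gene.
    """

    llr: pd.DataFrame
    tscore: pd.Series

    def __contains__(self, gene: str) -> bool:
        return gene in self.tscore.index

    def t(self, gene: str) -> float:
        try:
            return float(self.tscore[gene])
        except KeyError as exc:
            raise GTAError(f"gene {gene!r} has no score") from exc

    @property
    def genes(self) -> list[str]:
        return list(self.tscore.index)


def fit_class_densities(
    profile: ExpressionProfile, gene: str
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Fit a Gaussian to each phenotype class of one gene.

    Returns ((mean1, sd1), (mean2, sd2)) with unbiased (n−1) standard
    deviations floored at ``SD_FLOOR``.
    """
    if gene not in profile.values.index:
        raise GTAError(f"gene {gene!r} absent from the expression profile")
    row = profile.values.loc[gene]
    out = []
    for cls in (1, 2):
        x = row[profile.class_samples(cls)].to_numpy(dtype=float)
        out.append((float(np.mean(x)), max(float(np.std(x, ddof=1)), SD_FLOOR)))
    return out[0], out[1]


def compute_llr(profile: ExpressionProfile, gene: str) -> np.ndarray:
    """Natural-log likelihood ratio of one gene at each of the m samples."""
    (m1, s1), (m2, s2) = fit_class_densities(profile, gene)
    x = profile.values.loc[gene].to_numpy(dtype=float)
    return stats.norm.logpdf(x, m1, s1) - stats.norm.logpdf(x, m2, s2)


def _welch_fallback(a: np.ndarray, b: np.ndarray) -> float:
    """Welch statistic with floored variances, for degenerate inputs."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va < DEGENERATE_VAR and vb < DEGENERATE_VAR:
        if math.isclose(float(np.mean(a)), float(np.mean(b)),
                        rel_tol=0.0, abs_tol=1e-12):
            return 0.0
    va, vb = max(va, DEGENERATE_VAR ** 2), max(vb, DEGENERATE_VAR ** 2)
    se = math.sqrt(va / len(a) + vb / len(b))
    return float((np.mean(a) - np.mean(b)) / se)


def tscore_llr(llr: Sequence[float] | np.ndarray,
               labels: Sequence[int]) -> float:
    """Welch two-sample t of LLR values, class 1 minus class 2.

    ``labels`` is aligned with ``llr`` (one phenotype per entry). If both
    class variances are degenerate and the means equal, returns 0.
    """
    llr = np.asarray(llr, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if llr.shape != labels.shape:
        raise GTAError(
            f"llr length {llr.shape} does not match labels {labels.shape}"
        )
    a, b = llr[labels == 1], llr[labels == 2]
    if len(a) < 3 or len(b) < 3:
        raise GTAError("each phenotype class needs at least 3 samples")
    with warnings.catch_warnings():
        # near-constant vectors are handled by the degenerate fallback
        warnings.simplefilter("ignore", RuntimeWarning)
        t = stats.ttest_ind(a, b, equal_var=False).statistic
    if not np.isfinite(t):
        return _welch_fallback(a, b)
    return float(t)


def score_genes(profile: ExpressionProfile,
                genes: Iterable[str] | None = None) -> GeneScoreTable:
    """Compute LLR vectors and t-scores for all (or the given) genes.

    Vectorized over the whole matrix; equivalent to calling
    :func:`compute_llr` / :func:`tscore_llr` per gene.
    """
    if genes is None:
        genes = profile.genes
    else:
        genes = [g for g in profile.genes if g in set(genes)]
    X = profile.values.loc[genes]
    labels = profile.labels.to_numpy()
    case, ctrl = labels == 1, labels == 2

    Xv = X.to_numpy(dtype=float)
    params = []
    for mask in (case, ctrl):
        sub = Xv[:, mask]
        mu = sub.mean(axis=1)
        sd = np.maximum(sub.std(axis=1, ddof=1), SD_FLOOR)
        params.append((mu[:, None], sd[:, None]))
    (mu1, sd1), (mu2, sd2) = params
    llr = stats.norm.logpdf(Xv, mu1, sd1) - stats.norm.logpdf(Xv, mu2, sd2)

    with np.errstate(divide="ignore", invalid="ignore"), \
            warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t = stats.ttest_ind(llr[:, case], llr[:, ctrl],
                            axis=1, equal_var=False).statistic
    t = np.asarray(t, dtype=float)
    for i in np.nonzero(~np.isfinite(t))[0]:
        t[i] = _welch_fallback(llr[i, case], llr[i, ctrl])

    return GeneScoreTable(
        llr=pd.DataFrame(llr, index=genes, columns=profile.samples),
        tscore=pd.Series(t, index=genes),
    )


def local_score(gene: str, joined_neighbors: Iterable[str],
                scores: GeneScoreTable, strategy: int) -> float:
    """Local score LS: sum of t-scores of the gene's joined neighbours.

    A leaving player has no neighbour in the subnetwork, so its LS is 0.
    """
    if strategy == 0:
        return 0.0
    return float(sum(scores.t(n) for n in joined_neighbors))


def density(joined_nodes: Iterable[str], graph: nx.Graph) -> float:
    """Weighted edge density DE of the subgraph induced on the joined set.

    Σ_{e ∈ E_join} w(e) / C(|V_join|, 2); 0 when fewer than 2 nodes are
    joined (the binomial denominator is undefined there).
    """
    joined = set(joined_nodes)
    k = len(joined)
    if k < 2:
        return 0.0
    total = sum(
        d.get("weight", 1.0)
        for a, b, d in graph.edges(joined, data=True)
        if a in joined and b in joined
    )
    return float(total) / (k * (k - 1) / 2)


def gain(gene: str, state: Mapping[str, int], graph: nx.Graph,
         scores: GeneScoreTable, params: PayoffParams) -> float:
    """Gain GF = α·t(gene) + β·LS(gene) + γ·DE(joined subgraph).

    The t-score term applies under either strategy; LS and DE depend on
    the current joined set of ``state`` within ``graph``.
    """
    joined = {g for g, s in state.items() if s == 1}
    ls = local_score(
        gene,
        (n for n in graph.neighbors(gene) if n in joined and n != gene),
        scores,
        state[gene],
    )
    return (
        params.alpha * scores.t(gene)
        + params.beta * ls
        + params.gamma * density(joined, graph)
    )


def loss(joined_count: int, params: PayoffParams) -> float:
    """Loss LF = δ·(|V_join| − 1), identical for every player of the state."""
    if joined_count < 1:
        raise GTAError(
            "joined_count must be >= 1: the seed always joins"
        )
    return params.delta * (joined_count - 1)


def payoff(gene: str, state: Mapping[str, int], graph: nx.Graph,
           scores: GeneScoreTable, params: PayoffParams) -> float:
    """Payoff PF = GF − LF for one player under one strategy state."""
    joined_count = sum(1 for s in state.values() if s == 1)
    return gain(gene, state, graph, scores, params) - loss(joined_count, params)
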