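"""Weighted co-expression networks: soft threshold, TOM, edges, hubs.

Adjacency between genes i and j is |cor(x_i, x_j)|^beta (unsigned, the
default) or ((1 + cor)/2)^beta (signed). The topological overlap between
two genes combines their direct adjacency with the adjacency they share
through third genes:

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(K_i, K_j) + 1 - a_ij)

with K_i = sum_{u != i} a_iu; the diagonal is stored as 1 by convention and
excluded from the TOM connectivity k_i = sum_{j != i} TOM_ij, the hub-gene
ranking statistic.

Edge calling supports the top-quantile rule (highest TOM pairs), a
permutation FDR rule (per-gene independent sample-order permutation builds
the null TOM distribution, empirical p-values are pooled across pairs for
resolution, Benjamini–Hochberg q-values threshold the edges), and their
intersection. "Modules" are reported as connected components of the called
edge set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_qvalues, pearson_r_p
from .de import DEFAULT_ALPHA, DEResult
from .io import ExpressionStudy

logger = logging.getLogger("pathconcord")

DEFAULT_POWERS = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)
DEFAULT_POWER = 6
SCALE_FREE_R2_TARGET = 0.8
#: A power is only a candidate while the network keeps substance: once the
#: mean adjacency connectivity drops below 1, almost all mass sits in the
#: lowest histogram bin and the log-log fit turns spuriously linear.
MIN_MEAN_CONNECTIVITY = 1.0
#: Fallback floor: an argmax fit below this is indistinguishable from noise.
FALLBACK_R2_FLOOR = 0.5


# ---------------------------------------------------------------------------
# adjacency and TOM
# ---------------------------------------------------------------------------

def adjacency_matrix(X: np.ndarray, beta: float, mode: str = "unsigned") -> np.ndarray:
    """Soft-thresholded adjacency from a genes × samples matrix."""
    if mode not in ("unsigned", "signed"):
        raise ValueError(f"unknown mode {mode!r}")
    if X.shape[1] < 3:
        raise ValueError("need >= 3 samples for a correlation network")
    C = np.corrcoef(X)
    C = np.clip(C, -1.0, 1.0)
    A = np.abs(C) ** beta if mode == "unsigned" else ((1.0 + C) / 2.0) ** beta
    np.fill_diagonal(A, 0.0)
    return A


def tom_from_adjacency(A: np.ndarray) -> np.ndarray:
    """Topological overlap matrix from an adjacency with zero diagonal."""
    A = np.asarray(A, dtype=float)
    L = A @ A                      # zero diagonal makes u = i, j terms vanish
    K = A.sum(axis=1)
    min_k = np.minimum.outer(K, K)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + A) / (min_k + 1.0 - A)
    np.fill_diagonal(tom, 1.0)
    return tom


@dataclass
class TOMNetwork:
    """TOM network over one study's pathway genes."""

    study: str
    genes: list[str]
    beta: float
    mode: str
    adjacency: np.ndarray
    tom: np.ndarray
    scale_free_r2: float | None = None

    @property
    def connectivity(self) -> pd.Series:
        """k_i = sum of off-diagonal TOM values, indexed by gene."""
        k = self.tom.sum(axis=1) - np.diag(self.tom)
        return pd.Series(k, index=pd.Index(self.genes, name="gene"), name="k")

    def offdiag_values(self) -> np.ndarray:
        iu = np.triu_indices(len(self.genes), k=1)
        return self.tom[iu]


def tom_matrix(
    study: ExpressionStudy,
    beta: float,
    *,
    mode: str = "unsigned",
) -> TOMNetwork:
    """Build the TOM network for a study (zero-variance genes dropped)."""
    X = study.matrix.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need >= 3 genes")
    if X.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    keep = X.std(axis=1) > 0.0
    if not keep.all():
        logger.info("%s: dropping %d zero-variance genes from the network",
                    study.name, int((~keep).sum()))
    genes = [g for g, k in zip(study.matrix.index, keep) if k]
    A = adjacency_matrix(X[keep], beta, mode)
    return TOMNetwork(
        study=study.name, genes=genes, beta=beta, mode=mode,
        adjacency=A, tom=tom_from_adjacency(A),
    )


# ---------------------------------------------------------------------------
# soft-threshold (scale-free fit) selection
# ---------------------------------------------------------------------------

def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """(R², slope) of the log–log regression of the connectivity histogram.

    Connectivities are binned; log10 of the bin frequency is regressed on
    log10 of the bin-mean connectivity. A scale-free network shows a linear
    decay (negative slope, high R²).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < n_bins or np.ptp(k) == 0.0:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.digitize(k, edges[1:-1])
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        return 0.0, 0.0
    r, _ = pearson_r_p(np.array(xs), np.array(ys)) if np.std(xs) > 0 and np.std(ys) > 0 else (0.0, 1.0)
    slope = r * np.std(ys, ddof=1) / np.std(xs, ddof=1) if np.std(xs) > 0 else 0.0
    return float(r**2), float(slope)


def pick_soft_power(
    study: ExpressionStudy,
    powers=DEFAULT_POWERS,
    *,
    mode: str = "unsigned",
    r2_target: float = SCALE_FREE_R2_TARGET,
) -> tuple[float, pd.DataFrame]:
    """Smallest power whose scale-free fit (with decaying p(k)) reaches R² ≥ 0.8.

    Falls back to the argmax-R² candidate, and to the conventional default
    power 6 when no candidate shows any scale-free decay.
    """
    X = study.matrix.to_numpy(dtype=float)
    if X.shape[0] < 10:
        raise ValueError("need >= 10 genes for soft-power selection")
    if X.shape[1] < 4:
        raise ValueError("need >= 4 samples for soft-power selection")
    keep = X.std(axis=1) > 0.0
    X = X[keep]
    C = np.clip(np.corrcoef(X), -1.0, 1.0)
    rows = []
    for b in powers:
        A = np.abs(C) ** b if mode == "unsigned" else ((1.0 + C) / 2.0) ** b
        np.fill_diagonal(A, 0.0)
        k = A.sum(axis=1)
        if np.ptp(k) == 0.0:
            logger.warning("soft power %s: degenerate (constant) connectivity", b)
            r2, slope = 0.0, 0.0
        else:
            r2, slope = scale_free_fit(k)
        rows.append({"power": b, "r2": r2, "slope": slope, "mean_k": float(k.mean())})
    scan = pd.DataFrame(rows)
    eligible = (scan["slope"] < 0) & (scan["mean_k"] >= MIN_MEAN_CONNECTIVITY)
    fit_ok = eligible & (scan["r2"] >= r2_target)
    if fit_ok.any():
        beta = float(scan.loc[fit_ok, "power"].iloc[0])
    elif eligible.any() and scan.loc[eligible, "r2"].max() >= FALLBACK_R2_FLOOR:
        best = scan.loc[eligible, "r2"].idxmax()
        beta = float(scan.loc[best, "power"])
        logger.warning(
            "no soft power reached scale-free R2 >= %.2f; using argmax "
            "R2 power %g", r2_target, beta,
        )
    else:
        beta = float(DEFAULT_POWER)
        logger.warning(
            "no soft power produced a usable scale-free fit; "
            "falling back to default power %g", beta,
        )
    return beta, scan


# ---------------------------------------------------------------------------
# edge calling
# ---------------------------------------------------------------------------

EDGE_RULES = ("top_quantile", "fdr", "combined")


@dataclass
class EdgeCalls:
    """Called edges plus per-gene node attributes."""

    study: str
    rule: str
    threshold: float          # realized TOM threshold (top-quantile rules)
    edges: pd.DataFrame       # gene_i, gene_j, tom, p, q, in_top_quantile
    node_attrs: pd.DataFrame | None = None

    def components(self) -> list[set[str]]:
        """Connected components of the called edge set (the 'modules')."""
        import networkx as nx

        G = nx.Graph()
        G.add_edges_from(zip(self.edges["gene_i"], self.edges["gene_j"]))
        return [set(c) for c in nx.connected_components(G)]

    def to_graphml(self, path) -> None:
        import networkx as nx

        G = nx.Graph()
        if self.node_attrs is not None:
            for gene, row in self.node_attrs.iterrows():
                G.add_node(gene, **{k: v for k, v in row.items() if pd.notna(v)})
        for _, e in self.edges.iterrows():
            G.add_edge(e["gene_i"], e["gene_j"], tom=float(e["tom"]))
        nx.write_graphml(G, path)


def _null_tom_pool(
    X: np.ndarray, beta: float, mode: str, B: int, rng: np.random.Generator,
    scheme: str = "permute",
) -> np.ndarray:
    """Off-diagonal TOM values from B rounds of per-gene sample scrambling."""
    n_genes, n = X.shape
    iu = np.triu_indices(n_genes, k=1)
    pool = np.empty(B * iu[0].size)
    for b in range(B):
        if scheme == "permute":
            Xp = np.array([row[rng.permutation(n)] for row in X])
        elif scheme == "circular":
            shifts = rng.integers(1, n, size=n_genes)
            Xp = np.array([np.roll(row, s) for row, s in zip(X, shifts)])
        else:
            raise ValueError(f"unknown null scheme {scheme!r}")
        tom_b = tom_from_adjacency(adjacency_matrix(Xp, beta, mode))
        pool[b * iu[0].size : (b + 1) * iu[0].size] = tom_b[iu]
    return pool


def call_edges(
    net: TOMNetwork,
    study: ExpressionStudy | None = None,
    *,
    rule: str = "combined",
    top_q: float = 0.03,
    fdr_q: float = 0.001,
    B: int = 200,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    null_scheme: str = "permute",
    de: DEResult | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> EdgeCalls:
    """Select significant gene pairs from a TOM network.

    ``top_quantile`` keeps the top ``top_q`` fraction of pairs by TOM (ties
    at the cutoff are all kept and logged); ``fdr`` keeps pairs with
    Benjamini–Hochberg q < ``fdr_q`` against a permutation null pooled over
    pairs; ``combined`` intersects the two. ``study`` (the expression data
    the network was built from) is required for the FDR rules.
    """
    if rule not in EDGE_RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {EDGE_RULES}")
    if not 0.0 < top_q < 1.0:
        raise ValueError("top_q must lie in (0, 1)")
    genes = net.genes
    n = len(genes)
    iu = np.triu_indices(n, k=1)
    tom_vals = net.tom[iu]
    P = tom_vals.size
    edges = pd.DataFrame(
        {
            "gene_i": np.asarray(genes)[iu[0]],
            "gene_j": np.asarray(genes)[iu[1]],
            "tom": tom_vals,
        }
    )

    # top-quantile selection: rank-based, ties kept
    n_top = max(1, int(round(top_q * P)))
    cutoff = np.sort(tom_vals)[::-1][n_top - 1]
    in_top = tom_vals >= cutoff
    if int(in_top.sum()) > n_top:
        logger.info(
            "%s: ties at the top-%.3g cutoff kept %d pairs (%.2f%% realized)",
            net.study, top_q, int(in_top.sum()), 100.0 * in_top.sum() / P,
        )
    edges["in_top_quantile"] = in_top

    p_emp = q = None
    if rule in ("fdr", "combined"):
        if B < 100:
            raise ValueError("B must be >= 100 for the FDR rule")
        if study is None:
            raise ValueError("the FDR rule needs the study expression matrix")
        if rng is None:
            rng = np.random.default_rng(seed)
        floor = 1.0 / (B * P + 1.0)
        if floor > fdr_q:
            logger.warning(
                "edge FDR: pooled p floor %.3g exceeds requested q %.3g; "
                "increase B", floor, fdr_q,
            )
        X = study.matrix.loc[genes].to_numpy(dtype=float)
        pool = np.sort(_null_tom_pool(X, net.beta, net.mode, B, rng, null_scheme))
        # empirical p with +1 smoothing, pooled across pairs
        n_ge = pool.size - np.searchsorted(pool, tom_vals, side="left")
        p_emp = (1.0 + n_ge) / (pool.size + 1.0)
        q = bh_qvalues(p_emp)
        edges["p"] = p_emp
        edges["q"] = q

    if rule == "top_quantile":
        called = edges[edges["in_top_quantile"]]
    elif rule == "fdr":
        called = edges[edges["q"] < fdr_q]
    else:
        called = edges[edges["in_top_quantile"] & (edges["q"] < fdr_q)]

    node_attrs = None
    if de is not None:
        node_attrs = hub_table(net, de, alpha=alpha)
    return EdgeCalls(
        study=net.study, rule=rule, threshold=float(cutoff),
        edges=called.reset_index(drop=True), node_attrs=node_attrs,
    )


# ---------------------------------------------------------------------------
# connectivity vs DE significance
# ---------------------------------------------------------------------------

def de_class(de: DEResult, alpha: float = DEFAULT_ALPHA) -> pd.Series:
    """Per-gene class: up-significant / down-significant / not-significant."""
    t = de.table
    cls = np.where(
        t["p"] < alpha,
        np.where(t["t"] > 0, "up-significant", "down-significant"),
        "not-significant",
    )
    return pd.Series(cls, index=t.index, name="de_class")


def hub_table(net: TOMNetwork, de: DEResult, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Per-gene (k, −log10 p, DE class) sorted by connectivity descending."""
    shared = [g for g in net.genes if g in de.table.index]
    if len(shared) < 3:
        raise ValueError("fewer than 3 genes shared between network and DE result")
    tab = pd.DataFrame(
        {
            "k": net.connectivity.loc[shared],
            "t": de.table.loc[shared, "t"],
            "p": de.table.loc[shared, "p"],
            "neglog10p": de.table.loc[shared, "neglog10p"],
            "de_class": de_class(de, alpha).loc[shared],
        }
    )
    return tab.sort_values("k", ascending=False)


def connectivity_significance(
    net: TOMNetwork, de: DEResult, *, alpha: float = DEFAULT_ALPHA
) -> tuple[float, float, pd.DataFrame]:
    """Pearson r between TOM connectivity and −log10 DE p, plus hub table."""
    tab = hub_table(net, de, alpha=alpha)
    k = tab["k"].to_numpy(dtype=float)
    y = tab["neglog10p"].to_numpy(dtype=float)
    # tolerance-based: summation round-off must not mask a constant vector
    if np.ptp(k) <= 1e-9 * max(1.0, np.abs(k).max()) or np.std(y) == 0.0:
        raise ValueError("zero variance: connectivity–significance r undefined")
    r, p = pearson_r_p(k, y)
    return r, p, tab
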