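"""Permutation test for enrichment of differentially expressed genes in sets.

The observed statistic per set is k, the number of mapped set genes whose
per-gene DE p-value falls below ``alpha``. Two null schemes:

``label_permutation`` (default)
    Permute the case/control labels (or sign-flip each subject's
    late − early difference for paired designs) and recompute per-gene
    p-values each round. Preserves the gene–gene correlation structure.
``gene_sampling``
    Draw m genes at random from all genes mapped to the study per round —
    a competitive null that never touches the samples.

The permutation p-value uses +1 smoothing:
perm_p = (1 + #{k_null >= k_obs}) / (B + 1), so its floor is 1/(B+1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import paired_t_rows, welch_t_rows
from .de import DEFAULT_ALPHA, differential_expression
from .io import PAIRED, UNPAIRED, ExpressionStudy, GeneSetCollection

logger = logging.getLogger("pathconcord")

SCHEMES = ("label_permutation", "gene_sampling")
MIN_PERMUTATIONS = 100


def format_proportion(k: int, m: int) -> str:
    """Render k of m as ``"k/m (pct%)"`` with half-up percent rounding."""
    pct = math.floor(100.0 * k / m + 0.5)
    return f"{k}/{m} ({pct}%)"


@dataclass
class EnrichmentResult:
    """Permutation-enrichment outcome for one (study, set) pair."""

    study: str
    set_name: str
    m: int                 # mapped set size (genes in both set and study)
    k: int                 # mapped genes with p < alpha
    perm_p: float
    B: int
    scheme: str
    alpha: float

    @property
    def proportion(self) -> float:
        return self.k / self.m

    @property
    def display(self) -> str:
        return format_proportion(self.k, self.m)

    @property
    def at_floor(self) -> bool:
        return self.perm_p <= 1.0 / (self.B + 1)

    @property
    def perm_p_display(self) -> str:
        """Floor p-values are reported explicitly as an upper bound."""
        if self.at_floor:
            return f"< {1.0 / (self.B + 1):.2g}"
        return f"{self.perm_p:.4g}"


def _observed_pvalues(study: ExpressionStudy) -> pd.Series:
    de = differential_expression(study)
    return de.table["p"]


def _label_permutation_null(
    study: ExpressionStudy,
    member_idx: dict[str, np.ndarray],
    alpha: float,
    B: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Null k per set from B rounds of label permutation / sign flipping.

    One shared permutation per round serves every set, which keeps the
    joint structure of overlapping sets intact.
    """
    union = np.unique(np.concatenate(list(member_idx.values())))
    pos_of = {g: i for i, g in enumerate(union)}
    local = {name: np.array([pos_of[g] for g in idx]) for name, idx in member_idx.items()}
    k_null = {name: np.empty(B, dtype=int) for name in member_idx}

    if study.design == UNPAIRED:
        case_ids = study.group_columns("case")
        ctrl_ids = study.group_columns("control")
        X = study.matrix.iloc[union][case_ids + ctrl_ids].to_numpy(dtype=float)
        n_case = len(case_ids)
        n = X.shape[1]
        for b in range(B):
            perm = rng.permutation(n)
            _, _, p = welch_t_rows(X[:, perm[:n_case]], X[:, perm[n_case:]])
            sig = p < alpha
            for name, loc in local.items():
                k_null[name][b] = int(sig[loc].sum())
    else:
        early_ids, late_ids = study.paired_columns()
        D = (
            study.matrix.iloc[union][late_ids].to_numpy(dtype=float)
            - study.matrix.iloc[union][early_ids].to_numpy(dtype=float)
        )
        n_pairs = D.shape[1]
        for b in range(B):
            signs = rng.choice([-1.0, 1.0], size=n_pairs)
            _, _, p = paired_t_rows(D * signs[None, :])
            sig = p < alpha
            for name, loc in local.items():
                k_null[name][b] = int(sig[loc].sum())
    return k_null


def enrichment_test(
    study: ExpressionStudy,
    sets: GeneSetCollection,
    *,
    alpha: float = DEFAULT_ALPHA,
    B: int = 1000,
    scheme: str = "label_permutation",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[EnrichmentResult]:
    """Permutation enrichment of DE genes (p < alpha) in each gene set."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if B < MIN_PERMUTATIONS:
        raise ValueError(f"B must be >= {MIN_PERMUTATIONS} (got {B})")
    if rng is None:
        rng = np.random.default_rng(seed)

    pvals = _observed_pvalues(study)
    feature_pos = {g: i for i, g in enumerate(study.matrix.index)}

    member_idx: dict[str, np.ndarray] = {}
    for name, members in sets.sets.items():
        idx = np.array([feature_pos[g] for g in members if g in feature_pos])
        if idx.size == 0:
            logger.warning("enrichment: set %r has no genes in study %s; skipped",
                           name, study.name)
            continue
        member_idx[name] = idx

    if not member_idx:
        return []

    sig_obs = (pvals.to_numpy() < alpha)
    k_obs = {name: int(sig_obs[idx].sum()) for name, idx in member_idx.items()}

    if scheme == "label_permutation":
        k_null = _label_permutation_null(study, member_idx, alpha, B, rng)
    else:
        all_idx = np.arange(len(pvals))
        k_null = {}
        for name, idx in member_idx.items():
            m = idx.size
            draws = np.empty(B, dtype=int)
            for b in range(B):
                sample = rng.choice(all_idx, size=m, replace=False)
                draws[b] = int(sig_obs[sample].sum())
            k_null[name] = draws

    results = []
    for name, idx in member_idx.items():
        k = k_obs[name]
        perm_p = (1.0 + int((k_null[name] >= k).sum())) / (B + 1.0)
        results.append(
            EnrichmentResult(
                study=study.name, set_name=name, m=int(idx.size), k=k,
                perm_p=perm_p, B=B, scheme=scheme, alpha=alpha,
            )
        )
    return results


def summarize_enrichment(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Studies × sets grid of ``"k/m (pct%)"`` strings plus long-format columns."""
    if not results:
        raise ValueError("no enrichment results to summarize")
    long = pd.DataFrame(
        [
            {
                "study": r.study,
                "set": r.set_name,
                "k": r.k,
                "m": r.m,
                "proportion": r.proportion,
                "display": r.display,
                "perm_p": r.perm_p,
                "perm_p_display": r.perm_p_display,
            }
            for r in results
        ]
    )
    grid = long.pivot(index="set", columns="study", values="display")
    grid.attrs["long"] = long
    return grid
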