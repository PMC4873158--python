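"""Cross-study concordance of per-gene t statistics within gene sets.

For each study pair and each gene set, the Pearson correlation of the two
studies' t statistics over the genes mapped in both studies, with the
analytic two-sided p-value from the t transform of r. Spearman is available
as an option for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import pearson_r_p
from .de import DEResult
from .io import GeneSetCollection

MIN_COMMON_GENES = 3


@dataclass
class ConcordanceResult:
    """Concordance of expression changes for one (study pair, set)."""

    study_a: str
    study_b: str
    set_name: str
    n_common: int
    r: float
    p: float
    scatter: pd.DataFrame  # per-gene (t_a, t_b); identity line is the reference

    @property
    def pair(self) -> tuple[str, str]:
        return (self.study_a, self.study_b)


def concordance(
    de_a: DEResult,
    de_b: DEResult,
    sets: GeneSetCollection,
    *,
    method: str = "pearson",
) -> list[ConcordanceResult]:
    """Per-set correlation of t statistics between two studies."""
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    results = []
    for name, members in sets.sets.items():
        common = [
            g for g in members
            if g in de_a.table.index and g in de_b.table.index
        ]
        if len(common) < MIN_COMMON_GENES:
            raise ValueError(
                f"set {name!r}: only {len(common)} genes common to "
                f"{de_a.study} and {de_b.study} (need >= {MIN_COMMON_GENES})"
            )
        ta = de_a.table.loc[common, "t"].to_numpy(dtype=float)
        tb = de_b.table.loc[common, "t"].to_numpy(dtype=float)
        if np.std(ta) == 0.0 or np.std(tb) == 0.0:
            raise ValueError(f"set {name!r}: zero variance in a t vector")
        if method == "pearson":
            r, p = pearson_r_p(ta, tb)
        else:
            rho = stats.spearmanr(ta, tb)
            r, p = float(rho.statistic), float(rho.pvalue)
        scatter = pd.DataFrame(
            {"t_a": ta, "t_b": tb}, index=pd.Index(common, name="gene")
        )
        results.append(
            ConcordanceResult(
                study_a=de_a.study, study_b=de_b.study, set_name=name,
                n_common=len(common), r=r, p=p, scatter=scatter,
            )
        )
    return results


def all_pairs_concordance(
    de_results: dict[str, DEResult],
    sets: GeneSetCollection,
    *,
    method: str = "pearson",
) -> list[ConcordanceResult]:
    out: list[ConcordanceResult] = []
    for a, b in combinations(de_results, 2):
        out.extend(concordance(de_results[a], de_results[b], sets, method=method))
    return out


def to_long_table(results: list[ConcordanceResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "study_a": r.study_a,
                "study_b": r.study_b,
                "set": r.set_name,
                "n_common": r.n_common,
                "r": r.r,
                "p": r.p,
            }
            for r in results
        ]
    )


def concordance_matrix(results: list[ConcordanceResult]) -> pd.DataFrame:
    """Sets × study-pairs table of r, with a per-set min–max range column."""
    if not results:
        raise ValueError("no concordance results")
    long = to_long_table(results)
    long["pair"] = long["study_a"] + " vs " + long["study_b"]
    grid = long.pivot(index="set", columns="pair", values="r")
    ranges = []
    for _, row in grid.iterrows():
        lo, hi = float(np.nanmin(row)), float(np.nanmax(row))
        ranges.append(f"{lo:.2f}–{hi:.2f}")
    grid["range"] = ranges
    grid.attrs["long"] = long
    return grid
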