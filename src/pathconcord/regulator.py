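"""Regulator-gene analysis: correlation with pathway genes and own DE.

Correlates a designated regulator transcript (DNMT1 in the motivating
application) with every pathway gene across all samples of a study, and
reports the regulator's own differential-expression statistics with a
decreased/increased call. The Pearson kernel is shared with the
cross-study concordance module, so identical inputs give identical r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import pearson_rows_r_p
from .de import DEResult, differential_expression
from .io import ExpressionStudy, GeneSetCollection


@dataclass
class RegulatorCorrelation:
    """Per-gene correlations with the regulator plus per-set summaries."""

    study: str
    regulator: str
    per_gene: pd.DataFrame   # gene, set, r, p (ranked by |r| descending)
    per_set: pd.DataFrame    # set, n, mean_r, fraction_positive
    de_t: float | None = None
    de_p: float | None = None
    de_direction: str | None = None


def regulator_correlations(
    study: ExpressionStudy,
    sets: GeneSetCollection,
    regulator: str,
    *,
    group: str | None = None,
) -> RegulatorCorrelation:
    """Pearson r (with analytic p) between the regulator and each pathway gene.

    Computed across all samples pooled by default; ``group`` restricts to one
    arm of an unpaired study for sensitivity analysis.
    """
    if regulator not in study.matrix.index:
        raise ValueError(f"regulator {regulator!r} absent from study {study.name}")
    cols = study.sample_ids if group is None else study.group_columns(group)
    y = study.matrix.loc[regulator, cols].to_numpy(dtype=float)
    if np.std(y) == 0.0:
        raise ValueError(f"regulator {regulator!r} has zero variance")

    rows = []
    for set_name, members in sets.sets.items():
        genes = [g for g in members if g in study.matrix.index and g != regulator]
        if not genes:
            continue
        X = study.matrix.loc[genes, cols].to_numpy(dtype=float)
        r, p = pearson_rows_r_p(X, y)
        for g, ri, pi in zip(genes, r, p):
            rows.append({"gene": g, "set": set_name, "r": ri, "p": pi})
    if not rows:
        raise ValueError("no pathway genes present in the study")
    per_gene = pd.DataFrame(rows).dropna(subset=["r"])
    per_gene = per_gene.reindex(
        per_gene["r"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)
    per_set = (
        per_gene.groupby("set", sort=False)
        .agg(n=("r", "size"), mean_r=("r", "mean"),
             fraction_positive=("r", lambda s: float((s > 0).mean())))
        .reset_index()
    )
    return RegulatorCorrelation(
        study=study.name, regulator=regulator, per_gene=per_gene, per_set=per_set
    )


def regulator_de(
    study: ExpressionStudy, regulator: str, de: DEResult | None = None
) -> tuple[float, float, str]:
    """The regulator's own (t, p, direction) in the study's DE contrast.

    Direction is labeled ``"decreased"``/``"increased"`` (in cases, or at the
    late timepoint) or ``"unchanged"`` for t = 0.
    """
    if regulator not in study.matrix.index:
        raise ValueError(f"regulator {regulator!r} absent from study {study.name}")
    if de is None:
        de = differential_expression(study)
    row = de.table.loc[regulator]
    t, p = float(row["t"]), float(row["p"])
    direction = "decreased" if t < 0 else ("increased" if t > 0 else "unchanged")
    return t, p, direction


def full_regulator_analysis(
    study: ExpressionStudy,
    sets: GeneSetCollection,
    regulator: str,
    de: DEResult | None = None,
) -> RegulatorCorrelation:
    """Correlations plus the regulator's DE row in one report."""
    result = regulator_correlations(study, sets, regulator)
    t, p, direction = regulator_de(study, regulator, de)
    result.de_t, result.de_p, result.de_direction = t, p, direction
    return result
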