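"""Per-gene differential expression: Welch t (unpaired) and paired t.

The unpaired contrast is oriented case − control; the paired contrast is
late − early. Genes whose test is degenerate (no variance anywhere) are
reported with t = 0, p = 1 and logged rather than dropped, so every
downstream table keeps the full gene universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import paired_t_rows, welch_t_rows
from .io import PAIRED, UNPAIRED, ExpressionStudy

logger = logging.getLogger("pathconcord")

#: Default significance threshold for counting differentially expressed genes.
DEFAULT_ALPHA = 0.05


@dataclass
class DEResult:
    """Per-gene t statistics for one study.

    ``table`` is indexed by feature id with columns ``t``, ``p``,
    ``neglog10p`` and ``direction`` (sign of t). ``n_case``/``n_control``
    are set for unpaired designs, ``n_pairs`` for paired ones.
    """

    study: str
    design: str
    table: pd.DataFrame
    n_case: int | None = None
    n_control: int | None = None
    n_pairs: int | None = None

    def __post_init__(self) -> None:
        t = self.table
        if (t["p"] <= 0).any() or (t["p"] > 1).any():
            raise ValueError("p-values must lie in (0, 1]")

    def significant(self, alpha: float = DEFAULT_ALPHA) -> pd.Index:
        return self.table.index[self.table["p"] < alpha]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")


def _build_table(genes, t, p) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t": t,
            "p": p,
            "neglog10p": -np.log10(p),
            "direction": np.sign(t).astype(int),
        },
        index=pd.Index(genes, name="gene"),
    )


def welch_t(study: ExpressionStudy) -> DEResult:
    """Welch (unequal-variance) t per gene with Satterthwaite df."""
    if study.design != UNPAIRED:
        raise ValueError(f"welch_t requires an unpaired design, got {study.design!r}")
    case_ids = study.group_columns("case")
    ctrl_ids = study.group_columns("control")
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError(
            f"each group needs >= 2 samples "
            f"(case={len(case_ids)}, control={len(ctrl_ids)})"
        )
    X1 = study.matrix[case_ids].to_numpy(dtype=float)
    X2 = study.matrix[ctrl_ids].to_numpy(dtype=float)
    t, _, p = welch_t_rows(X1, X2)
    n_flat = int(((t == 0.0) & (p == 1.0)).sum())
    if n_flat:
        logger.info("%s: %d genes with zero variance in both groups (t=0, p=1)",
                    study.name, n_flat)
    return DEResult(
        study=study.name,
        design=UNPAIRED,
        table=_build_table(study.matrix.index, t, p),
        n_case=len(case_ids),
        n_control=len(ctrl_ids),
    )


def paired_t(study: ExpressionStudy) -> DEResult:
    """Paired t per gene on within-subject (late − early) differences."""
    if study.design != PAIRED:
        raise ValueError(f"paired_t requires a paired design, got {study.design!r}")
    early_ids, late_ids = study.paired_columns()
    if len(early_ids) < 2:
        raise ValueError(f"need >= 2 complete pairs (got {len(early_ids)})")
    D = (
        study.matrix[late_ids].to_numpy(dtype=float)
        - study.matrix[early_ids].to_numpy(dtype=float)
    )
    t, _, p = paired_t_rows(D)
    n_flat = int(((t == 0.0) & (p == 1.0)).sum())
    if n_flat:
        logger.info("%s: %d genes with zero-variance differences (t=0, p=1)",
                    study.name, n_flat)
    return DEResult(
        study=study.name,
        design=PAIRED,
        table=_build_table(study.matrix.index, t, p),
        n_pairs=len(early_ids),
    )


def differential_expression(study: ExpressionStudy) -> DEResult:
    """Dispatch on the study design."""
    return welch_t(study) if study.design == UNPAIRED else paired_t(study)
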