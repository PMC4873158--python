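"""Expression-matrix, sample-annotation and gene-set (GMT) I/O.

Supports two on-disk dialects for expression matrices: plain TSV
(features in rows, header = sample ids) and the GEO series-matrix text
format, from which only the table between the
``!series_matrix_table_begin`` / ``!series_matrix_table_end`` fences is
read. Sample annotations always come from a sidecar TSV
(``sample_id`` + either ``group`` or ``subject``/``timepoint`` columns).

Also houses quantile normalization and DE-guided probe-to-gene collapsing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .de import DEResult

logger = logging.getLogger("pathconcord")

UNPAIRED = "unpaired"
PAIRED = "paired"
EARLY = "early"
LATE = "late"

#: Heuristic: expression values above this are assumed to be on the raw
#: (unlogged) intensity scale and are log2(x+1)-transformed on ingestion.
LOG_SCALE_MAX = 30.0


@dataclass
class ExpressionStudy:
    """One cohort: a features × samples matrix plus its design.

    ``matrix`` is indexed by feature id (probe or gene symbol) with sample
    ids as columns. ``samples`` is indexed by sample id and carries either a
    ``group`` column (values ``case``/``control``) for an unpaired design or
    ``subject``/``timepoint`` columns (timepoint ``early``/``late``) for a
    paired design.
    """

    name: str
    matrix: pd.DataFrame
    samples: pd.DataFrame
    design: str
    log_scale: bool = True

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.design not in (UNPAIRED, PAIRED):
            raise ValueError(f"unknown design {self.design!r}")
        if self.matrix.size == 0:
            raise ValueError("empty expression matrix")
        if self.matrix.columns.duplicated().any():
            raise ValueError("duplicated sample ids in expression matrix")
        if self.samples.index.duplicated().any():
            raise ValueError("duplicated sample ids in annotation")
        missing = set(self.matrix.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without annotation: {sorted(missing)[:5]}")
        if self.matrix.isna().any().any():
            raise ValueError("matrix contains missing values after ingestion")
        if self.design == UNPAIRED:
            if "group" not in self.samples.columns:
                raise ValueError("unpaired design requires a 'group' column")
            bad = set(self.samples["group"]) - {"case", "control"}
            if bad:
                raise ValueError(f"unknown group labels: {sorted(bad)}")
        else:
            for col in ("subject", "timepoint"):
                if col not in self.samples.columns:
                    raise ValueError(f"paired design requires a {col!r} column")
            ann = self.samples.loc[list(self.matrix.columns)]
            counts = ann.groupby("subject")["timepoint"].apply(
                lambda s: sorted(s.tolist())
            )
            for subject, tps in counts.items():
                if tps != [EARLY, LATE]:
                    raise ValueError(
                        f"subject {subject!r} must have exactly one early and "
                        f"one late sample, got {tps}"
                    )

    # -- design accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)

    def group_columns(self, group: str) -> list[str]:
        """Sample ids with the given group label (unpaired designs)."""
        if self.design != UNPAIRED:
            raise ValueError("group_columns is only defined for unpaired designs")
        ann = self.samples.loc[list(self.matrix.columns)]
        return list(ann.index[ann["group"] == group])

    def paired_columns(self) -> tuple[list[str], list[str]]:
        """(early, late) sample ids, matched subject-by-subject."""
        if self.design != PAIRED:
            raise ValueError("paired_columns is only defined for paired designs")
        ann = self.samples.loc[list(self.matrix.columns)]
        early = ann[ann["timepoint"] == EARLY].sort_values("subject")
        late = ann[ann["timepoint"] == LATE].sort_values("subject")
        return list(early.index), list(late.index)

    def subset_features(self, feature_ids) -> "ExpressionStudy":
        keep = [f for f in feature_ids if f in self.matrix.index]
        return replace(self, matrix=self.matrix.loc[keep])


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways) as ordered symbol lists."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(set(members)) != len(members):
                raise ValueError(f"duplicate symbols in set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def union(self) -> list[str]:
        seen: dict[str, None] = {}
        for members in self.sets.values():
            for g in members:
                seen.setdefault(g)
        return list(seen)

    def mapped(self, feature_ids) -> "GeneSetCollection":
        """Intersect every set with a study's features (mapped sizes)."""
        feats = set(feature_ids)
        return GeneSetCollection(
            sets={n: [g for g in m if g in feats] for n, m in self.sets.items()},
            provenance=self.provenance,
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_series_matrix_table(path: Path) -> pd.DataFrame:
    lines = path.read_text().splitlines()
    try:
        start = next(
            i for i, l in enumerate(lines)
            if l.startswith("!series_matrix_table_begin")
        )
        end = next(
            i for i, l in enumerate(lines)
            if l.startswith("!series_matrix_table_end")
        )
    except StopIteration:
        raise ValueError(f"{path}: missing series_matrix table fences") from None
    from io import StringIO

    body = "\n".join(lines[start + 1 : end])
    df = pd.read_csv(StringIO(body), sep="\t", index_col=0)
    df.columns = [str(c).strip('"') for c in df.columns]
    df.index = pd.Index([str(i).strip('"') for i in df.index], name=df.index.name)
    return df


def read_expression(
    expr_path,
    samples_path,
    *,
    dialect: str = "tsv",
    name: str | None = None,
) -> ExpressionStudy:
    """Read an expression matrix plus its sidecar sample-annotation TSV.

    Features with any missing value are dropped (count logged). Values on an
    apparent raw intensity scale (max > 30) are log2(x+1)-transformed.
    The design is inferred from the annotation columns: ``group`` marks an
    unpaired case/control study, ``subject``/``timepoint`` a paired one.
    """
    expr_path = Path(expr_path)
    if dialect == "tsv":
        mat = pd.read_csv(expr_path, sep="\t", index_col=0)
    elif dialect == "series_matrix":
        mat = _read_series_matrix_table(expr_path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if mat.size == 0:
        raise ValueError(f"{expr_path}: empty expression matrix")
    mat = mat.apply(pd.to_numeric, errors="coerce")
    n_missing = int(mat.isna().any(axis=1).sum())
    if n_missing:
        logger.info(
            "%s: dropped %d/%d features with missing values",
            expr_path.name, n_missing, mat.shape[0],
        )
        mat = mat.dropna(axis=0)
    if mat.size == 0:
        raise ValueError(f"{expr_path}: no features left after missing-value filter")

    log_scale = True
    if float(mat.to_numpy().max()) > LOG_SCALE_MAX:
        logger.info("%s: max value > %g, applying log2(x+1)", expr_path.name, LOG_SCALE_MAX)
        mat = np.log2(mat + 1.0)

    samples = pd.read_csv(samples_path, sep="\t", dtype=str).set_index("sample_id")
    design = UNPAIRED if "group" in samples.columns else PAIRED
    missing = set(mat.columns) - set(samples.index)
    if missing:
        raise ValueError(f"annotation/sample-id mismatch: {sorted(missing)[:5]}")
    return ExpressionStudy(
        name=name or expr_path.stem.split(".")[0],
        matrix=mat,
        samples=samples,
        design=design,
        log_scale=log_scale,
    )


def write_expression(study: ExpressionStudy, expr_path, samples_path) -> None:
    study.matrix.to_csv(expr_path, sep="\t", index_label="feature_id")
    study.samples.to_csv(samples_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Force every sample onto the mean order-statistic distribution.

    Each column's value at rank r is replaced by the across-column mean of
    the rank-r order statistics; within-column ranks are preserved (ties
    keep their original order via a stable sort), which makes the transform
    exactly idempotent.
    """
    X = study.matrix.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    order = np.argsort(X, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(X.shape[0])[:, None]
    np.put_along_axis(ranks, order, rows.repeat(X.shape[1], axis=1), axis=0)
    mean_sorted = np.sort(X, axis=0).mean(axis=1)
    Xn = mean_sorted[ranks]
    return replace(study, matrix=pd.DataFrame(Xn, index=study.matrix.index,
                                              columns=study.matrix.columns))


# ---------------------------------------------------------------------------
# probe collapsing
# ---------------------------------------------------------------------------

def collapse_probes(
    study: ExpressionStudy,
    probe_to_gene: Mapping[str, str],
    de: "DEResult",
) -> ExpressionStudy:
    """Collapse multiple probes per gene, keeping the most significant probe.

    For each gene symbol the probe with the smallest DE p-value (computed on
    the uncollapsed study) is retained; ties break by larger \\|t\\|, then by
    lexicographic probe id. Probes absent from the mapping are dropped and
    logged.
    """
    table = de.table
    unmapped = [p for p in study.matrix.index if p not in probe_to_gene]
    if unmapped:
        logger.info("collapse_probes: dropping %d unmapped probes", len(unmapped))
    records = []
    for probe in study.matrix.index:
        gene = probe_to_gene.get(probe)
        if gene is None or probe not in table.index:
            continue
        row = table.loc[probe]
        records.append((gene, float(row["p"]), -abs(float(row["t"])), str(probe)))
    if not records:
        raise ValueError("collapse_probes: no mapped probes with DE statistics")
    rec = pd.DataFrame(records, columns=["gene", "p", "neg_abs_t", "probe"])
    # sort implements the selection rule: min p, then max |t|, then probe id
    rec = rec.sort_values(["gene", "p", "neg_abs_t", "probe"], kind="stable")
    chosen = rec.groupby("gene", sort=True).first()["probe"]
    collapsed = study.matrix.loc[chosen.to_numpy()]
    collapsed.index = chosen.index
    return replace(study, matrix=collapsed)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name, description, then tab-separated members)."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: malformed GMT line (<3 fields)")
        name = fields[0]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        members: list[str] = []
        seen: set[str] = set()
        dupes = 0
        for sym in fields[2:]:
            if not sym:
                continue
            if sym in seen:
                dupes += 1
                continue
            seen.add(sym)
            members.append(sym)
        if dupes:
            logger.info("read_gmt: %s: %d duplicate symbols removed in %s",
                        path, dupes, name)
        sets[name] = members
    return GeneSetCollection(sets=sets, provenance=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = [
        "\t".join([name, collection.provenance or "na", *members])
        for name, members in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
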