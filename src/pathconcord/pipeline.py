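"""End-to-end multi-study pipeline driven by a single YAML config.

Per study: ingestion (optional probe collapsing, quantile normalization),
differential expression, permutation pathway enrichment, the pathway-gene
TOM network with edge calls and connectivity–significance correlation, and
the regulator analysis; across studies: pairwise concordance of t
statistics. Everything lands in an output directory as TSV tables plus one
machine-readable ``report.json``; a structured log records versions, the
seed and every threshold. The pipeline is deterministic under a fixed seed,
so reruns reproduce the report byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concordance import all_pairs_concordance, concordance_matrix, to_long_table
from .de import DEFAULT_ALPHA, DEResult, differential_expression
from .enrichment import enrichment_test, summarize_enrichment
from .io import (
    ExpressionStudy,
    collapse_probes,
    quantile_normalize,
    read_expression,
    read_gmt,
)
from .network import call_edges, connectivity_significance, pick_soft_power, tom_matrix
from .regulator import regulator_correlations, regulator_de

logger = logging.getLogger("pathconcord")


@dataclass
class StudyConfig:
    name: str
    expr: str
    samples: str
    dialect: str = "tsv"
    probe_map: str | None = None


@dataclass
class NetworkConfig:
    mode: str = "unsigned"
    beta: float | None = None      # None = automatic soft-power selection
    top_q: float = 0.03
    fdr_q: float = 0.001
    permutations: int = 200


@dataclass
class RunConfig:
    """Validated parameterization of a full multi-study run."""

    studies: list[StudyConfig]
    gmt: str
    out_dir: str
    seed: int
    alpha: float = DEFAULT_ALPHA
    enrichment_permutations: int = 1000
    enrichment_scheme: str = "label_permutation"
    quantile_normalize: bool = True
    network: NetworkConfig = field(default_factory=NetworkConfig)
    regulator: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["studies"] = [StudyConfig(**s) for s in raw["studies"]]
        if "network" in raw:
            raw["network"] = NetworkConfig(**raw["network"])
        cfg = cls(**raw)
        cfg.validate(base=Path(path).parent)
        return cfg

    def validate(self, base: Path | None = None) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        base = base or Path(".")

        def resolve(p: str) -> str:
            q = Path(p)
            return str(q if q.is_absolute() else base / q)

        self.gmt = resolve(self.gmt)
        if not Path(self.gmt).exists():
            raise FileNotFoundError(self.gmt)
        for st in self.studies:
            st.expr, st.samples = resolve(st.expr), resolve(st.samples)
            for p in (st.expr, st.samples):
                if not Path(p).exists():
                    raise FileNotFoundError(p)
            if st.probe_map is not None:
                st.probe_map = resolve(st.probe_map)
                if not Path(st.probe_map).exists():
                    raise FileNotFoundError(st.probe_map)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs remain on disk."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _setup_logging(out_dir: Path) -> None:
    root = logging.getLogger("pathconcord")
    root.setLevel(logging.INFO)
    have = {getattr(h, "_pathconcord_tag", None) for h in root.handlers}
    if "stderr" not in have:
        h = logging.StreamHandler(sys.stderr)
        h._pathconcord_tag = "stderr"
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        root.addHandler(h)
    fh = logging.FileHandler(out_dir / "run.log", mode="w")
    fh._pathconcord_tag = "file"
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root.handlers = [h for h in root.handlers
                     if getattr(h, "_pathconcord_tag", None) != "file"]
    root.addHandler(fh)


def _load_study(cfg: RunConfig, st: StudyConfig) -> ExpressionStudy:
    study = read_expression(
        st.expr, st.samples, dialect=st.dialect, name=st.name
    )
    if st.probe_map is not None:
        mapping = (
            pd.read_csv(st.probe_map, sep="\t", dtype=str)
            .set_index("probe")["gene"]
            .to_dict()
        )
        de_probe = differential_expression(study)
        study = collapse_probes(study, mapping, de_probe)
    if cfg.quantile_normalize:
        study = quantile_normalize(study)
    return study


def run_all(config: RunConfig) -> dict:
    """Run the full analysis; returns (and writes) the report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    logger.info("pathconcord %s | seed=%d alpha=%g enrichment B=%d scheme=%s "
                "network=%s", __version__, config.seed, config.alpha,
                config.enrichment_permutations, config.enrichment_scheme,
                config.network)

    root_ss = np.random.SeedSequence(config.seed)
    sets = read_gmt(config.gmt)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "alpha": config.alpha,
            "enrichment_permutations": config.enrichment_permutations,
            "enrichment_scheme": config.enrichment_scheme,
            "quantile_normalize": config.quantile_normalize,
            "network": {
                "mode": config.network.mode,
                "beta": config.network.beta,
                "top_q": config.network.top_q,
                "fdr_q": config.network.fdr_q,
                "permutations": config.network.permutations,
            },
            "regulator": config.regulator,
        },
        "gene_sets": {n: len(m) for n, m in sets.sets.items()},
        "studies": {},
    }

    de_results: dict[str, DEResult] = {}
    enrich_all = []
    stage = "setup"
    try:
        for i, st_cfg in enumerate(config.studies):
            name = st_cfg.name
            study_dir = out / name
            study_dir.mkdir(exist_ok=True)
            # one independent, deterministic substream per study
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 1000 + i])
            )
            study_report: dict = {"design": None}

            stage = f"{name}:ingest"
            study = _load_study(config, st_cfg)
            study_report["design"] = study.design
            study_report["n_features"] = int(study.matrix.shape[0])
            study_report["n_samples"] = int(study.matrix.shape[1])
            mapped = sets.mapped(study.feature_ids)
            study_report["mapped_set_sizes"] = {
                n: len(m) for n, m in mapped.sets.items()
            }

            stage = f"{name}:differential_expression"
            de = differential_expression(study)
            de.to_tsv(study_dir / "de.tsv")
            de_results[name] = de

            stage = f"{name}:enrichment"
            enr = enrichment_test(
                study, sets,
                alpha=config.alpha,
                B=config.enrichment_permutations,
                scheme=config.enrichment_scheme,
                rng=rng,
            )
            enrich_all.extend(enr)
            study_report["enrichment"] = {
                r.set_name: {
                    "k": r.k, "m": r.m, "display": r.display,
                    "perm_p": r.perm_p, "perm_p_display": r.perm_p_display,
                }
                for r in enr
            }

            stage = f"{name}:network"
            pathway_study = study.subset_features(sets.union())
            if config.network.beta is None:
                beta, scan = pick_soft_power(pathway_study, mode=config.network.mode)
                scan.to_csv(study_dir / "soft_power_scan.tsv", sep="\t", index=False)
            else:
                beta = config.network.beta
            net = tom_matrix(pathway_study, beta, mode=config.network.mode)
            calls = call_edges(
                net, pathway_study,
                rule="combined",
                top_q=config.network.top_q,
                fdr_q=config.network.fdr_q,
                B=config.network.permutations,
                rng=rng,
                de=de,
                alpha=config.alpha,
            )
            calls.edges.to_csv(study_dir / "edges.tsv", sep="\t", index=False)
            r_ks, p_ks, hub_tab = connectivity_significance(net, de, alpha=config.alpha)
            hub_tab.to_csv(study_dir / "nodes.tsv", sep="\t", index_label="gene")
            study_report["network"] = {
                "beta": beta,
                "n_genes": len(net.genes),
                "n_edges": int(len(calls.edges)),
                "n_components": len(calls.components()),
                "connectivity_significance_r": r_ks,
                "connectivity_significance_p": p_ks,
                "top_hubs": list(hub_tab.index[:10]),
            }

            if config.regulator is not None:
                stage = f"{name}:regulator"
                if config.regulator in study.matrix.index:
                    reg = regulator_correlations(study, sets, config.regulator)
                    t, p, direction = regulator_de(study, config.regulator, de)
                    reg.per_gene.to_csv(study_dir / "regulator.tsv", sep="\t",
                                        index=False)
                    study_report["regulator"] = {
                        "de": {"t": t, "p": p, "direction": direction},
                        "per_set": {
                            row["set"]: {
                                "mean_r": row["mean_r"],
                                "fraction_positive": row["fraction_positive"],
                                "n": int(row["n"]),
                            }
                            for _, row in reg.per_set.iterrows()
                        },
                    }
                else:
                    logger.warning("regulator %r absent from study %s",
                                   config.regulator, name)
                    study_report["regulator"] = {"absent": True}

            report["studies"][name] = study_report

        stage = "concordance"
        if len(de_results) >= 2:
            conc = all_pairs_concordance(de_results, sets)
            long = to_long_table(conc)
            long.to_csv(out / "concordance.tsv", sep="\t", index=False)
            for c in conc:
                c.scatter.to_csv(
                    out / f"scatter_{c.study_a}_vs_{c.study_b}_{c.set_name}.tsv",
                    sep="\t",
                )
            grid = concordance_matrix(conc)
            report["concordance"] = {
                "matrix": {
                    s: {c: (None if pd.isna(v) else v) for c, v in row.items()}
                    for s, row in grid.drop(columns="range").iterrows()
                },
                "ranges": grid["range"].to_dict(),
            }

        stage = "report"
        grid = summarize_enrichment(enrich_all)
        grid.attrs["long"].to_csv(out / "enrichment.tsv", sep="\t", index=False)
        report["enrichment_grid"] = {
            s: dict(row.dropna()) for s, row in grid.iterrows()
        }
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        if isinstance(exc, StageError):
            raise
        logger.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc) from exc
    return report
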