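"""Synthetic multi-cohort expression data with planted pathway structure.

The generator emulates the statistical shape of the analysis inputs: several
cohorts (unpaired case/control or paired two-timepoint) sharing the same
pathway gene sets, direction-consistent planted effects, hub-structured
within-set correlation, and one regulator gene coupled to the set factors
with chosen signs.

Model (per study, per sample): each gene-set *s* has a latent factor
F_s ~ N(0,1) drawn per sample. Gene *g* with factor loading
l_g = sqrt(rho_g) is

    x_g = mu_g + noise_sd * ( sum_s l_{g,s} F_s + sigma_g * eps_g )
          + noise_sd * shift_g * 1[case or late sample]

with sigma_g chosen so the total variance is noise_sd^2; hub genes load with
rho_hub, remaining set members with rho_nonhub. The planted per-gene shift is
shift_g = direction_s * delta_g where delta_g is drawn **once per design**
(shared by every study, so cross-study concordance is planted) as
delta_g = max(0, N(delta, (effect_dispersion*delta)^2)).

The regulator gene is a weighted sum of the set factors (weights = signed
coupling strengths) plus independent noise, giving corr(regulator, F_s) equal
to the coupling and corr(regulator, gene g in s) = coupling_s * sqrt(rho_g).

Paired designs add a per-subject intercept b_j ~ N(0, noise_sd) to both of a
subject's samples, so within-subject differences cancel it and paired tests
gain power; the late sample receives the planted shift.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import EARLY, LATE, PAIRED, UNPAIRED, ExpressionStudy, GeneSetCollection

__all__ = [
    "GeneSetSpec",
    "StudySpec",
    "RegulatorSpec",
    "SyntheticDesign",
    "GroundTruth",
    "simulate_study",
    "simulate_all",
    "write_truth",
    "read_truth",
    "three_cohort_design",
    "design_from_yaml",
    "design_to_yaml",
]

#: Cap on the summed squared factor loadings of one gene (overlapping sets).
_MAX_COMMUNALITY = 0.95


def gene_symbol(idx: int) -> str:
    return f"G{idx:05d}"


@dataclass
class GeneSetSpec:
    """One planted pathway: members, effect direction/size, hub structure."""

    name: str
    members: list[int]
    direction: int = 0            # +1 up in cases, -1 down, 0 null
    effect_size: float = 0.0      # mean standardized shift delta >= 0
    n_hubs: int = 0
    rho_hub: float = 0.0          # pairwise correlation target for hub genes
    rho_nonhub: float = 0.0       # background loading for non-hub members
    effect_scope: str = "all"     # "all" members shifted, or "hubs" only
    hub_effect_multiplier: float = 1.0  # hubs carry this multiple of delta

    @property
    def hubs(self) -> list[int]:
        return self.members[: self.n_hubs]


@dataclass
class StudySpec:
    name: str
    design: str                   # "unpaired" | "paired"
    n_case: int = 0
    n_control: int = 0
    n_subjects: int = 0


@dataclass
class RegulatorSpec:
    """Regulator gene latent-coupled to set factors with signed strengths."""

    gene: int
    couplings: dict[str, float] = field(default_factory=dict)
    effect_size: float = 0.0      # standardized shift magnitude
    direction: int = 0            # -1 = decreased in cases/late
    symbol: str | None = None     # display symbol (e.g. "DNMT1")


@dataclass
class SyntheticDesign:
    """Full parameterization of the simulated multi-cohort truth."""

    n_genes: int
    studies: list[StudySpec]
    gene_sets: list[GeneSetSpec]
    regulator: RegulatorSpec | None = None
    noise_sd: float = 1.0
    effect_dispersion: float = 0.6
    probes_per_gene: int = 1
    probe_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.probes_per_gene < 1:
            raise ValueError("probes_per_gene must be >= 1")
        names = [s.name for s in self.studies]
        if len(set(names)) != len(names):
            raise ValueError("duplicate study names")
        for st in self.studies:
            if st.design == UNPAIRED:
                if st.n_case <= 0 or st.n_control <= 0:
                    raise ValueError(f"{st.name}: non-positive sample sizes")
            elif st.design == PAIRED:
                if st.n_subjects <= 0:
                    raise ValueError(f"{st.name}: non-positive subject count")
            else:
                raise ValueError(f"{st.name}: unknown design {st.design!r}")
        set_names = [gs.name for gs in self.gene_sets]
        if len(set(set_names)) != len(set_names):
            raise ValueError("duplicate gene-set names")
        for gs in self.gene_sets:
            if any(m < 0 or m >= self.n_genes for m in gs.members):
                raise ValueError(f"{gs.name}: member index out of range")
            if len(set(gs.members)) != len(gs.members):
                raise ValueError(f"{gs.name}: duplicate members")
            if gs.direction not in (-1, 0, 1):
                raise ValueError(f"{gs.name}: direction must be -1, 0 or +1")
            if gs.effect_size < 0:
                raise ValueError(f"{gs.name}: effect_size must be >= 0")
            if not (0.0 <= gs.rho_hub < 1.0 and 0.0 <= gs.rho_nonhub < 1.0):
                raise ValueError(f"{gs.name}: rho must lie in [0, 1)")
            if not 0 <= gs.n_hubs <= len(gs.members):
                raise ValueError(f"{gs.name}: n_hubs out of range")
            if gs.effect_scope not in ("all", "hubs"):
                raise ValueError(f"{gs.name}: unknown effect_scope")
            if gs.hub_effect_multiplier < 0:
                raise ValueError(f"{gs.name}: hub_effect_multiplier must be >= 0")
        if self.regulator is not None:
            reg = self.regulator
            if not 0 <= reg.gene < self.n_genes:
                raise ValueError("regulator gene index out of range")
            if any(reg.gene in gs.members for gs in self.gene_sets):
                raise ValueError("regulator gene must not be a set member")
            known = {gs.name for gs in self.gene_sets}
            if set(reg.couplings) - known:
                raise ValueError("regulator coupling to unknown set")
            if any(abs(c) >= 1.0 for c in reg.couplings.values()):
                raise ValueError("|coupling strength| must be < 1")
            if sum(c**2 for c in reg.couplings.values()) >= 1.0:
                raise ValueError("sum of squared couplings must be < 1")

    # -- derived ----------------------------------------------------------
    def study(self, name: str) -> StudySpec:
        for st in self.studies:
            if st.name == name:
                return st
        raise KeyError(f"unknown study name {name!r}")

    def symbols(self) -> list[str]:
        syms = [gene_symbol(i) for i in range(self.n_genes)]
        if self.regulator is not None and self.regulator.symbol:
            syms[self.regulator.gene] = self.regulator.symbol
        return syms

    def gene_set_collection(self) -> GeneSetCollection:
        syms = self.symbols()
        return GeneSetCollection(
            sets={gs.name: [syms[i] for i in gs.members] for gs in self.gene_sets},
            provenance="synthetic",
        )

    def _effects_rng(self) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, 0x5EED]))

    def _study_rng(self, study_name: str) -> np.random.Generator:
        key = zlib.crc32(study_name.encode())
        return np.random.default_rng(np.random.SeedSequence([self.seed, key]))

    def loadings(self) -> np.ndarray:
        """(n_genes, n_sets) factor-loading matrix, communality-capped."""
        L = np.zeros((self.n_genes, len(self.gene_sets)))
        for j, gs in enumerate(self.gene_sets):
            hubs = set(gs.hubs)
            for m in gs.members:
                L[m, j] = np.sqrt(gs.rho_hub if m in hubs else gs.rho_nonhub)
        if self.regulator is not None:
            for j, gs in enumerate(self.gene_sets):
                L[self.regulator.gene, j] = self.regulator.couplings.get(gs.name, 0.0)
        comm = (L**2).sum(axis=1)
        over = comm > _MAX_COMMUNALITY
        if over.any():
            L[over] *= np.sqrt(_MAX_COMMUNALITY / comm[over, None])
        return L

    def planted_shifts(self) -> np.ndarray:
        """Per-gene standardized shift (noise_sd units), shared by all studies."""
        rng = self._effects_rng()
        shifts = np.zeros(self.n_genes)
        for gs in self.gene_sets:
            targets = gs.hubs if gs.effect_scope == "hubs" else gs.members
            if gs.effect_size > 0 and gs.direction != 0:
                delta = rng.normal(
                    gs.effect_size,
                    self.effect_dispersion * gs.effect_size,
                    size=len(targets),
                )
                delta = np.maximum(delta, 0.0)
                hubs = set(gs.hubs)
                boost = np.array(
                    [gs.hub_effect_multiplier if m in hubs else 1.0 for m in targets]
                )
                delta = delta * boost
            else:
                # keep the stream position stable regardless of effect size
                rng.normal(size=len(targets))
                delta = np.zeros(len(targets))
            for m, d in zip(targets, delta):
                shifts[m] += gs.direction * d
        if self.regulator is not None and self.regulator.effect_size > 0:
            shifts[self.regulator.gene] += (
                self.regulator.direction * self.regulator.effect_size
            )
        return shifts


@dataclass
class GroundTruth:
    """Planted truth for one simulated study."""

    study: str
    gene_shifts: pd.DataFrame     # index gene symbol; column true_shift
    set_table: pd.DataFrame       # one row per planted set
    loadings: pd.DataFrame        # gene symbol x set name factor loadings

    def pair_sharing(self) -> pd.DataFrame:
        """Latent-factor sharing flag for every unordered pathway-gene pair."""
        active = self.loadings.loc[(self.loadings != 0).any(axis=1)]
        genes = list(active.index)
        L = (active.to_numpy() != 0)
        rows = []
        for a in range(len(genes)):
            for b in range(a + 1, len(genes)):
                rows.append(
                    (genes[a], genes[b], bool((L[a] & L[b]).any()))
                )
        return pd.DataFrame(rows, columns=["gene_i", "gene_j", "shared_factor"])


def _truth_for(design: SyntheticDesign, study_name: str) -> GroundTruth:
    syms = design.symbols()
    shifts = design.planted_shifts()
    gene_shifts = pd.DataFrame(
        {"true_shift": shifts}, index=pd.Index(syms, name="gene")
    )
    set_table = pd.DataFrame(
        [
            {
                "set": gs.name,
                "direction": gs.direction,
                "effect_size": gs.effect_size,
                "n_members": len(gs.members),
                "n_hubs": gs.n_hubs,
                "rho_hub": gs.rho_hub,
            }
            for gs in design.gene_sets
        ],
        columns=["set", "direction", "effect_size", "n_members", "n_hubs", "rho_hub"],
    )
    loadings = pd.DataFrame(
        design.loadings(),
        index=pd.Index(syms, name="gene"),
        columns=[gs.name for gs in design.gene_sets],
    )
    return GroundTruth(
        study=study_name, gene_shifts=gene_shifts,
        set_table=set_table, loadings=loadings,
    )


def simulate_study(
    design: SyntheticDesign, study_name: str
) -> tuple[ExpressionStudy, GroundTruth]:
    """Simulate one cohort of the design. Deterministic in (seed, study_name)."""
    spec = design.study(study_name)
    rng = design._study_rng(study_name)
    syms = design.symbols()
    L = design.loadings()
    shifts = design.planted_shifts()
    sigma = np.sqrt(np.clip(1.0 - (L**2).sum(axis=1), 0.0, None))
    n_sets = len(design.gene_sets)

    if spec.design == UNPAIRED:
        n = spec.n_case + spec.n_control
        case_mask = np.zeros(n)
        case_mask[: spec.n_case] = 1.0
        sample_ids = [f"{study_name}_case{i+1}" for i in range(spec.n_case)] + [
            f"{study_name}_ctrl{i+1}" for i in range(spec.n_control)
        ]
        samples = pd.DataFrame(
            {"group": ["case"] * spec.n_case + ["control"] * spec.n_control},
            index=pd.Index(sample_ids, name="sample_id"),
        )
        subject_term = 0.0
        shift_mask = case_mask
    else:
        n = 2 * spec.n_subjects
        sample_ids = [
            f"{study_name}_s{j+1}_{tp}"
            for j in range(spec.n_subjects)
            for tp in (EARLY, LATE)
        ]
        samples = pd.DataFrame(
            {
                "subject": [f"s{j+1}" for j in range(spec.n_subjects) for _ in range(2)],
                "timepoint": [EARLY, LATE] * spec.n_subjects,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        b = rng.normal(0.0, design.noise_sd, size=spec.n_subjects)
        subject_term = np.repeat(b, 2)[None, :]
        shift_mask = np.tile([0.0, 1.0], spec.n_subjects)

    baseline = rng.normal(8.0, 1.0, size=design.n_genes)[:, None]
    F = rng.standard_normal((n_sets, n)) if n_sets else np.zeros((0, n))
    eps = rng.standard_normal((design.n_genes, n))
    X = (
        baseline
        + design.noise_sd * (L @ F + sigma[:, None] * eps)
        + design.noise_sd * shifts[:, None] * shift_mask[None, :]
        + subject_term
    )

    if design.probes_per_gene > 1:
        k = design.probes_per_gene
        feat_ids = [f"{s}_p{j+1}" for s in syms for j in range(k)]
        X = np.repeat(X, k, axis=0) + rng.normal(
            0.0, design.probe_noise_sd * design.noise_sd, size=(design.n_genes * k, n)
        )
    else:
        feat_ids = syms

    matrix = pd.DataFrame(X, index=pd.Index(feat_ids, name="feature_id"),
                          columns=sample_ids)
    study = ExpressionStudy(
        name=study_name, matrix=matrix, samples=samples, design=spec.design
    )
    return study, _truth_for(design, study_name)


def simulate_all(design: SyntheticDesign) -> dict[str, tuple[ExpressionStudy, GroundTruth]]:
    return {st.name: simulate_study(design, st.name) for st in design.studies}


def probe_map(design: SyntheticDesign) -> dict[str, str]:
    """Probe-id → gene-symbol mapping for multi-probe designs."""
    k = design.probes_per_gene
    if k == 1:
        return {s: s for s in design.symbols()}
    return {f"{s}_p{j+1}": s for s in design.symbols() for j in range(k)}


# ---------------------------------------------------------------------------
# truth table I/O
# ---------------------------------------------------------------------------

def write_truth(truth: GroundTruth, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.gene_shifts.to_csv(out / "gene_shifts.tsv", sep="\t")
    truth.set_table.to_csv(out / "sets.tsv", sep="\t", index=False)
    truth.loadings.to_csv(out / "loadings.tsv", sep="\t")
    truth.pair_sharing().to_csv(out / "pair_sharing.tsv", sep="\t", index=False)


def read_truth(out_dir) -> dict[str, pd.DataFrame]:
    out = Path(out_dir)
    return {
        "gene_shifts": pd.read_csv(out / "gene_shifts.tsv", sep="\t", index_col=0),
        "sets": pd.read_csv(out / "sets.tsv", sep="\t"),
        "loadings": pd.read_csv(out / "loadings.tsv", sep="\t", index_col=0),
        "pair_sharing": pd.read_csv(out / "pair_sharing.tsv", sep="\t"),
    }


# ---------------------------------------------------------------------------
# the default three-cohort design
# ---------------------------------------------------------------------------

def three_cohort_design(
    seed: int,
    n_genes: int = 5000,
    effect_tlr: float = 0.4,
    effect_tcr: float = 0.5,
    effect_bcr: float = 0.5,
) -> SyntheticDesign:
    """Three cohorts emulating the atherosclerosis / stroke / MI structure.

    Two unpaired case/control cohorts and one paired 18-subject two-timepoint
    cohort; three pathway-sized gene sets (innate-like set planted up,
    two adaptive-like sets planted down) with 10 hub genes each; a DNMT1-like
    regulator negatively coupled to the up-set and positively to the down
    sets, itself planted down.
    """
    tlr = list(range(0, 106))
    tcr = list(range(106, 210))
    bcr = list(range(210, 282))
    reg_idx = 282
    if n_genes <= reg_idx:
        raise ValueError("three_cohort_design needs n_genes > 282")
    return SyntheticDesign(
        n_genes=n_genes,
        studies=[
            StudySpec("atherosclerosis", UNPAIRED, n_case=50, n_control=50),
            StudySpec("stroke", UNPAIRED, n_case=40, n_control=24),
            StudySpec("mi", PAIRED, n_subjects=18),
        ],
        gene_sets=[
            GeneSetSpec("TLR", tlr, direction=+1, effect_size=effect_tlr,
                        n_hubs=10, rho_hub=0.6, rho_nonhub=0.2,
                        hub_effect_multiplier=2.0),
            GeneSetSpec("TCR", tcr, direction=-1, effect_size=effect_tcr,
                        n_hubs=10, rho_hub=0.6, rho_nonhub=0.2,
                        hub_effect_multiplier=2.0),
            GeneSetSpec("BCR", bcr, direction=-1, effect_size=effect_bcr,
                        n_hubs=10, rho_hub=0.6, rho_nonhub=0.2,
                        hub_effect_multiplier=2.0),
        ],
        regulator=RegulatorSpec(
            gene=reg_idx,
            couplings={"TLR": -0.4, "TCR": 0.5, "BCR": 0.4},
            effect_size=0.8,
            direction=-1,
            symbol="DNMT1",
        ),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# YAML (de)serialization for the CLI
# ---------------------------------------------------------------------------

def design_to_yaml(design: SyntheticDesign, path) -> None:
    import yaml
    from dataclasses import asdict

    Path(path).write_text(yaml.safe_dump(asdict(design), sort_keys=False))


def design_from_yaml(path) -> SyntheticDesign:
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    raw["studies"] = [StudySpec(**s) for s in raw.get("studies", [])]
    raw["gene_sets"] = [GeneSetSpec(**g) for g in raw.get("gene_sets", [])]
    if raw.get("regulator") is not None:
        raw["regulator"] = RegulatorSpec(**raw["regulator"])
    return SyntheticDesign(**raw)
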