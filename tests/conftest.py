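import numpy as np
import pandas as pd
import pytest

from pathconcord import ExpressionStudy, GeneSetCollection
from pathconcord.synthetic import (
    GeneSetSpec,
    RegulatorSpec,
    StudySpec,
    SyntheticDesign,
)


def make_unpaired_study(
    n_genes=20, n_case=5, n_control=5, seed=0, name="toy"
) -> ExpressionStudy:
    rng = np.random.default_rng(seed)
    X = rng.normal(8.0, 1.0, size=(n_genes, n_case + n_control))
    cols = [f"case{i}" for i in range(n_case)] + [f"ctrl{i}" for i in range(n_control)]
    matrix = pd.DataFrame(X, index=[f"G{i:03d}" for i in range(n_genes)], columns=cols)
    samples = pd.DataFrame(
        {"group": ["case"] * n_case + ["control"] * n_control},
        index=pd.Index(cols, name="sample_id"),
    )
    return ExpressionStudy(name=name, matrix=matrix, samples=samples, design="unpaired")


def make_paired_study(n_genes=20, n_subjects=6, seed=0, name="toy_paired") -> ExpressionStudy:
    rng = np.random.default_rng(seed)
    X = rng.normal(8.0, 1.0, size=(n_genes, 2 * n_subjects))
    cols = [f"s{j}_{tp}" for j in range(n_subjects) for tp in ("early", "late")]
    matrix = pd.DataFrame(X, index=[f"G{i:03d}" for i in range(n_genes)], columns=cols)
    samples = pd.DataFrame(
        {
            "subject": [f"s{j}" for j in range(n_subjects) for _ in range(2)],
            "timepoint": ["early", "late"] * n_subjects,
        },
        index=pd.Index(cols, name="sample_id"),
    )
    return ExpressionStudy(name=name, matrix=matrix, samples=samples, design="paired")


def null_design(n_genes=2000, n_case=20, n_control=20, seed=0, set_sizes=(100,),
                studies=("s1",)) -> SyntheticDesign:
    """No effects, no hub structure: pure-noise cohorts with labelled sets."""
    sets, start = [], 0
    for i, size in enumerate(set_sizes):
        sets.append(GeneSetSpec(f"set{i}", list(range(start, start + size))))
        start += size
    return SyntheticDesign(
        n_genes=n_genes,
        studies=[StudySpec(s, "unpaired", n_case=n_case, n_control=n_control)
                 for s in studies],
        gene_sets=sets,
        seed=seed,
    )


def planted_design(
    n_genes=500, set_size=100, effect=0.8, n_case=20, n_control=20, seed=0,
    n_hubs=0, rho_hub=0.0, rho_nonhub=0.0, effect_scope="all", dispersion=0.6,
    studies=("s1", "s2"), direction=1,
) -> SyntheticDesign:
    return SyntheticDesign(
        n_genes=n_genes,
        studies=[StudySpec(s, "unpaired", n_case=n_case, n_control=n_control)
                 for s in studies],
        gene_sets=[
            GeneSetSpec("set0", list(range(set_size)), direction=direction,
                        effect_size=effect, n_hubs=n_hubs, rho_hub=rho_hub,
                        rho_nonhub=rho_nonhub, effect_scope=effect_scope)
        ],
        effect_dispersion=dispersion,
        seed=seed,
    )


@pytest.fixture
def unpaired_study():
    return make_unpaired_study()


@pytest.fixture
def paired_study():
    return make_paired_study()


@pytest.fixture
def three_sets():
    return GeneSetCollection(
        sets={
            "A": [f"G{i:03d}" for i in range(0, 6)],
            "B": [f"G{i:03d}" for i in range(6, 12)],
            "C": [f"G{i:03d}" for i in range(12, 18)],
        }
    )
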