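import numpy as np
import pytest

from stagespec.expression import ExpressionMatrix, GroupScheme, SampleGroup


@pytest.fixture
def oyster_scheme() -> GroupScheme:
    """Three-group scheme with the default 0.20/0.70 thresholds."""
    return GroupScheme(
        groups=(
            SampleGroup("pediveliger", ("P1", "P2"), "reference"),
            SampleGroup("late_umbo", ("LU1", "LU2"), "relaxed"),
            SampleGroup("other", ("E", "U1", "S", "J", "Gill", "Mantle"), "strict"),
        )
    )


@pytest.fixture
def oyster_samples(oyster_scheme) -> list[str]:
    return list(oyster_scheme.all_samples())


def make_matrix(gene_rows: dict[str, list[float]], samples: list[str]) -> ExpressionMatrix:
    values = np.array(list(gene_rows.values()), dtype=float).reshape(
        len(gene_rows), len(samples)
    )
    return ExpressionMatrix.from_arrays(
        gene_ids=list(gene_rows), sample_ids=samples, values=values
    )


def random_matrix(
    rng: np.random.Generator, n_genes: int, samples: list[str], zero_fraction: float = 0.2
) -> ExpressionMatrix:
    """Random non-negative matrix with a sprinkling of exact zeros."""
    values = rng.uniform(0.0, 100.0, size=(n_genes, len(samples)))
    values[rng.uniform(size=values.shape) < zero_fraction] = 0.0
    return ExpressionMatrix.from_arrays(
        gene_ids=[f"G{i:04d}" for i in range(n_genes)],
        sample_ids=samples,
        values=values,
    )
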