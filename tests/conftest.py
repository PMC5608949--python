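import numpy as np
import pandas as pd
import pytest

from fluidmap.datatypes import AnnotationTable, IntensityMatrix, PhenotypeTable


@pytest.fixture
def tiny_matrix() -> IntensityMatrix:
    """3 samples x 2 features with one missing entry, two run days."""
    values = pd.DataFrame(
        {"m1": [2.0, 4.0, 6.0], "m2": [1.0, np.nan, 3.0]},
        index=["s1", "s2", "s3"],
    )
    runday = pd.Series(["d1", "d1", "d2"], index=values.index)
    fluid = pd.Series(["P", "U"], index=values.columns)
    return IntensityMatrix(values, runday, fluid)


@pytest.fixture
def small_annotations() -> AnnotationTable:
    t = pd.DataFrame(
        {
            "fluid": ["P", "P", "U", "U", "S"],
            "sub_pathway": ["Lysolipid", "Lysolipid", "Sterol", None, "TCA Cycle"],
            "super_pathway": ["Lipid", "Lipid", "Lipid", None, "Energy"],
        },
        index=["m1", "m2", "u1", "u2", "s1"],
    )
    return AnnotationTable(t)


@pytest.fixture
def gaussian_phenotypes() -> PhenotypeTable:
    rng = np.random.default_rng(0)
    n = 40
    t = pd.DataFrame(
        {
            "P": rng.standard_normal(n),
            "age": rng.normal(50, 10, n),
            "gender": rng.integers(0, 2, n).astype(float),
            "BMI": rng.normal(27, 4, n),
        },
        index=[f"s{i:03d}" for i in range(n)],
    )
    return PhenotypeTable(t, "P")
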