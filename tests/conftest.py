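import numpy as np
import pandas as pd
import pytest

from autoplot import MeasurementTable, SampleDesign


def make_table(values: dict[str, dict[str, float]], rt: float | None = None
               ) -> MeasurementTable:
    """Build a MeasurementTable from {compound: {sample: intensity}} (NaN for
    missing)."""
    rows = []
    for compound, per_sample in values.items():
        for sample, intensity in per_sample.items():
            rows.append((compound, np.nan if rt is None else rt, sample, intensity))
    return MeasurementTable(
        pd.DataFrame(rows, columns=["compound", "rt", "sample_id", "intensity"]),
        "other_list",
    )


def make_design(conditions: dict[str, list[str]],
                correction: dict[str, float] | None = None,
                experimental: dict[str, str] | None = None,
                technical: dict[str, str] | None = None) -> SampleDesign:
    """Build a SampleDesign from {condition: [sample ids]}."""
    rows = []
    for order, (condition, samples) in enumerate(conditions.items(), start=1):
        for sample in samples:
            rows.append(
                {
                    "sample_id": sample,
                    "condition": condition,
                    "order": order,
                    "colour": None,
                    "experimental_replicate": (experimental or {}).get(sample),
                    "technical_replicate": (technical or {}).get(sample),
                    "correction_value": (correction or {}).get(sample),
                    "include": True,
                }
            )
    return SampleDesign(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def quant_fixture(tmp_path_factory):
    """A written-to-disk quantitative dataset with technical replicates and
    injected missing values."""
    from autoplot import FixtureSpec, generate_fixture

    spec = FixtureSpec(n_compounds=8, n_conditions=3,
                       n_experimental_replicates=4, n_technical_replicates=2,
                       missing_rate=0.1, seed=7)
    out = tmp_path_factory.mktemp("quant_fixture")
    return generate_fixture(spec, "other_list", out)


@pytest.fixture(scope="session")
def tracing_fixture(tmp_path_factory):
    """A written-to-disk tracing dataset with known ground-truth MIDs."""
    from autoplot import FixtureSpec, generate_fixture

    spec = FixtureSpec(n_compounds=6, tracing=True, missing_rate=0.0,
                       noise_sigma=0.02, seed=11)
    out = tmp_path_factory.mktemp("tracing_fixture")
    return generate_fixture(spec, "other_list", out)
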