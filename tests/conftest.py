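import numpy as np
import pandas as pd
import pytest

from ephygraze.core_io import (CountMatrix, MicrocosmDesign, OtuTable,
                               SampleMeta, load_table1_taxa,
                               taxon_records_from_table1)


@pytest.fixture(scope="session")
def table1():
    """Bundled 28-taxon microplankton reference table."""
    return load_table1_taxa()


@pytest.fixture(scope="session")
def table1_records():
    return taxon_records_from_table1()


@pytest.fixture
def design():
    return MicrocosmDesign()


def make_samples():
    samples = [SampleMeta(f"T0_{r}", "T0", "control", r) for r in (1, 2, 3)]
    samples += [SampleMeta(f"T24_C{r}", "T24", "control", r) for r in (1, 2, 3)]
    samples += [SampleMeta(f"T24_E{r}", "T24", "treatment", r) for r in (1, 2, 3)]
    return samples


@pytest.fixture
def simple_counts():
    """Two-taxon microcosm with known trajectories: taxon 'a' halves in the
    treatments (g = ln2 at k = 0), taxon 'b' is identical everywhere."""
    samples = make_samples()
    data = pd.DataFrame(
        {s.sample_id: [100.0, 40.0] for s in samples}, index=["a", "b"])
    for s in samples:
        if s.condition == "treatment" and s.timepoint == "T24":
            data.loc["a", s.sample_id] = 50.0
    return CountMatrix(data, samples)


@pytest.fixture
def small_otu_table():
    samples = [SampleMeta(f"s{i}", "T0", "control", i) for i in (1, 2, 3)]
    counts = pd.DataFrame({"s1": [50, 30, 20], "s2": [10, 60, 30], "s3": [5, 5, 90]},
                          index=["o1", "o2", "o3"])
    lineages = pd.Series({"o1": "Eukaryota;Alveolata;Ciliophora",
                          "o2": "Eukaryota;Stramenopiles;Bacillariophyta",
                          "o3": "Eukaryota;Metazoa;Arthropoda"})
    return OtuTable(counts, lineages, samples)
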