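"""Shared fixtures: one small synthetic study reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from methylscape.annotation import Annotation, FeatureIndex, Gene, Transposon
from methylscape.calling import MethylationCallingModel, merge_replicates
from methylscape.simulate import (
    CONTROL_LABEL,
    SimulationConfig,
    simulate_annotation,
    simulate_bisulfite_counts,
    simulate_genome,
)


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def study(sim_config):
    """Genome, annotation, counts and truth of one seeded synthetic study."""
    genome = simulate_genome(sim_config)
    annotation = simulate_annotation(sim_config, genome)
    control_tables, truth = simulate_bisulfite_counts(
        sim_config, genome, annotation, CONTROL_LABEL
    )
    treatment_tables, _ = simulate_bisulfite_counts(
        sim_config, genome, annotation, "treatment"
    )
    return {
        "config": sim_config,
        "genome": genome,
        "annotation": annotation,
        "control_tables": control_tables,
        "treatment_tables": treatment_tables,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def merged_calls(study):
    """Merged-replicate call sets for both conditions."""
    out = {}
    for cond, key in ((CONTROL_LABEL, "control_tables"), ("treatment", "treatment_tables")):
        reps = [
            MethylationCallingModel(t, sample_id=f"{cond}_rep{i}", condition=cond).fit()
            for i, t in enumerate(study[key], start=1)
        ]
        out[cond] = merge_replicates(reps[0], reps[1])
    return out


@pytest.fixture(scope="session")
def toy_index() -> FeatureIndex:
    """A hand-built annotation whose categories are easy to reason about.

    chrA (20 kb): plus-strand two-exon gene at [5000, 8000) with intron
    [6000, 6500), a minus-strand single-exon gene at [12000, 14000), and a
    TE at [17000, 17800).
    """
    ann = Annotation(
        chrom_lengths={"chrA": 20_000},
        genes=[
            Gene("gplus", "chrA", 5000, 8000, "+", [(5000, 6000), (6500, 8000)]),
            Gene("gminus", "chrA", 12000, 14000, "-", [(12000, 14000)]),
        ],
        tes=[Transposon("te1", "chrA", 17000, 17800)],
    )
    return FeatureIndex(ann)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
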