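import numpy as np
import pytest

from nascentarch.pipeline import PipelineInputs, run_pipeline
from nascentarch.synthetic_data import PRESETS, SimulationConfig, simulate


def pipeline_inputs(sim):
    return PipelineInputs(
        annotation=sim.annotation,
        peaks=sim.peaks,
        tracks=sim.tracks,
        acrs=sim.acrs,
        te_intervals=sim.te_intervals,
        transcripts=sim.transcripts,
        de_tables=sim.de_tables,
        mutant_samples=list(sim.config.mutants),
    )


@pytest.fixture(scope="session")
def micro_sim():
    return simulate(SimulationConfig(seed=7, **PRESETS["micro"]))


@pytest.fixture(scope="session")
def micro_result(micro_sim):
    return run_pipeline(pipeline_inputs(micro_sim), null_draws=500, null_seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
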