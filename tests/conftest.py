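import numpy as np
import pytest
from hypothesis import settings

from ecocline.pipeline import PipelineConfig, load_report, run_pipeline
from ecocline.simulate import desk_spec

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: the three study seeds used for every desk-scale phenomenology comparison
DESK_SEEDS = (101, 102, 103)

#: desk-scale scenario grid: matched tract lengths across scenarios
DESK_SCENARIOS = {
    "neutral": dict(scenario="neutral", tract="intermediate"),
    "selective": dict(scenario="selective_uniform", tract="intermediate"),
    "selective_high": dict(scenario="selective_uniform", tract="high"),
    "gamma": dict(scenario="selective_gamma", tract="intermediate"),
    "stepping": dict(scenario="stepping_stone", tract="intermediate"),
}


@pytest.fixture(scope="session")
def desk_runs(tmp_path_factory):
    """Desk-scale pipeline runs (N=500, L=100 kb, 2,000 generations) for the
    scenario grid at the three study seeds; maps (name, seed) to a dict with
    the run report and run directory."""
    base = tmp_path_factory.mktemp("desk_runs")
    runs = {}
    for name, kw in DESK_SCENARIOS.items():
        for seed in DESK_SEEDS:
            spec = desk_spec(kw["scenario"], tract=kw["tract"], seed=seed)
            out = base / f"{name}_{seed}"
            run_pipeline(PipelineConfig(spec=spec, out_dir=out, preset="desk"))
            runs[(name, seed)] = {"report": load_report(out), "dir": out}
    return runs


@pytest.fixture(scope="session")
def tiny_run(tmp_path_factory):
    """A fast, fully-featured pipeline run for smoke/round-trip tests."""
    spec = desk_spec(
        "selective_uniform",
        seed=7,
        genome_length=20_000,
        pop_size=60,
        mutation_rate=5e-5,
        hgt_tract_length=500,
        generations=300,
        selection_start=151,
    )
    out = tmp_path_factory.mktemp("tiny") / "run"
    run_pipeline(PipelineConfig(spec=spec, out_dir=out, preset="desk"))
    return {"spec": spec, "dir": out, "report": load_report(out)}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
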