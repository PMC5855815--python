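import pytest

from aposenet.simulate import SimulationConfig, generate_bundle, write_bundle


@pytest.fixture(scope="session")
def bundle():
    """One synthetic bundle, default study conditions, fixed seed."""
    return generate_bundle(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    """The same bundle written to disk as the pipeline's file inputs."""
    d = tmp_path_factory.mktemp("bundle")
    paths = write_bundle(bundle, d)
    return {k: str(v) for k, v in paths.items()}


@pytest.fixture
def pipeline_config(bundle_dir, tmp_path):
    from aposenet.pipeline import PipelineConfig

    return PipelineConfig(
        peaks=bundle_dir["peaks"],
        chip=bundle_dir["chip"],
        input=bundle_dir["input"],
        aerbs=bundle_dir["aerbs"],
        genes=bundle_dir["genes"],
        de_sirna=bundle_dir["de_sirna"],
        de_e2=bundle_dir["de_e2"],
        pairs=[bundle_dir["pairs"]],
        out_dir=str(tmp_path / "out"),
    )
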