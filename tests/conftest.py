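import pytest

from hydrotrait import pipeline, synthetic


ZERO_NOISE = dict(sigma_js_rel=0.0, sigma_gs=0.0, sigma_la=0.0)


@pytest.fixture(scope="session")
def zero_noise_config():
    return synthetic.default_config(seed=7, **ZERO_NOISE)


@pytest.fixture(scope="session")
def zero_noise_campaign(zero_noise_config):
    return synthetic.simulate_campaign(zero_noise_config)


@pytest.fixture(scope="session")
def noisy_campaign():
    return synthetic.simulate_campaign(synthetic.default_config(seed=11))


@pytest.fixture()
def pipeline_config(tmp_path):
    return pipeline.PipelineConfig(output_dir=str(tmp_path / "out"),
                                   seed=3, n_boot=100)
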