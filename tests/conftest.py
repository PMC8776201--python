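import pytest

import glucodyn as gd


@pytest.fixture(scope="session")
def hyper_preset():
    return gd.severity_preset("hyperglycaemic")


@pytest.fixture(scope="session")
def noiseless_hyper(hyper_preset):
    p = hyper_preset
    return gd.generate_dataset(p.model_id, p.params, p.init, p.times,
                               noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def noisy_hyper(hyper_preset):
    p = hyper_preset
    return gd.generate_dataset(p.model_id, p.params, p.init, p.times,
                               noise_sd=10.0, seed=7)


@pytest.fixture(scope="session")
def fitted_hyper(hyper_preset, noisy_hyper):
    """One fitted calibrator shared across tests (short but mixed chain)."""
    est = gd.GlucoseModelCalibrator(
        model_id=1, fixed_params=hyper_preset.params,
        init_state=hyper_preset.init, chain_length=2500, random_state=5,
    )
    est.fit(noisy_hyper.times, noisy_hyper.glucose)
    return est


@pytest.fixture()
def blowup_params():
    """β-cell parameters whose trajectory overflows (integration failure)."""
    return gd.Model2Parameters(a=45.0, b=0.13, f=1.0, i=0.0, h=1.0,
                               e=1e30, c=0.0)
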