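import numpy as np
import pytest

from nbcall import AlterationKey, SampleCounts, SitePileup


def nb_draw(rng, mu, sigma, size):
    """Reference NB sampler (Var = mu + sigma*mu^2)."""
    if sigma < 1e-8:
        return rng.poisson(mu, size)
    n = 1.0 / sigma
    p = 1.0 / (1.0 + sigma * mu)
    return rng.negative_binomial(n, p, size)


def make_site(
    rng,
    n=50,
    dp=5000,
    e=1e-3,
    sigma=0.1,
    spike_idx=(),
    spike_vaf=0.1,
    pos=100,
    ref="G",
    alt="T",
):
    """One alteration with NB error counts and optional binomial spikes."""
    ao = nb_draw(rng, e * dp, sigma, n)
    for i in spike_idx:
        ao[i] = rng.binomial(dp, spike_vaf + e * (1 - spike_vaf))
    key = AlterationKey("chr1", pos, ref, alt)
    half = dp // 2
    samples = []
    for i in range(n):
        a = int(min(ao[i], dp))
        af = min(a // 2, half)
        samples.append(
            SampleCounts(f"s{i:03d}", dp_fwd=half, dp_rev=dp - half, ao_fwd=af, ao_rev=a - af)
        )
    return SitePileup(key, samples)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_site(rng):
    return make_site(rng, n=100, dp=5000, e=1e-3, sigma=0.1)
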