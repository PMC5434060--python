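import numpy as np
import pytest

from thermoscreen.containers import GenotypeMatrix


def make_panel(
    gt,
    samples=None,
    gq=60,
    dp=10,
    site_qual=50.0,
    alt=None,
    chrom=None,
    pos=None,
):
    """Build a GenotypeMatrix from a sites-x-samples dosage array."""
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_samples = gt.shape
    samples = samples or [f"s{i+1}" for i in range(n_samples)]
    return GenotypeMatrix(
        samples=list(samples),
        chrom=np.asarray(
            chrom if chrom is not None else ["c"] * n_sites, dtype=object
        ),
        pos=np.asarray(pos if pos is not None else np.arange(1, n_sites + 1)),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.asarray(alt if alt is not None else ["T"] * n_sites, dtype=object),
        gt=gt,
        gq=np.broadcast_to(np.asarray(gq), gt.shape).copy().astype(int),
        dp=np.broadcast_to(np.asarray(dp), gt.shape).copy().astype(int),
        site_qual=np.broadcast_to(np.asarray(site_qual, dtype=float), (n_sites,)).copy(),
    )


@pytest.fixture(scope="session")
def screen_data():
    """One modest end-to-end synthetic scenario shared across tests."""
    from thermoscreen import syndata

    return syndata.simulate_screen_dataset(syndata.ScreenSimConfig(seed=7))
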