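import warnings

import numpy as np
import pytest

from phenoscreen.pipeline import summarize_all
from phenoscreen.plate_io import assemble_curves, blank_correct
from phenoscreen.simulate import SimConfig, simulate_plate

NOISELESS = dict(noise_sigma_mult=0.0, noise_sd_add=0.0)


def simulate_replicates(specs, n_replicates=2, seed=0, **cfg_kwargs):
    """Plate curves for the given specs across replicates (blank-corrected)."""
    cfg = SimConfig(n_replicates=n_replicates, seed=seed, **cfg_kwargs)
    curves = []
    for r in range(n_replicates):
        rng = np.random.default_rng([seed, r])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            layout, plates = simulate_plate(specs, cfg, replicate_id=f"R{r+1}", rng=rng)
        curves += assemble_curves([blank_correct(p, layout) for p in plates], layout)
    return curves


@pytest.fixture(scope="session")
def control_summaries():
    """Noiseless 2-replicate control plate, fitted and aggregated."""
    curves = simulate_replicates([], n_replicates=2, seed=1, **NOISELESS)
    fits, summaries = summarize_all(curves)
    return fits, summaries
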