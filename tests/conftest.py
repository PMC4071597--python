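import numpy as np
import pytest

import msderep as M


@pytest.fixture(scope="session")
def fixture_library():
    return M.make_fixture_library(0)


@pytest.fixture(scope="session")
def fixture_comps():
    return M.fixture_compounds(0)


@pytest.fixture(scope="session")
def positive_run(fixture_comps):
    """Positive-mode auto-MS/MS run over the scenario compounds."""
    pos = [
        c for c in fixture_comps.values()
        if not all(l.endswith("-") for l in c.adduct_ratios)
    ]
    recipe = M.RunRecipe(
        compounds=pos, scan_interval=0.5, noise_level=200.0, seed=1
    )
    run, truth = M.simulate_run(recipe)
    return run, truth


@pytest.fixture(scope="session")
def negative_run(fixture_comps):
    """Negative-mode run spiking well-separated isobar-panel compounds.

    The panel members at 2.80/3.74/3.85/3.87 min co-elute closely enough
    with their neighbours that their auto-MS/MS events at the shared
    precursor m/z fuse into mixed groups (the known failure mode of
    integrating overlapping isomer peaks), so the spiked subset keeps the
    elution windows disjoint.
    """
    names = ["3,5-dihydroxybenzoic acid", "Patulin", "Terreic acid"]
    comps = [fixture_comps[n] for n in names]
    recipe = M.RunRecipe(
        compounds=comps, scan_interval=0.5, noise_level=200.0,
        polarity="negative", seed=2,
    )
    run, truth = M.simulate_run(recipe)
    return run, truth


def gaussian_ms1_run(compounds, *, noise=0.0, ceiling=float("inf"),
                     interval=0.5, seed=0, polarity="positive", **kw):
    recipe = M.RunRecipe(
        compounds=list(compounds), scan_interval=interval, noise_level=noise,
        detector_ceiling=ceiling, dda=None, polarity=polarity, seed=seed, **kw
    )
    return M.simulate_run(recipe)


def simple_compound(name="X", formula="C20H30O5", rt=2.0, response=1e6,
                    sigma=0.05, adducts=None):
    return M.SyntheticCompound(
        name=name, formula=M.parse_formula(formula), rt=rt,
        peak_sigma=sigma, response=response,
        adduct_ratios=adducts or {"[M+H]+": 1.0},
    )
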