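import numpy as np
import pytest

import dielmat as dm


@pytest.fixture
def geometry():
    return dm.DEFAULT_GEOMETRY


@pytest.fixture
def scenario():
    """Noise-free study-condition scenario."""
    return dm.ScenarioConfig(seed=0)


@pytest.fixture
def printed_table2():
    """The published balance-table inputs (mmol m⁻², SD in parens)."""
    return {
        "fixed_c": {"day": (-121.4, 10.3), "night": (77.5, 6.9)},
        "glycogen": {"day": (21.2, 25.2), "night": (-31.6, 30.4)},
        "net": {"acetate": (14.9, 0.9), "formate": (8.3, 1.2),
                "propionate": (2.4, 0.5), "h2": (0.83, 0.05)},
        "total": {"acetate": (28.0, 1.3), "formate": (10.0, 1.0),
                  "propionate": (6.6, 1.2), "h2": (1.77, 0.18)},
        # e− column as printed (computed from unrounded fluxes)
        "e_column": {"fixed_c": 397.9, "glycogen": 633.8,
                     "net": {"acetate": 119.2, "formate": 8.3,
                             "propionate": 31.7, "h2": 1.66},
                     "total": {"acetate": 224.2, "formate": 10.0,
                               "propionate": 85.3, "h2": 3.55}},
    }


def make_flux(species, phase, value, sd=0.0, n=1, treatment="control"):
    return dm.AreaFlux(species=species, phase=phase, flux_mmol_m2=value,
                       sd_mmol_m2=sd, n_replicates=n, treatment=treatment)


@pytest.fixture
def printed_balance_inputs(printed_table2):
    """Table inputs as AreaFlux objects, ready for build_balance_table."""
    t2 = printed_table2
    fixed = (make_flux("dic", "day", *t2["fixed_c"]["day"]),
             make_flux("dic", "night", *t2["fixed_c"]["night"]))
    gly = (make_flux("glycogen", "day", *t2["glycogen"]["day"]),
           make_flux("glycogen", "night", *t2["glycogen"]["night"]))
    net = {sp: make_flux(sp, "night", v, s)
           for sp, (v, s) in t2["net"].items()}
    total = {sp: make_flux(sp, "night", v, s, treatment="disruption")
             for sp, (v, s) in t2["total"].items()}
    return fixed, gly, net, total
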