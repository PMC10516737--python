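import warnings

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from nrbe.assay import (
    plating_efficiency,
    replicate_survival_fractions,
    survival_fractions,
)
from nrbe.lq import dose_at_survival, fit_lq
from nrbe.rbe import rbe_dose_partition, rbe_sf_division


def analyze_experiment(records, gamma_fraction, drop_unestimable=False):
    """Run the per-cell-line analysis on a flat record list.

    Returns a dict with, per arm, (pe, points, replicate SFs, fit, d10)
    plus both RBE estimates. Shared by unit and acceptance tests so they
    exercise the same code path as the pipeline.
    """
    out = {}
    for arm in ("gamma", "neutron_beam"):
        arm_records = [r for r in records if r.arm == arm]
        controls = [r for r in arm_records if r.dose == 0]
        irradiated = [r for r in arm_records if r.dose > 0]
        pe = plating_efficiency(controls)
        points = survival_fractions(irradiated, pe, drop_unestimable=drop_unestimable)
        rep_sfs = replicate_survival_fractions(
            irradiated, pe, drop_unestimable=drop_unestimable
        )
        fit = fit_lq(points)
        out[arm] = {
            "pe": pe,
            "pe_ratios": [c.colonies / c.cells_seeded for c in controls],
            "points": points,
            "replicate_sfs": rep_sfs,
            "fit": fit,
            "d10": dose_at_survival(fit, 0.1),
        }
    out["dose_partition"] = rbe_dose_partition(
        out["gamma"]["d10"], out["neutron_beam"]["d10"], gamma_fraction
    )
    out["sf_division"] = rbe_sf_division(
        out["neutron_beam"]["points"],
        out["gamma"]["fit"],
        out["gamma"]["d10"],
        gamma_fraction,
    )
    return out


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # low-count and SF>1 warnings are routine in noisy simulations
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
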