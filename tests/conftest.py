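import math

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, database=None, deadline=None)
settings.load_profile("deterministic")

from auxokit.growth import ODTimeSeries
from auxokit.synthetic import CommunitySpec, simulate_strain_params
from auxokit.crm import derive_params


def exponential_series(
    mu: float = 0.6,
    od0: float = 0.05,
    duration_h: float = 3.0,
    interval_h: float = 1 / 6,
    **kwargs,
) -> ODTimeSeries:
    """Noiseless exponential OD curve (no dilutions)."""
    t = np.arange(0, duration_h + 1e-9, interval_h)
    return ODTimeSeries(time_h=t, od=od0 * np.exp(mu * t), **kwargs)


def piecewise_series(
    mu: float,
    rate_after: float,
    t_break: float,
    duration_h: float = 20.0,
    od0: float = 0.05,
    interval_h: float = 1 / 6,
    **kwargs,
) -> ODTimeSeries:
    """Exponential at ``mu`` until ``t_break``, then at ``rate_after``.

    Dilution events keep the OD bounded so nothing leaves a detector range.
    """
    t = np.arange(0, duration_h + 1e-9, interval_h)
    lnod = np.where(
        t <= t_break,
        math.log(od0) + mu * t,
        math.log(od0) + mu * t_break + rate_after * (t - t_break),
    )
    # rescale into (0, 1] via periodic dilutions by factor 8 whenever ln OD
    # passes ln(od0) + k*ln(8)
    step = math.log(8.0)
    k = np.floor((lnod - math.log(od0)) / step).astype(int)
    events = []
    for kk in range(1, int(k.max()) + 1):
        if mu > 0:
            te_ln = math.log(od0) + kk * step
            if te_ln <= math.log(od0) + mu * t_break:
                te = (te_ln - math.log(od0)) / mu
            elif rate_after > 0:
                te = t_break + (te_ln - math.log(od0) - mu * t_break) / rate_after
            else:
                continue
            events.append((te, 8.0))
    od = np.exp(lnod - k * step)
    return ODTimeSeries(time_h=t, od=od, dilution_events=events, **kwargs)


@pytest.fixture(scope="session")
def community_params():
    """A fixed quantile-spaced 20-strain community with derived parameters."""
    raw = simulate_strain_params(CommunitySpec(seed=0, spacing="quantile"))
    return derive_params(raw)
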