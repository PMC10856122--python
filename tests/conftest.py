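import math

import pytest

from endodecay import BiexpParams, CohortConfig, MeanSeries, evaluate

# Fitted coefficients and donor baseline reported for the reference
# 65-eye DMEK cohort; used throughout as a realistic decay curve.
PUBLISHED = BiexpParams(a=177.5, b=-0.2298, c=1580.0, d=-0.005271)
DONOR_MEAN = 2518.46
VISIT_MONTHS = (1, 3, 6, 9, 12, 18, 24)


@pytest.fixture
def published_params() -> BiexpParams:
    return PUBLISHED


@pytest.fixture
def published_series() -> MeanSeries:
    """Noiseless mean series generated by the published curve at the visit schedule."""
    return MeanSeries(
        months=VISIT_MONTHS,
        mean_ecc=tuple(evaluate(PUBLISHED, t) for t in VISIT_MONTHS),
    )


@pytest.fixture
def fractional_params() -> BiexpParams:
    """The published curve expressed as fractions of the mean donor ECC."""
    return BiexpParams(
        a=PUBLISHED.a / DONOR_MEAN,
        b=PUBLISHED.b,
        c=PUBLISHED.c / DONOR_MEAN,
        d=PUBLISHED.d,
    )


@pytest.fixture
def shared_arm_config(fractional_params) -> CohortConfig:
    """Null cohort: both arms decay along the same fractional curve."""
    return CohortConfig(
        true_params_by_arm={
            "dmek_only": fractional_params,
            "dmek_phaco": fractional_params,
        },
        late_visit_month=None,
        late_visit_count=0,
        noise_sd=20.0,
    )


def mono_series(c=1000.0, d=-0.1, months=VISIT_MONTHS) -> MeanSeries:
    return MeanSeries(
        months=tuple(months),
        mean_ecc=tuple(c * math.exp(d * m) for m in months),
    )
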