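"""Published center-level summary statistics bundled with the package.

These are printed summary tables from a large European multicenter
cohort on diet and colorectal cancer: per recruitment center, event
counts, person-years (in thousands) and the mean and SD of dietary
fiber intake (g/day) from the dietary questionnaire, both as measured
and after linear regression calibration.  They support summary-level
analyses (ICC from published tables) and cross-checks; subject-level
data are not included and are instead emulated by
:mod:`pwemix.simulate`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_fiber_center_summary", "PUBLISHED_INTERCEPT_VC_CALIBRATED"]

#: Published random-intercept variance components (calibrated analysis)
#: from the same study: a model with individual-level covariates only
#: versus the model adding centered individual and aggregate covariates.
PUBLISHED_INTERCEPT_VC_CALIBRATED = {
    "individual_only": {"sigma2_intercept_men": 0.038, "sigma2_intercept_women": 0.053},
    "with_aggregate": {"sigma2_intercept_men": 0.020, "sigma2_intercept_women": 0.020},
}


def load_fiber_center_summary(sex: str) -> pd.DataFrame:
    """Center-level fiber summary table for ``sex`` in {"women", "men"}.

    Columns: country, center, crc_cases, person_years_1000, fiber_mean,
    fiber_sd, fiber_cal_mean, fiber_cal_sd.  Only centers with reported
    data are included (21 rows for men, 28 for women).
    """
    if sex not in ("women", "men"):
        raise ValueError("sex must be 'women' or 'men'")
    ref = resources.files("pwemix.data") / f"fiber_center_summary_{sex}.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
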