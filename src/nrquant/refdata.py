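"""Published reference tallies used as inputs to arithmetic checks.

Cohort-flow counts and one printed bivariate row from the source study's
tables; the package recomputes rates and test statistics from these
counts rather than hard-coding the published percentages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: cohort flow of the SMS-to-web survey study
STUDY_COUNTS = {
    "n_total": 6553,
    "n_responders": 1342,
    "n_measured": 2868,
}

#: cohort flow of the earlier telephone reference survey
PHONE_COUNTS = {
    "n_eligible": 3302,
    "n_complete": 1980,
}

#: printed sex row of the response bivariate table: (N, response %)
TABLE_SEX_ROW = {
    "female": (3422, 21.2),
    "male": (3131, 19.7),
}


def reconstruct_sex_records() -> pd.DataFrame:
    """Patient-level records reconstructed from the printed sex row via
    round(N x pct); suitable for re-running the association test."""
    rows = []
    for sex, (n, pct) in TABLE_SEX_ROW.items():
        k = int(round(n * pct / 100.0))
        rows.append(pd.DataFrame({
            "sex": np.repeat(sex, n),
            "responded": np.r_[np.ones(k, dtype=int),
                               np.zeros(n - k, dtype=int)],
        }))
    return pd.concat(rows, ignore_index=True)
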