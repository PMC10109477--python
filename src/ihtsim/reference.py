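"""Packaged reference summary tables from the hospital case study.

Two small CSVs ship with the package:

* ``waiting_time_summaries.csv`` — the published per-scenario waiting-time
  summaries (code, N, mean, SD in hours) for the 20-scenario experiment, the
  input to the Tukey all-pairs comparison and the pooled group CIs.
* ``validation_summaries.csv`` — the published validation summaries:
  requests/day per period, (n, mean, SE of mean) for the 13 observed days
  and the 30 simulated days, the input to the Welch validation test.

These are *inputs* (published summary statistics); every derived quantity —
differences, CIs, t statistics, adjusted p-values — is recomputed by
:mod:`ihtsim.stats`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import GroupSummary

__all__ = ["load_waiting_time_summaries", "load_validation_summaries"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("ihtsim.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_waiting_time_summaries() -> list[GroupSummary]:
    """The 20 published (code, N, mean, SD) waiting-time rows, in table order."""
    df = _read("waiting_time_summaries.csv")
    return [
        GroupSummary(r.code, int(r.n), float(r.mean), float(r.sd))
        for r in df.itertuples()
    ]


def load_validation_summaries() -> pd.DataFrame:
    """Historical-vs-simulated daily request-count summaries per period."""
    return _read("validation_summaries.csv")
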