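"""Long-format assay record schema and CSV round-trip helpers.

One row per individual x trial x trait.  Columns:

========== =======================================================
column      meaning
========== =======================================================
individual  individual identifier (string)
pool        pool-of-origin identifier (string)
group       ``naive`` or ``exposed`` (developmental predator regime)
batch       experimental batch, integer 1..5
trial       trial number, 0-based (first trial coded 0)
size        snout-vent length, mm
density     number of conspecifics in the pool of origin
trait       ``distance_moved`` (pixels) or ``time_to_emerge`` (s)
value_raw   raw measurement; distance > 0, emergence time in [0, 600]
censored    ``none``, ``right`` (at the 600 s cap) or ``left``
========== =======================================================
"""

from __future__ import annotations

import pandas as pd

TRAITS = ("distance_moved", "time_to_emerge")
GROUPS = ("naive", "exposed")
CENSOR_LEVELS = ("none", "right", "left")
CENSOR_CODE = {"none": 0, "right": 1, "left": -1}

COLUMNS = [
    "individual",
    "pool",
    "group",
    "batch",
    "trial",
    "size",
    "density",
    "trait",
    "value_raw",
    "censored",
]

#: raw-scale censoring bounds for the emergence-time assay (seconds)
TE_BOUNDS = (0.0, 600.0)


def check_columns(records: pd.DataFrame) -> None:
    missing = [c for c in COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records are missing columns: {missing}")


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={
            "individual": str,
            "pool": str,
            "group": str,
            "trait": str,
            "censored": str,
        },
    )
    check_columns(df)
    df["batch"] = df["batch"].astype(int)
    df["trial"] = df["trial"].astype(int)
    return df[COLUMNS]


def write_records(records: pd.DataFrame, path) -> None:
    check_columns(records)
    records[COLUMNS].to_csv(path, index=False)
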