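"""Dataset readers and writers (delimited text) and the PAQUID-style import.

The on-disk dataset format is a delimited text file with header columns
``entry_age, t_left, t_right, t_mid, last_age, delta1, delta2`` followed by
covariate columns.  For undiagnosed subjects the right interval bound is
written as the literal ``inf`` (an empty field is accepted on input).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = [
    "entry_age",
    "t_left",
    "t_right",
    "t_mid",
    "last_age",
    "delta1",
    "delta2",
]

# Default column mapping for the 1000-subject PAQUID sample distributed with
# the SmoothHazard R package (dementia as the non-terminal event; covariates
# sex, 1 = male, and primary-school diploma, 1 = yes).
PAQUID_COLUMN_MAP = {
    "e": "entry_age",
    "l": "t_left",
    "r": "t_right",
    "t": "last_age",
    "dementia": "delta1",
    "death": "delta2",
    "gender": "sex",
    "certif": "diploma",
}


def validate_dataset(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a dataset frame in place; raises with row indices on error."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns and c != "t_mid"]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if len(df) == 0:
        raise ValueError("dataset is empty")
    df = df.copy()
    if "t_mid" not in df.columns:
        df["t_mid"] = np.nan
    for col in ("delta1", "delta2"):
        bad = ~df[col].isin([0, 1])
        if bad.any():
            raise ValueError(
                f"column {col!r} must be 0/1; offending rows: "
                f"{df.index[bad].tolist()[:10]}"
            )
    for col in ("entry_age", "t_left", "last_age"):
        bad = ~(df[col] >= 0)
        if bad.any():
            raise ValueError(
                f"column {col!r} must be non-negative; offending rows: "
                f"{df.index[bad].tolist()[:10]}"
            )
    bad = ~(df["last_age"] > df["entry_age"])
    if bad.any():
        raise ValueError(
            "last_age must exceed entry_age; offending rows: "
            f"{df.index[bad].tolist()[:10]}"
        )
    d1 = df["delta1"] == 1
    # undiagnosed rows: interval degenerates to [last_age, inf)
    df.loc[~d1, "t_left"] = df.loc[~d1, "last_age"]
    df.loc[~d1, "t_right"] = np.inf
    df.loc[~d1, "t_mid"] = np.nan
    bad = d1 & ~(
        (df["t_left"] < df["t_right"]) & np.isfinite(df["t_right"])
    )
    if bad.any():
        raise ValueError(
            "diagnosed rows need a finite interval t_left < t_right; "
            f"offending rows: {df.index[bad].tolist()[:10]}"
        )
    need_mid = d1 & ~np.isfinite(df["t_mid"])
    df.loc[need_mid, "t_mid"] = 0.5 * (
        df.loc[need_mid, "t_left"] + df.loc[need_mid, "t_right"]
    )
    cov_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    return df[REQUIRED_COLUMNS + cov_cols]


def read_dataset(path, delimiter: str = ",") -> pd.DataFrame:
    """Read and validate a dataset file; empty/'inf' right bounds accepted."""
    df = pd.read_csv(path, sep=delimiter)
    if "t_right" in df.columns:
        df["t_right"] = pd.to_numeric(
            df["t_right"].replace({"": np.nan, "inf": np.inf}), errors="coerce"
        )
        df.loc[df["delta1"] == 0, "t_right"] = np.inf
    return validate_dataset(df)


def write_dataset(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    validate_dataset(df).to_csv(path, sep=delimiter, index=False)


def import_paquid(path, column_map=None, delimiter: str = ",") -> pd.DataFrame:
    """Import a delimited export of the SmoothHazard PAQUID sample.

    The default mapping expects columns ``e, l, r, t, dementia, death,
    gender, certif`` (entry age, interval bounds, last observed age,
    dementia and death indicators, sex, primary-school diploma).  Pass
    ``column_map`` to adapt other layouts; unknown column sets raise with
    the found vs expected names.
    """
    cmap = dict(column_map or PAQUID_COLUMN_MAP)
    raw = pd.read_csv(path, sep=delimiter)
    missing = [c for c in cmap if c not in raw.columns]
    if missing:
        raise ValueError(
            f"unexpected column set: missing {missing}; found "
            f"{list(raw.columns)}, expected {list(cmap)}"
        )
    df = raw[list(cmap)].rename(columns=cmap)
    # in this layout undiagnosed subjects have l = r = age at last visit;
    # the time of death / end of follow-up is the terminal age t
    d1 = df["delta1"] == 1
    df.loc[~d1, "t_left"] = df.loc[~d1, "last_age"]
    df.loc[~d1, "t_right"] = np.inf
    df["t_mid"] = np.where(d1, 0.5 * (df["t_left"] + df["t_right"]), np.nan)
    df = validate_dataset(df)
    n = len(df)
    males = int((df["sex"] == 1).sum())
    counts = {
        "n_subjects": n,
        "n_male": males,
        "n_female": n - males,
        "n_dementia": int((df["delta1"] == 1).sum()),
        "n_death_disease_free": int(((df["delta1"] == 0) & (df["delta2"] == 1)).sum()),
        "n_death_after_diagnosis": int(
            ((df["delta1"] == 1) & (df["delta2"] == 1)).sum()
        ),
    }
    df.attrs["summary"] = counts
    return df
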