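"""Atlas region tables (node labels for covariance networks)."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["load_atlas"]

_REQUIRED = ["region_index", "abbreviation", "full_name"]


def load_atlas(path: str | Path | None = None) -> pd.DataFrame:
    """Load an atlas table (region_index, abbreviation, full_name).

    With no argument, returns the packaged 90-region AAL cerebral atlas
    (45 regions x 2 hemispheres, abbreviations suffixed .L/.R). A user CSV
    with the same columns may describe an atlas of any size.
    """
    if path is None:
        src = resources.files("scovnet.data").joinpath("aal90.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"atlas table missing columns: {missing}")
    if df["abbreviation"].duplicated().any():
        dup = df["abbreviation"][df["abbreviation"].duplicated()].tolist()
        raise ValueError(f"duplicate atlas abbreviations: {dup}")
    return df.reset_index(drop=True)
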