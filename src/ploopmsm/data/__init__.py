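"""Packaged reference tables.

``load_motor_panel`` returns the experimentally determined duty ratios and
ADP release rates of the twelve-motor reference panel;
``load_crystal_counts`` returns the printed crystal-ensemble contingency
counts (nucleotide occupancy vs RMSD partition, and duty-ratio class vs
P-loop state for the unliganded structures).
"""

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_motor_panel() -> pd.DataFrame:
    return _read("motor_panel.csv")


def load_crystal_counts() -> pd.DataFrame:
    return _read("crystal_counts.csv")


def crystal_table(analysis: str):
    """2x2 counts for one of the packaged contingency analyses, rows in the
    order stored (outlier/low-duty group first)."""
    df = load_crystal_counts()
    sub = df[df["analysis"] == analysis]
    if len(sub) != 2:
        raise ValueError(f"unknown analysis {analysis!r}")
    return sub[["bound_or_outside", "unbound_or_inside"]].to_numpy()
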