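"""Bundled reference panel: 38 measured RNA/DNA hybrid duplexes.

The panel was measured in 100 mM NaCl buffer (10 mM Na2HPO4, 1 mM
Na2EDTA, pH 7.0) with Tm reported at 8 uM total strands.  It carries the
measured (dH, T*dS, dG37, Tm) quartets with standard errors, plus two sets
of reference predictions: the global-salt-correction route from the 1 M
NaCl parameters ("old") and the bundled 100 mM NN set ("new").  Eight
label pairs Xa/Xb are duplexes with identical NN stack multisets, the
panel's built-in test of the NN model's validity.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .constants import DEFAULT_CT, T37_K
from .duplex import HybridDuplex
from .predict import ThermoRecord

__all__ = [
    "load_reference_table",
    "reference_duplexes",
    "measured_records",
    "identical_nn_pairs",
    "PAIR_NUMBERS",
]

#: Label stems of the eight identical-NN duplex pairs (Xa/Xb).
PAIR_NUMBERS = ("3", "4", "14", "17", "18", "19", "22", "29")


def load_reference_table() -> pd.DataFrame:
    """The 38-duplex reference panel as a DataFrame (one row per duplex).

    Columns: label, rna, measured dh/tds/dg37 (kcal/mol, with *_err),
    tm (degC), and the printed old/new reference predictions.  A derived
    ``ds_meas`` column gives the measured entropy in cal/(mol K).
    """
    path = resources.files("hybridnn.data") / "hybrid_duplexes_100mM_NaCl.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#", dtype={"label": str})
    df["ds_meas"] = df["tds_meas"] * 1000.0 / T37_K
    df["ds_err"] = df["tds_err"] * 1000.0 / T37_K
    return df


def reference_duplexes(df: pd.DataFrame | None = None) -> list[HybridDuplex]:
    """The panel's duplexes as HybridDuplex objects, table order."""
    if df is None:
        df = load_reference_table()
    return [HybridDuplex.from_rna(r.rna, label=r.label) for r in df.itertuples()]


def measured_records(df: pd.DataFrame | None = None) -> list[ThermoRecord]:
    """Measured ThermoRecords of the panel, table order."""
    if df is None:
        df = load_reference_table()
    return [
        ThermoRecord(
            dH=r.dh_meas,
            dS=r.ds_meas,
            dG37=r.dg37_meas,
            Tm=r.tm_meas,
            Ct=DEFAULT_CT,
            sigma_dH=r.dh_err,
            sigma_dS=r.ds_err,
            sigma_dG37=r.dg37_err,
            provenance="measured",
            label=r.label,
        )
        for r in df.itertuples()
    ]


def identical_nn_pairs(
    df: pd.DataFrame | None = None,
) -> list[tuple[ThermoRecord, ThermoRecord]]:
    """The eight (Xa, Xb) measured-record pairs with identical NN stacks."""
    if df is None:
        df = load_reference_table()
    records = {r.label: r for r in measured_records(df)}
    return [(records[x + "a"], records[x + "b"]) for x in PAIR_NUMBERS]
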