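"""Nearest-neighbor parameter sets.

A parameter set holds one (dH, dS, dG37) triple per NN stack plus two
helix-initiation triples (init_GC / init_AU, selected by the terminal base
pairs of a duplex).  The bundled ``hybrid_100mM_NaCl`` set is the RNA/DNA
hybrid table at 100 mM NaCl; its initiation enthalpies are zero because
initiation is treated as entropy-controlled, and its dG37 column is an
independently fitted surface -- it is never recomputed from dH and dS
(:func:`internal_consistency_report` quantifies the difference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import pandas as pd

from .constants import T37_K
from .duplex import STACKS

__all__ = [
    "ThermoTriple",
    "NnParameterSet",
    "builtin_set",
    "available_sets",
    "load_parameter_table",
    "save_parameter_table",
    "internal_consistency_report",
    "ParameterTableError",
]

INIT_KEYS = ("init_GC", "init_AU")


class ParameterTableError(ValueError):
    """Raised when a parameter table fails validation."""


class ThermoTriple(NamedTuple):
    dH: float  # kcal/mol
    dS: float  # cal/(mol K)
    dG37: float  # kcal/mol


@dataclass(frozen=True)
class NnParameterSet:
    """16 stack triples + 2 initiation triples with provenance metadata."""

    stacks: dict[str, ThermoTriple]
    init_GC: ThermoTriple
    init_AU: ThermoTriple
    name: str = "unnamed"
    salt: str = ""
    reference: str = ""

    def __post_init__(self) -> None:
        missing = [s for s in STACKS if s not in self.stacks]
        if missing:
            raise ParameterTableError(f"missing stack entries: {missing}")
        extra = [s for s in self.stacks if s not in STACKS]
        if extra:
            raise ParameterTableError(f"unknown stack entries: {extra}")

    def entry(self, key: str) -> ThermoTriple:
        if key == "init_GC":
            return self.init_GC
        if key == "init_AU":
            return self.init_AU
        try:
            return self.stacks[key]
        except KeyError:
            raise KeyError(f"unknown stack {key!r}") from None

    def to_frame(self) -> pd.DataFrame:
        rows = [(s, *self.stacks[s]) for s in STACKS]
        rows.append(("init_GC", *self.init_GC))
        rows.append(("init_AU", *self.init_AU))
        return pd.DataFrame(rows, columns=["stack", "dH", "dS", "dG37"]).set_index(
            "stack"
        )


_BUILTIN_FILES = {
    "hybrid_100mM_NaCl": "nn_hybrid_100mM_NaCl.tsv",
}

_BUILTIN_META = {
    "hybrid_100mM_NaCl": dict(
        salt="100 mM NaCl, 10 mM Na2HPO4, 1 mM Na2EDTA, pH 7.0",
        reference="RNA/DNA hybrid NN set at physiological salt",
    ),
}


def available_sets() -> list[str]:
    return sorted(_BUILTIN_FILES)


def builtin_set(name: str = "hybrid_100mM_NaCl") -> NnParameterSet:
    """Return a bundled parameter set by name."""
    if name not in _BUILTIN_FILES:
        raise KeyError(
            f"unknown parameter set {name!r}; available: {available_sets()}"
        )
    path = resources.files("hybridnn.data") / _BUILTIN_FILES[name]
    with resources.as_file(path) as p:
        pset = load_parameter_table(p, name=name, **_BUILTIN_META[name])
    return pset


def load_parameter_table(
    path: str | Path, name: str | None = None, **meta: str
) -> NnParameterSet:
    """Load a parameter TSV (columns stack, dH, dS, dG37; '#' comments).

    Requires exactly the 16 stack rows plus init_GC and init_AU; duplicates,
    missing rows and non-numeric values are rejected with the row named.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"stack": str})
    except Exception as exc:  # noqa: BLE001 - surface parse context
        raise ParameterTableError(f"cannot parse {path}: {exc}") from exc
    required_cols = {"stack", "dH", "dS", "dG37"}
    if not required_cols <= set(df.columns):
        raise ParameterTableError(
            f"{path}: header must contain {sorted(required_cols)}, "
            f"got {list(df.columns)}"
        )
    # normalize unicode minus from copy-pasted tables
    for col in ("dH", "dS", "dG37"):
        if df[col].dtype == object:
            df[col] = df[col].astype(str).str.replace("−", "-", regex=False)
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ParameterTableError(f"{path}: non-numeric {col}: {exc}") from exc
    dup = df["stack"][df["stack"].duplicated()]
    if len(dup):
        raise ParameterTableError(f"{path}: duplicate rows for {sorted(set(dup))}")
    table = {r.stack: ThermoTriple(r.dH, r.dS, r.dG37) for r in df.itertuples()}
    missing_stacks = [s for s in STACKS if s not in table]
    if missing_stacks:
        raise ParameterTableError(
            f"{path}: 16 stack rows required; missing {missing_stacks}"
        )
    for key in INIT_KEYS:
        if key not in table:
            raise ParameterTableError(f"{path}: missing initiation row {key}")
    unknown = sorted(set(table) - set(STACKS) - set(INIT_KEYS))
    if unknown:
        raise ParameterTableError(f"{path}: unknown rows {unknown}")
    return NnParameterSet(
        stacks={s: table[s] for s in STACKS},
        init_GC=table["init_GC"],
        init_AU=table["init_AU"],
        name=name or path.stem,
        **meta,
    )


def save_parameter_table(pset: NnParameterSet, path: str | Path) -> None:
    """Write a parameter set in the TSV dialect read by load_parameter_table."""
    path = Path(path)
    with path.open("w") as f:
        f.write(f"# {pset.name}")
        if pset.salt:
            f.write(f" ({pset.salt})")
        f.write("\n# Units: dH kcal/mol, dS cal/(mol K), dG37 kcal/mol.\n")
        f.write("stack\tdH\tdS\tdG37\n")
        for key, triple in [*pset.stacks.items(), ("init_GC", pset.init_GC), ("init_AU", pset.init_AU)]:
            f.write(f"{key}\t{triple.dH:g}\t{triple.dS:g}\t{triple.dG37:g}\n")


def internal_consistency_report(pset: NnParameterSet, T: float = T37_K) -> pd.DataFrame:
    """Signed discrepancy dG37 - (dH - T*dS/1000) per entry, kcal/mol.

    Diagnostic only: for an independently fitted dG37 column (like the
    bundled set's) the discrepancies are small but nonzero, and distinctly
    nonzero for the initiation terms.  No pass/fail judgment is made.
    """
    df = pset.to_frame()
    df["dG37_from_HS"] = df["dH"] - T * df["dS"] / 1000.0
    df["discrepancy"] = df["dG37"] - df["dG37_from_HS"]
    return df
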