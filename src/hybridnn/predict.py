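"""Thermodynamic prediction for hybrid duplexes.

The NN model writes each quantity as a sum over adjacent base-pair stacks
plus a helix-initiation term chosen by the terminal base pairs:

    dX_pred = sum_i dX_NN(stack_i) + dX_init,   X in {H, S, G37}

The melting temperature of a non-self-complementary bimolecular duplex at
total strand concentration Ct follows

    1/Tm = R ln(Ct/4) / dH + dS / dH            (Tm in kelvin)

Two entropy conventions are supported when computing Tm from a parameter
set whose dG37 column is an independent fit (as the bundled one is):

* ``dg_consistent`` (default): dS = (dH_pred - dG37_pred) * 1000 / 310.15,
  which keeps the (dH, dS, dG37) triple thermodynamically consistent and
  reproduces the reference predictions;
* ``stack_entropy``: dS is the plain NN sum of the dS column.  The two
  modes genuinely disagree (by ~2-4 degC for the bundled set) because the
  dS and dG37 columns were fitted independently.

Affine salt-correction models map stabilities measured at 1 M NaCl to
100 mM NaCl, either globally or per salt-response group (A/B/C; dG37 only).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .constants import DEFAULT_CT, KELVIN_OFFSET, R_CAL, T37_K
from .duplex import HybridDuplex, decompose, init_class, InitClass, SaltGroup
from .parameters import NnParameterSet

__all__ = [
    "ThermoRecord",
    "TmMode",
    "predict_thermo",
    "consistent_entropy",
    "predict_tm",
    "predict_record",
    "LinearSaltModel",
    "GLOBAL_DG37",
    "GLOBAL_TM",
    "GROUP_DG37",
    "salt_correct_dg37",
    "salt_correct_tm",
    "error_stats",
    "pair_concordance",
]


@dataclass(frozen=True)
class ThermoRecord:
    """A duplex's thermodynamic quartet, measured or predicted.

    dH and dG37 in kcal/mol, dS in cal/(mol K), Tm in degC at the stated Ct.
    """

    dH: float
    dS: float
    dG37: float
    Tm: float
    Ct: float = DEFAULT_CT
    sigma_dH: float | None = None
    sigma_dS: float | None = None
    sigma_dG37: float | None = None
    provenance: str = "measured"
    label: str | None = None

    def __post_init__(self) -> None:
        if self.Ct <= 0:
            raise ValueError("Ct must be positive")


class TmMode(enum.Enum):
    DG_CONSISTENT = "dg_consistent"
    STACK_ENTROPY = "stack_entropy"


def predict_thermo(
    duplex: HybridDuplex, pset: NnParameterSet
) -> tuple[float, float, float]:
    """NN sums (dH_pred, dS_stacksum, dG37_pred) including initiation."""
    init = pset.entry(f"init_{init_class(duplex).value}")
    dh = init.dH
    ds = init.dS
    dg = init.dG37
    for stack in decompose(duplex):
        t = pset.stacks[stack]
        dh += t.dH
        ds += t.dS
        dg += t.dG37
    return dh, ds, dg


def consistent_entropy(dH_pred: float, dG37_pred: float) -> float:
    """Entropy (cal/(mol K)) making (dH, dS, dG37) satisfy dG = dH - T dS."""
    return (dH_pred - dG37_pred) / T37_K * 1000.0


def predict_tm(dH: float, dS: float, Ct: float = DEFAULT_CT) -> float:
    """Melting temperature (degC) of a bimolecular non-self-complementary
    duplex: Tm(K) = 1000 dH / (dS + R ln(Ct/4)).

    Requires dH < 0 and a negative denominator so Tm is physical.
    """
    if dH >= 0:
        raise ValueError(f"dH must be negative for duplex formation, got {dH}")
    denom = dS + R_CAL * math.log(Ct / 4.0)
    if denom >= 0:
        raise ValueError(
            f"non-physical denominator dS + R ln(Ct/4) = {denom:.3f} >= 0"
        )
    return 1000.0 * dH / denom - KELVIN_OFFSET


def predict_record(
    duplex: HybridDuplex,
    pset: NnParameterSet,
    Ct: float = DEFAULT_CT,
    tm_mode: TmMode | str = TmMode.DG_CONSISTENT,
) -> ThermoRecord:
    """Full predicted record for a duplex at concentration Ct."""
    tm_mode = TmMode(tm_mode)
    dh, ds_stack, dg = predict_thermo(duplex, pset)
    ds = consistent_entropy(dh, dg) if tm_mode is TmMode.DG_CONSISTENT else ds_stack
    return ThermoRecord(
        dH=dh,
        dS=ds,
        dG37=dg,
        Tm=predict_tm(dh, ds, Ct),
        Ct=Ct,
        provenance="predicted",
        label=duplex.label,
    )


@dataclass(frozen=True)
class LinearSaltModel:
    """Affine map value(100 mM) = slope * value(1 M) + intercept."""

    slope: float
    intercept: float
    quantity: str  # "dG37" or "Tm"
    scope: str  # "global" or "A"/"B"/"C"

    def __call__(self, value_1M: float) -> float:
        return self.slope * value_1M + self.intercept


GLOBAL_DG37 = LinearSaltModel(0.63, -1.667, "dG37", "global")
GLOBAL_TM = LinearSaltModel(0.876, -5.148, "Tm", "global")
GROUP_DG37 = {
    SaltGroup.A: LinearSaltModel(0.698, -2.065, "dG37", "A"),
    SaltGroup.B: LinearSaltModel(0.662, -0.682, "dG37", "B"),
    SaltGroup.C: LinearSaltModel(0.664, -1.637, "dG37", "C"),
}


def salt_correct_dg37(dg37_1M: float, group: SaltGroup | None = None) -> float:
    """Map dG37 at 1 M NaCl to 100 mM NaCl.

    With ``group=None`` the global model applies; otherwise the
    group-specific model for the duplex's salt-response class.
    """
    model = GLOBAL_DG37 if group is None else GROUP_DG37[SaltGroup(group)]
    return model(dg37_1M)


def salt_correct_tm(tm_1M: float, group: SaltGroup | None = None) -> float:
    """Map Tm (degC) at 1 M NaCl to 100 mM NaCl (global model only).

    Group-specific Tm corrections are not defined by the model and raise.
    """
    if group is not None:
        raise ValueError("group-specific salt correction exists only for dG37")
    return GLOBAL_TM(tm_1M)


def error_stats(
    measured: Sequence[ThermoRecord], predicted: Sequence[ThermoRecord]
) -> dict[str, float]:
    """Mean prediction errors over paired records.

    Percentage errors are |measured - predicted| / |predicted| * 100
    (relative to the predicted value); Tm error is the mean absolute
    deviation in degC.  Means are unweighted.
    """
    if len(measured) != len(predicted):
        raise ValueError(
            f"length mismatch: {len(measured)} measured vs {len(predicted)} predicted"
        )
    if not measured:
        raise ValueError("empty input")

    def pct(attr: str) -> float:
        m = np.array([getattr(r, attr) for r in measured], dtype=float)
        p = np.array([getattr(r, attr) for r in predicted], dtype=float)
        return float(np.mean(np.abs(m - p) / np.abs(p)) * 100.0)

    tm_m = np.array([r.Tm for r in measured], dtype=float)
    tm_p = np.array([r.Tm for r in predicted], dtype=float)
    return {
        "dG37_pct": pct("dG37"),
        "Tm_abs": float(np.mean(np.abs(tm_m - tm_p))),
        "dH_pct": pct("dH"),
        "dS_pct": pct("dS"),
    }


def pair_concordance(
    pairs: Sequence[tuple[ThermoRecord, ThermoRecord]]
) -> dict[str, float]:
    """Concordance statistics for identical-NN duplex pairs.

    Percentage difference per pair uses the mean-magnitude denominator
    |a - b| / ((|a| + |b|)/2) * 100 for dH, T*dS and dG37; Tm differences
    are absolute (degC).  T*dS is evaluated at 310.15 K in kcal/mol.
    """
    if not pairs:
        raise ValueError("empty input")

    def pct(a: float, b: float) -> float:
        return abs(a - b) / ((abs(a) + abs(b)) / 2.0) * 100.0

    dh, tds, dg, tm = [], [], [], []
    for a, b in pairs:
        dh.append(pct(a.dH, b.dH))
        tds.append(pct(T37_K * a.dS / 1000.0, T37_K * b.dS / 1000.0))
        dg.append(pct(a.dG37, b.dG37))
        tm.append(abs(a.Tm - b.Tm))
    return {
        "dH_pct": float(np.mean(dh)),
        "TdS_pct": float(np.mean(tds)),
        "dG37_pct": float(np.mean(dg)),
        "Tm_abs": float(np.mean(tm)),
    }
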