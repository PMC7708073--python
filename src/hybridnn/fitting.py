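"""Constrained linear least-squares derivation of NN parameters.

Each duplex contributes one row of a design matrix whose columns are the
16 stack counts plus two initiation indicator columns (init_GC, init_AU).
For the enthalpy fit the initiation columns are dropped: initiation is
treated as entropy-controlled, so its dH is constrained to zero and the
three quantities (dH, dS, dG37) are fitted in separate regressions.

The solver is the SVD-based least-squares routine (minimum-norm solution
when rank-deficient -- NN designs are collinearity-prone, so the rank is
always surfaced and a rank-deficient fit warns loudly).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import T37_K
from .duplex import HybridDuplex, STACKS, count_stacks, init_class
from .parameters import INIT_KEYS, NnParameterSet, ThermoTriple

__all__ = [
    "DesignMatrix",
    "FitResult",
    "build_design_matrix",
    "fit_nn",
    "fit_parameter_set",
    "propagate_dg_error",
    "frequency_balance",
    "RankDeficientWarning",
]

QUANTITIES = ("dH", "dS", "dG37")


class RankDeficientWarning(UserWarning):
    """Emitted when the design matrix does not have full column rank."""


@dataclass(frozen=True)
class DesignMatrix:
    """Duplexes-by-parameters count matrix for one fitted quantity."""

    frame: pd.DataFrame
    quantity: str

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)


@dataclass(frozen=True)
class FitResult:
    """OLS estimates for one quantity with classical standard errors."""

    quantity: str
    coefficients: pd.Series
    standard_errors: pd.Series
    residuals: np.ndarray
    rank: int
    n_observations: int

    @property
    def dof(self) -> int:
        return self.n_observations - self.rank


def build_design_matrix(
    duplexes: Sequence[HybridDuplex],
    quantity: str,
    terminal_au_column: bool = False,
) -> DesignMatrix:
    """Stack-count design matrix for the given quantity.

    For ``quantity="dH"`` the initiation columns are omitted (initiation
    enthalpy constrained to zero); otherwise both indicator columns are
    present and each row has exactly one of them set.  The optional
    ``terminal_au_column`` adds a count of rA-dT/rU-dA terminals for
    experimentation; it is off by default because it brings no improvement
    for this model.
    """
    if quantity not in QUANTITIES:
        raise ValueError(f"quantity must be one of {QUANTITIES}, got {quantity!r}")
    cols = list(STACKS) + ([] if quantity == "dH" else list(INIT_KEYS))
    if terminal_au_column:
        cols.append("terminal_AU")
    rows = np.zeros((len(duplexes), len(cols)))
    index = []
    for i, d in enumerate(duplexes):
        index.append(d.label if d.label is not None else str(d))
        counts = count_stacks(d)
        for j, s in enumerate(STACKS):
            rows[i, j] = counts.get(s, 0)
        if quantity != "dH":
            key = f"init_{init_class(d).value}"
            rows[i, cols.index(key)] = 1.0
        if terminal_au_column:
            rows[i, cols.index("terminal_AU")] = sum(
                b in "AU" for b in (d.rna[0], d.rna[-1])
            )
    return DesignMatrix(pd.DataFrame(rows, index=index, columns=cols), quantity)


def fit_nn(
    duplexes: Sequence[HybridDuplex],
    values: Sequence[float],
    quantity: str,
    weights: Sequence[float] | None = None,
    terminal_au_column: bool = False,
) -> FitResult:
    """Least-squares NN parameter fit for one thermodynamic quantity.

    ``values`` are the measured quantities in the same order as
    ``duplexes``.  Optional ``weights`` (1/sigma) enable weighted LS; the
    default is the unweighted fit.  Standard errors are classical OLS SEs,
    sqrt(diag(s^2 (X'X)^+)) with s^2 = RSS / (n - rank).
    """
    dm = build_design_matrix(duplexes, quantity, terminal_au_column)
    X = dm.values
    y = np.asarray(values, dtype=float)
    if len(y) != X.shape[0]:
        raise ValueError(f"{X.shape[0]} duplexes but {len(y)} values")
    if not np.all(np.isfinite(y)):
        raise ValueError("measured values must be finite")
    if X.shape[0] < X.shape[1]:
        raise ValueError(
            f"need at least {X.shape[1]} observations for {X.shape[1]} "
            f"parameters, got {X.shape[0]}"
        )
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        Xw, yw = X * w[:, None], y * w
    else:
        Xw, yw = X, y
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            f"design matrix rank {rank} < {X.shape[1]} columns; "
            "minimum-norm solution returned",
            RankDeficientWarning,
            stacklevel=2,
        )
    residuals = y - X @ beta
    dof = X.shape[0] - rank
    if dof > 0:
        s2 = float(residuals @ residuals) / dof if weights is None else float(
            (w * residuals) @ (w * residuals)
        ) / dof
        cov = s2 * np.linalg.pinv(Xw.T @ Xw)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    else:
        se = np.full(X.shape[1], np.nan)
    return FitResult(
        quantity=quantity,
        coefficients=pd.Series(beta, index=dm.columns),
        standard_errors=pd.Series(se, index=dm.columns),
        residuals=residuals,
        rank=int(rank),
        n_observations=X.shape[0],
    )


def fit_parameter_set(
    duplexes: Sequence[HybridDuplex],
    table: pd.DataFrame,
    name: str = "refit",
) -> tuple[NnParameterSet, dict[str, FitResult]]:
    """Fit all three quantities and assemble an NnParameterSet.

    ``table`` needs columns dH, dS, dG37 aligned with ``duplexes``.
    Initiation dH is zero by construction (the dH regression has no
    initiation columns).
    """
    fits = {
        q: fit_nn(duplexes, table[q].to_numpy(), q) for q in QUANTITIES
    }
    stacks = {
        s: ThermoTriple(
            fits["dH"].coefficients[s],
            fits["dS"].coefficients[s],
            fits["dG37"].coefficients[s],
        )
        for s in STACKS
    }
    inits = {
        key: ThermoTriple(
            0.0, fits["dS"].coefficients[key], fits["dG37"].coefficients[key]
        )
        for key in INIT_KEYS
    }
    pset = NnParameterSet(
        stacks=stacks,
        init_GC=inits["init_GC"],
        init_AU=inits["init_AU"],
        name=name,
    )
    return pset, fits


def propagate_dg_error(
    sigma_dH: float, sigma_dS: float, corr: float = 0.0
) -> float:
    """Propagate (sigma_dH, sigma_dS) into sigma_dG37 at 310.15 K.

    sigma^2 = sigma_H^2 + T^2 sigma_S^2 - 2 T corr sigma_H sigma_S with
    T = 310.15 K.  Both sigmas are in kcal-based units (sigma_dS in
    kcal/(mol K)); corr is the dH-dS estimate correlation, typically very
    close to +1 for van't Hoff fits, which is why dG37 errors are far
    smaller than dH errors.
    """
    if sigma_dH < 0 or sigma_dS < 0:
        raise ValueError("standard errors must be non-negative")
    if not -1.0 <= corr <= 1.0:
        raise ValueError(f"correlation must be in [-1, 1], got {corr}")
    var = (
        sigma_dH**2
        + T37_K**2 * sigma_dS**2
        - 2.0 * T37_K * corr * sigma_dH * sigma_dS
    )
    return math.sqrt(max(var, 0.0))


def frequency_balance(duplexes: Sequence[HybridDuplex]) -> pd.Series:
    """Total count of each of the 16 stacks over a duplex panel.

    The series carries the coefficient of variation in ``.attrs["cv"]``;
    a well-designed fitting panel has every stack represented and a low CV
    ("almost equal number of frequencies").
    """
    if not duplexes:
        raise ValueError("empty duplex list")
    totals = pd.Series(0, index=list(STACKS), dtype=int)
    for d in duplexes:
        for s, c in count_stacks(d).items():
            totals[s] += c
    mean = totals.mean()
    totals.attrs["cv"] = float(totals.std(ddof=0) / mean) if mean else float("nan")
    totals.attrs["n_zero"] = int((totals == 0).sum())
    return totals
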