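"""Design matrices, least-squares parameter recovery and error propagation."""

import math

import numpy as np
import pytest

from hybridnn import (
    HybridDuplex,
    build_design_matrix,
    fit_nn,
    fit_parameter_set,
    frequency_balance,
    predict_thermo,
    propagate_dg_error,
)
from hybridnn.duplex import STACKS, random_duplexes
from hybridnn.fitting import RankDeficientWarning


def _full_rank_panel(pset, rng, n=60):
    """Random duplex panel guaranteed full rank for all three designs."""
    for attempt in range(20):
        duplexes = random_duplexes(n, rng, length_range=(6, 14))
        X = build_design_matrix(duplexes, "dG37").values
        if np.linalg.matrix_rank(X) == 18:
            return duplexes
    raise AssertionError("could not build a full-rank panel")


def test_design_matrix_structure(pset):
    duplexes = [HybridDuplex.from_rna("GGUCGC"), HybridDuplex.from_rna("AAAA")]
    dm = build_design_matrix(duplexes, "dG37")
    assert dm.frame.shape == (2, 18)
    row = dm.frame.iloc[0]
    for stack in ("rGG/dCC", "rGU/dAC", "rUC/dGA", "rCG/dCG", "rGC/dGC"):
        assert row[stack] == 1
    assert row["init_GC"] == 1 and row["init_AU"] == 0
    row2 = dm.frame.iloc[1]
    assert row2["rAA/dTT"] == 3 and row2["init_AU"] == 1
    # stack counts sum to length - 1; exactly one initiation indicator
    assert dm.frame[list(STACKS)].sum(axis=1).tolist() == [5, 3]
    assert dm.frame[["init_GC", "init_AU"]].sum(axis=1).tolist() == [1, 1]


def test_dh_design_drops_initiation_columns():
    duplexes = [HybridDuplex.from_rna("GGUCGC")]
    dm = build_design_matrix(duplexes, "dH")
    assert dm.frame.shape == (1, 16)
    assert not any(c.startswith("init") for c in dm.columns)


def test_reference_panel_covers_all_stacks(ref_duplexes):
    balance = frequency_balance(ref_duplexes)
    assert (balance > 0).all()
    assert balance.attrs["n_zero"] == 0
    # the panel was designed for near-equal stack frequencies
    assert balance.attrs["cv"] < 0.5


def test_frequency_balance_flags_degenerate_panel():
    poly_a = [HybridDuplex.from_rna("AAAAAA")] * 3
    balance = frequency_balance(poly_a)
    assert balance.attrs["n_zero"] == 15
    with pytest.raises(ValueError, match="empty"):
        frequency_balance([])


def test_noiseless_recovery_all_quantities(pset, rng):
    """Exact synthetic data from the bundled set refits to the same set."""
    duplexes = _full_rank_panel(pset, rng)
    truth = np.array([predict_thermo(d, pset) for d in duplexes])
    import pandas as pd

    table = pd.DataFrame(truth, columns=["dH", "dS", "dG37"])
    refit, fits = fit_parameter_set(duplexes, table)
    assert all(f.rank == len(f.coefficients) for f in fits.values())
    for s in STACKS:
        for got, want in zip(refit.stacks[s], pset.stacks[s]):
            assert got == pytest.approx(want, abs=1e-8)
    assert refit.init_GC.dS == pytest.approx(pset.init_GC.dS, abs=1e-8)
    assert refit.init_AU.dG37 == pytest.approx(pset.init_AU.dG37, abs=1e-8)
    assert refit.init_GC.dH == 0.0  # constrained, not fitted
    for f in fits.values():
        assert np.all(f.standard_errors.to_numpy() < 1e-6)


def test_square_full_rank_matches_direct_solve(pset, rng):
    """On a square full-rank toy design, OLS equals the exact linear solve."""
    for _ in range(50):
        duplexes = random_duplexes(18, rng, length_range=(6, 14))
        X = build_design_matrix(duplexes, "dG37").values
        if np.linalg.matrix_rank(X) == 18 and abs(np.linalg.det(X)) > 1e-6:
            break
    else:
        pytest.skip("no invertible square design found")
    y = np.array([predict_thermo(d, pset)[2] for d in duplexes])
    fit = fit_nn(duplexes, y, "dG37")
    direct = np.linalg.solve(X, y)
    np.testing.assert_allclose(fit.coefficients.to_numpy(), direct, atol=1e-7)


def test_permutation_equivariance(pset, rng):
    duplexes = _full_rank_panel(pset, rng, n=40)
    y = np.array([predict_thermo(d, pset)[2] for d in duplexes]) + rng.normal(
        0, 0.2, len(duplexes)
    )
    fit1 = fit_nn(duplexes, y, "dG37")
    perm = rng.permutation(len(duplexes))
    fit2 = fit_nn([duplexes[i] for i in perm], y[perm], "dG37")
    np.testing.assert_allclose(
        fit1.coefficients.to_numpy(), fit2.coefficients.to_numpy(), atol=1e-10
    )
    np.testing.assert_allclose(fit1.residuals[perm], fit2.residuals, atol=1e-10)


def test_underdetermined_raises_and_rank_deficiency_warns(pset, rng):
    duplexes = random_duplexes(5, rng)
    with pytest.raises(ValueError, match="observations"):
        fit_nn(duplexes, [1.0] * 5, "dG37")
    # 20 copies of one sequence: plenty of rows, rank 2 (one stack + one init)
    clones = [HybridDuplex.from_rna("AAAAAA", label=f"c{i}") for i in range(20)]
    with pytest.warns(RankDeficientWarning):
        fit = fit_nn(clones, [-2.0] * 20, "dG37")
    assert fit.rank < 18


def test_standard_errors_match_monte_carlo(pset, rng):
    """Reported OLS standard errors agree with the scatter of repeated fits."""
    duplexes = _full_rank_panel(pset, rng, n=60)
    truth = np.array([predict_thermo(d, pset)[2] for d in duplexes])
    sigma = 0.3
    reported = fit_nn(
        duplexes, truth + rng.normal(0, sigma, len(truth)), "dG37"
    ).standard_errors.to_numpy()
    replicates = np.array(
        [
            fit_nn(duplexes, truth + rng.normal(0, sigma, len(truth)), "dG37")
            .coefficients.to_numpy()
            for _ in range(120)
        ]
    )
    empirical = replicates.std(axis=0, ddof=1)
    ratio = reported / empirical
    assert 0.75 < np.median(ratio) < 1.25


def test_refit_reference_panel_self_consistency(ref_table, ref_duplexes):
    """Refitting the measured dG37 panel re-predicts it about as well as the
    published parameters do (mean error within 2.9% + 0.3 pp)."""
    y = ref_table.dg37_meas.to_numpy()
    fit = fit_nn(ref_duplexes, y, "dG37")
    assert fit.rank == 18
    X = build_design_matrix(ref_duplexes, "dG37").values
    pred = X @ fit.coefficients.to_numpy()
    mean_err = np.mean(np.abs(y - pred) / np.abs(pred)) * 100
    assert mean_err <= 2.9 + 0.3
    # fitted dG37 SEs are of the same order as the published +/-0.06
    avg_se = fit.standard_errors.mean()
    assert 0.006 <= avg_se <= 0.6


def test_dh_fit_has_16_coefficients(ref_table, ref_duplexes):
    fit = fit_nn(ref_duplexes, ref_table.dh_meas.to_numpy(), "dH")
    assert len(fit.coefficients) == 16


@pytest.mark.parametrize(
    "sh,ss,corr,expected",
    [
        (1.0, 1.0 / 310.15, 1.0, 0.0),
        (1.0, 1.0 / 310.15, 0.0, math.sqrt(2.0)),
        (1.5, 1.3 / 310.15, 0.9995, 0.2048),
    ],
)
def test_propagate_dg_error(sh, ss, corr, expected):
    assert propagate_dg_error(sh, ss, corr) == pytest.approx(expected, abs=1e-3)


def test_propagate_dg_error_validation():
    with pytest.raises(ValueError, match="correlation"):
        propagate_dg_error(1.0, 0.001, 1.5)
    with pytest.raises(ValueError, match="non-negative"):
        propagate_dg_error(-1.0, 0.001)
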