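"""SBM-DEA scoring: hand-solved LPs, units invariance, dominance consistency."""

import numpy as np
import pytest

from ecohealth.panel import DEA_BAD_COLUMNS, DEA_GOOD_COLUMNS, DEA_INPUT_COLUMNS
from ecohealth.sbm import (
    DEAProblem,
    DEAValidationError,
    sbm_efficiency,
    score_panel,
)
from tests.conftest import pairwise_dominated


def _problem(inputs, goods, bads=None):
    inputs = np.asarray(inputs, dtype=float)
    n = inputs.shape[0]
    bads = np.empty((n, 0)) if bads is None else np.asarray(bads, dtype=float)
    return DEAProblem(
        units=tuple(f"U{i}" for i in range(n)),
        inputs=inputs,
        good_outputs=np.asarray(goods, dtype=float),
        bad_outputs=bads,
    )


def test_single_dmu_scores_one():
    prob = _problem([[2.0, 3.0]], [[5.0]], [[1.0]])
    score = sbm_efficiency(prob, "U0")
    assert score.rho == 1.0
    assert score.is_efficient
    assert np.all(score.input_slacks == 0)


def test_two_dmu_hand_solved_lp():
    # B uses twice A's input for the same output: projecting B onto A leaves
    # input slack 1, numerator 1 - (1/1)(1/2) = 0.5, denominator 1 — hence
    # rho = 0.5.  (The LP has alternate optima, e.g. an output-slack
    # projection with the same objective, so only rho and the slack/score
    # consistency are asserted.)
    prob = _problem([[1.0], [2.0]], [[1.0], [1.0]])
    assert sbm_efficiency(prob, "U0").rho == 1.0
    score_b = sbm_efficiency(prob, "U1")
    assert score_b.rho == pytest.approx(0.5, abs=1e-9)
    numerator = 1.0 - score_b.input_slacks[0] / 2.0
    denominator = 1.0 + score_b.good_output_slacks[0] / 1.0
    assert numerator / denominator == pytest.approx(0.5, abs=1e-7)


def test_identical_dmus_all_score_one():
    prob = _problem([[3.0, 1.0]] * 4, [[2.0]] * 4, [[0.5]] * 4)
    for unit in prob.units:
        assert sbm_efficiency(prob, unit).rho == 1.0


@pytest.mark.parametrize("rts", ["constant", "variable"])
def test_units_invariance_under_column_scaling(rts):
    rng = np.random.default_rng(11)
    inputs = rng.uniform(1, 10, size=(6, 3))
    goods = rng.uniform(1, 10, size=(6, 1))
    bads = rng.uniform(1, 10, size=(6, 2))
    base = _problem(inputs, goods, bads)
    scaled_inputs = inputs.copy()
    scaled_inputs[:, 2] *= 1000.0  # rescale the third input column for all DMUs
    scaled = _problem(scaled_inputs, goods, bads)
    for unit in base.units:
        r0 = sbm_efficiency(base, unit, rts).rho
        r1 = sbm_efficiency(scaled, unit, rts).rho
        assert abs(r0 - r1) <= 1e-9


def test_monotonicity_more_input_never_raises_score():
    rng = np.random.default_rng(4)
    inputs = rng.uniform(1, 10, size=(5, 2))
    goods = rng.uniform(1, 10, size=(5, 1))
    bads = rng.uniform(1, 5, size=(5, 1))
    base = _problem(inputs, goods, bads)
    for i in range(5):
        worse_inputs = inputs.copy()
        worse_inputs[i, 0] *= 1.5
        worse = _problem(worse_inputs, goods, bads)
        assert (
            sbm_efficiency(worse, f"U{i}").rho
            <= sbm_efficiency(base, f"U{i}").rho + 1e-9
        )
        worse_bads = bads.copy()
        worse_bads[i, 0] *= 1.5
        worse = _problem(inputs, goods, worse_bads)
        assert (
            sbm_efficiency(worse, f"U{i}").rho
            <= sbm_efficiency(base, f"U{i}").rho + 1e-9
        )


def test_vrs_score_at_least_crs_score():
    rng = np.random.default_rng(9)
    prob = _problem(
        rng.uniform(1, 10, size=(6, 2)),
        rng.uniform(1, 10, size=(6, 1)),
        rng.uniform(1, 5, size=(6, 1)),
    )
    for unit in prob.units:
        crs = sbm_efficiency(prob, unit, "constant").rho
        vrs = sbm_efficiency(prob, unit, "variable").rho
        assert vrs >= crs - 1e-9


def test_scores_consistent_with_dominance_oracle():
    rng = np.random.default_rng(21)
    inputs = rng.uniform(1, 10, size=(8, 2))
    goods = rng.uniform(1, 10, size=(8, 1))
    bads = rng.uniform(1, 5, size=(8, 1))
    # plant one clearly dominated unit
    inputs[7] = inputs[0] * 1.4
    goods[7] = goods[0]
    bads[7] = bads[0] * 1.3
    prob = _problem(inputs, goods, bads)
    for i, unit in enumerate(prob.units):
        rho = sbm_efficiency(prob, unit).rho
        if rho == 1.0:
            assert not pairwise_dominated(i, inputs, goods, bads)
        if pairwise_dominated(i, inputs, goods, bads):
            assert rho < 1.0


def test_nonpositive_data_rejected():
    with pytest.raises(DEAValidationError):
        _problem([[1.0], [0.0]], [[1.0], [1.0]])
    with pytest.raises(DEAValidationError):
        _problem([[1.0]], [[-2.0]])


def test_missing_unit_rejected():
    prob = _problem([[1.0], [2.0]], [[1.0], [1.0]])
    with pytest.raises(DEAValidationError):
        sbm_efficiency(prob, "nope")


class TestScorePanel:
    def test_frontier_fixture_scores_match_construction(self, frontier_panel):
        scored = score_panel(frontier_panel, per_year=True)
        rho = scored.data["ree"].to_numpy()
        eff = frontier_panel.efficient_truth.to_numpy()
        assert np.all(rho[eff] == 1.0)
        assert np.all(rho[~eff] < 1.0)
        assert np.all((rho > 0) & (rho <= 1.0))

    def test_per_year_and_pooled_fill_every_row(self, frontier_panel):
        for per_year in (True, False):
            scored = score_panel(frontier_panel, per_year=per_year)
            assert scored.data["ree"].notna().all()

    def test_scoring_is_deterministic(self, frontier_panel):
        a = score_panel(frontier_panel)
        b = score_panel(frontier_panel)
        assert a.data["ree"].equals(b.data["ree"])
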