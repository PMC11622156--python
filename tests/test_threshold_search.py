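"""Grid search vs an independent scalar brute-force oracle."""

import math

import numpy as np
import pytest

from vfcensor import (
    CohortSpec,
    compute_td,
    censor_value,
    evaluate_cell,
    generate_cohort,
    grid_search,
)

from conftest import make_pair


def naive_cell(pairs, t_iii, t_v, norm_iii, norm_v):
    """Scalar re-implementation: per-field compute_td + censor_value flags."""
    diffs = []
    for pair in pairs:
        td3 = compute_td(pair.field_III, norm_iii, censor_threshold=t_iii)
        td5 = compute_td(pair.field_V, norm_v, censor_threshold=t_v)
        for loc in td3.td:
            _, c3 = censor_value(pair.field_III.sensitivities[loc], t_iii)
            _, c5 = censor_value(pair.field_V.sensitivities[loc], t_v)
            if c3 or c5:
                diffs.append(td5.td[loc] - td3.td[loc])
    n = len(diffs)
    mean = sum(diffs) / n if n else float("nan")
    sd = math.sqrt(sum((d - mean) ** 2 for d in diffs) / (n - 1)) if n >= 2 else float("nan")
    return mean, sd, n


def naive_best(pairs, grid3, grid5, norm_iii, norm_v, min_count, tie_se_factor=2.0):
    """Independent selection: argmin |mean| with SE-tolerance ties, then
    (SD, t_III, t_V)."""
    cells = {}
    for a in grid3:
        for b in grid5:
            cells[(a, b)] = naive_cell(pairs, a, b, norm_iii, norm_v)
    eligible = {k: v for k, v in cells.items() if v[2] >= min_count}
    best_key = min(eligible, key=lambda k: (abs(eligible[k][0]), k))
    mean, sd, n = eligible[best_key]
    se = sd / math.sqrt(n) if n >= 2 and math.isfinite(sd) else 0.0
    tied = [k for k, v in eligible.items()
            if abs(v[0]) <= abs(mean) + tie_se_factor * se]
    tied.sort(key=lambda k: (
        eligible[k][1] if math.isfinite(eligible[k][1]) else math.inf, k[0], k[1]))
    return tied[0], cells


class TestEvaluateCell:
    def test_toy_mean_sd(self, flat_norms):
        # three pairs, each with exactly one censored point; diffs {+1, -1, 0}
        pairs = [
            make_pair(30, 30, overrides_III={(3, 3): 10}, overrides_V={(3, 3): 22}),
            make_pair(30, 30, overrides_III={(3, 3): 22}, overrides_V={(3, 3): 10}),
            make_pair(30, 30, overrides_III={(3, 3): 10}, overrides_V={(3, 3): 10}),
        ]
        cell = evaluate_cell(pairs, 21, 21, *flat_norms)
        assert cell.mean_diff == pytest.approx(0.0)
        assert cell.sd_diff == pytest.approx(1.0)
        assert cell.n_censored == 3

    def test_empty_subset_flagged(self, flat_norms):
        cell = evaluate_cell([make_pair(30, 30)], 21, 24, *flat_norms)
        assert cell.empty and np.isnan(cell.mean_diff)

    def test_single_pair_sd_undefined(self, flat_norms):
        pairs = [make_pair(30, 30, overrides_III={(3, 3): 10}, overrides_V={(3, 3): 23})]
        cell = evaluate_cell(pairs, 21, 21, *flat_norms)
        assert cell.mean_diff == pytest.approx(2.0)
        assert np.isnan(cell.sd_diff)
        assert cell.n_censored == 1

    def test_matches_naive_oracle(self, flat_norms):
        pairs = [make_pair(30, 30, overrides_III={(3, 3): 10, (9, 9): 18},
                           overrides_V={(3, 3): 25, (-9, 3): 12})]
        cell = evaluate_cell(pairs, 21, 24, *flat_norms)
        mean, sd, n = naive_cell(pairs, 21, 24, *flat_norms)
        assert cell.mean_diff == pytest.approx(mean)
        assert cell.sd_diff == pytest.approx(sd)
        assert cell.n_censored == n


class TestGridSearch:
    def test_identical_stimuli_tie_break(self, flat_norms):
        # V raw equals III raw, identical norms: every defined cell has mean 0
        pairs = [make_pair(30, 30, overrides_III={(3, 3): 10}, overrides_V={(3, 3): 10}),
                 make_pair(30, 30, overrides_III={(9, 9): 12}, overrides_V={(9, 9): 12},
                           subject_id="p2")]
        res = grid_search(pairs, *flat_norms, grid_III=[15, 18], grid_V=[15, 18],
                          min_count=1)
        assert res.objective_at_best == pytest.approx(0.0)
        # all four cells tie at mean 0 and sd 0: lowest thresholds win
        assert (res.best.threshold_III, res.best.threshold_V) == (15, 15)

    def test_toy_matches_hand_enumeration(self, flat_norms):
        pairs = [
            make_pair(30, 30, overrides_III={(3, 3): 16}, overrides_V={(3, 3): 19}),
            make_pair(30, 30, overrides_III={(9, 9): 14}, overrides_V={(9, 9): 22},
                      subject_id="p2"),
            make_pair(30, 30, overrides_III={(-3, 9): 19}, overrides_V={(-3, 9): 17},
                      subject_id="p3"),
        ]
        grid = [18, 21]
        res = grid_search(pairs, *flat_norms, grid_III=grid, grid_V=grid, min_count=1)
        best_key, cells = naive_best(pairs, grid, grid, *flat_norms, min_count=1)
        assert (res.best.threshold_III, res.best.threshold_V) == best_key
        for i, a in enumerate(grid):
            for j, b in enumerate(grid):
                mean, sd, n = cells[(a, b)]
                assert res.mean_diff[i, j] == pytest.approx(mean, nan_ok=True)
                assert res.n_censored[i, j] == n

    def test_matches_bruteforce_on_random_cohorts(self, default_norm_pair):
        niii, nv = default_norm_pair
        for seed in (3, 9):
            spec = CohortSpec.naion_default(n_pairs=12, n_participants=6, seed=seed)
            pairs = generate_cohort(spec, norm_III=niii, norm_V=nv)
            grid3 = range(17, 22)
            grid5 = range(20, 25)
            res = grid_search(pairs, niii, nv, grid3, grid5, min_count=5)
            best_key, cells = naive_best(pairs, list(grid3), list(grid5), niii, nv,
                                         min_count=5)
            assert (res.best.threshold_III, res.best.threshold_V) == best_key
            for i, a in enumerate(grid3):
                for j, b in enumerate(grid5):
                    mean, sd, n = cells[(a, b)]
                    assert res.mean_diff[i, j] == pytest.approx(mean, nan_ok=True)
                    assert res.sd_diff[i, j] == pytest.approx(sd, nan_ok=True)
                    assert res.n_censored[i, j] == n

    def test_order_invariance(self, default_norm_pair):
        niii, nv = default_norm_pair
        spec = CohortSpec.glaucoma_default(n_pairs=10, n_participants=5, seed=1)
        pairs = generate_cohort(spec, norm_III=niii, norm_V=nv)
        a = grid_search(pairs, niii, nv, [19, 21], [22, 24], min_count=1)
        b = grid_search(pairs[::-1], niii, nv, [19, 21], [22, 24], min_count=1)
        np.testing.assert_allclose(a.mean_diff, b.mean_diff)
        np.testing.assert_allclose(a.sd_diff, b.sd_diff)
        assert a.best == b.best

    def test_min_count_unreachable_errors(self, flat_norms):
        with pytest.raises(ValueError, match="larger cohort"):
            grid_search([make_pair(30, 30)], *flat_norms, grid_III=[21], grid_V=[24],
                        min_count=30)

    def test_result_export(self, flat_norms, tmp_path):
        pairs = [make_pair(30, 30, overrides_III={(3, 3): 10})]
        res = grid_search(pairs, *flat_norms, grid_III=[20, 21], grid_V=[20, 24],
                          min_count=1)
        res.write(tmp_path / "r.json", tmp_path / "h.csv")
        assert (tmp_path / "r.json").exists()
        frame = res.heatmap_frame()
        assert list(frame.index) == [20, 21] and list(frame.columns) == [20, 24]
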