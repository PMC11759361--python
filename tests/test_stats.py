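"""Aggregation, scaling, hit calling, ranking, and the hypothesis tests."""

import itertools
import math

import numpy as np
import pytest

from axonwrap import stats as axs
from axonwrap.stack_io import PlateManifest
from axonwrap.wrapping import FieldMetrics

import pandas as pd


def _metrics(wi, valid=True, sheaths=()):
    return FieldMetrics(
        n_pillars=9, n_fully_wrapped=0, n_nuclei=10,
        wi=wi, wi_valid=valid, sheath_lengths_um=list(sheaths), per_pillar=None,
    )


def _manifest(conditions, wells=3, fields=9):
    rows = [
        {"well_id": f"{c}-w{w}", "field_id": f"f{f}", "condition": c, "path": "x.tif"}
        for c in conditions for w in range(wells) for f in range(fields)
    ]
    return PlateManifest(table=pd.DataFrame(rows))


class TestAggregate:
    def test_three_wells_nine_fields_pool_to_27(self):
        manifest = _manifest(["DMSO"])
        metrics = {
            (r.well_id, r.field_id): _metrics(0.2)
            for r in manifest.table.itertuples()
        }
        (summary,) = axs.aggregate(manifest, metrics)
        assert summary.n_fields == 27
        assert summary.mean_wi == pytest.approx(0.2)
        assert summary.sem_wi == pytest.approx(0.0)

    def test_wi_error_field_excluded(self):
        manifest = _manifest(["DMSO"])
        keys = [(r.well_id, r.field_id) for r in manifest.table.itertuples()]
        metrics = {k: _metrics(0.2) for k in keys}
        metrics[keys[0]] = _metrics(float("nan"), valid=False)
        (summary,) = axs.aggregate(manifest, metrics)
        assert summary.n_fields == 26

    def test_unknown_field_rejected(self):
        manifest = _manifest(["DMSO"])
        with pytest.raises(axs.StatsError):
            axs.aggregate(manifest, {("nope", "f0"): _metrics(0.1)})

    def test_condition_with_no_valid_fields_errors(self):
        manifest = _manifest(["DMSO"], wells=1, fields=1)
        metrics = {("DMSO-w0", "f0"): _metrics(float("nan"), valid=False)}
        with pytest.raises(axs.StatsError):
            axs.aggregate(manifest, metrics)


class TestScaleAndHits:
    def _summaries(self, means, control_sd=0.1, n=27):
        out = []
        for label, mean in means.items():
            vals = list(np.linspace(mean - control_sd, mean + control_sd, n))
            arr = np.asarray(vals)
            # rescale to the exact target mean/sd
            arr = (arr - arr.mean()) / arr.std(ddof=1) * control_sd + mean
            out.append(axs.ConditionSummary(label, list(arr), float(arr.mean()),
                                            float(arr.std(ddof=1) / math.sqrt(n)), n))
        return out

    def test_scaling_by_control(self):
        res = axs.scale_by_control(self._summaries({"DMSO": 0.2, "drugA": 0.3}))
        by = {r.compound: r.scaled_wi for r in res}
        assert by["drugA"] == pytest.approx(1.5)
        assert by["DMSO"] == pytest.approx(1.0)

    def test_scaling_is_idempotent_on_ratios(self):
        first = axs.scale_by_control(self._summaries({"DMSO": 0.2, "drugA": 0.3}))
        as_summaries = [
            axs.ConditionSummary(r.compound, [r.scaled_wi], r.scaled_wi,
                                 0.0, 1) for r in first
        ]
        second = axs.scale_by_control(as_summaries)
        assert {r.compound: r.scaled_wi for r in second} == {
            r.compound: pytest.approx(r.scaled_wi) for r in first
        }

    def test_missing_control_errors(self):
        with pytest.raises(axs.StatsError):
            axs.scale_by_control(self._summaries({"drugA": 0.3}))

    @pytest.mark.parametrize(
        "mean,expected", [(2.75, True), (1.575, False), (2.0, False)]
    )
    def test_two_sd_rule_is_strict(self, mean, expected):
        # control sd is exactly 0.5, so the hit cut sits exactly at 2.0
        control = axs.ConditionSummary("DMSO", [0.5, 1.0, 1.5], 1.0, 0.5 / 3**0.5, 3)
        drug = axs.ConditionSummary("drug", [mean] * 3, mean, 0.0, 3)
        hits = axs.call_hits([control, drug])
        assert hits["drug"] is expected

    def test_control_with_one_field_errors(self):
        s = [axs.ConditionSummary("DMSO", [1.0], 1.0, float("nan"), 1)]
        with pytest.raises(axs.StatsError):
            axs.call_hits(s)


class TestRanking:
    def _results(self, d):
        return [axs.CompoundResult(k, v) for k, v in d.items()]

    def test_descending_order(self):
        ranked = axs.rank_compounds(self._results({"A": 2.0, "B": 1.5, "C": 1.8}))
        assert [r.compound for r in ranked] == ["A", "C", "B"]
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_ties_break_alphabetically(self):
        ranked = axs.rank_compounds(self._results({"B": 1.5, "A": 1.5}))
        assert [r.compound for r in ranked] == ["A", "B"]

    def test_input_order_irrelevant(self):
        d = {"D": 1.1, "A": 2.0, "C": 1.1, "B": 0.4}
        r1 = axs.rank_compounds(self._results(d))
        r2 = axs.rank_compounds(self._results(dict(reversed(list(d.items())))))
        assert [(r.compound, r.rank) for r in r1] == [(r.compound, r.rank) for r in r2]


def _brute_force_mw_p(x, y):
    """Two-sided permutation p for U, counting pairwise wins directly."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        return sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys)

    mu = n1 * len(y) / 2.0
    obs = abs(u_of(tuple(range(n1))) - mu)
    labelings = list(itertools.combinations(range(len(pooled)), n1))
    hits = sum(1 for idx in labelings if abs(u_of(idx) - mu) >= obs - 1e-12)
    return hits / len(labelings)


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        u, p = axs.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        _, p = axs.mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_mirror_identity(self):
        x, y = [1.0, 3.0, 5.0], [2.0, 2.0, 6.0, 7.0]
        ux, px = axs.mann_whitney(x, y)
        uy, py = axs.mann_whitney(y, x)
        assert ux + uy == pytest.approx(len(x) * len(y))
        assert px == pytest.approx(py)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(1, 6))
        n2 = int(rng.integers(1, 11 - n1))
        # integer draws so ties occur regularly
        x = rng.integers(0, 5, n1).astype(float)
        y = rng.integers(0, 5, n2).astype(float)
        _, p = axs.mann_whitney(x, y)
        assert p == pytest.approx(_brute_force_mw_p(x, y))

    def test_empty_sample_rejected(self):
        with pytest.raises(axs.StatsError):
            axs.mann_whitney([], [1.0])


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = axs.kruskal_wallis([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        assert (h, p) == (0.0, 1.0)

    def test_hand_computed_rank_sum_value(self):
        # ranks 1..6; H = 12/(6*7) * (9/2 + 49/2 + 121/2) - 3*7 = 32/7
        h, _ = axs.kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert h == pytest.approx(32.0 / 7.0)

    def test_invariance_under_monotone_transform(self):
        groups = [[1.0, 4.0], [2.0, 9.0], [5.0, 6.0, 8.0]]
        h1, _ = axs.kruskal_wallis(groups)
        h2, _ = axs.kruskal_wallis([[math.exp(v) for v in g] for g in groups])
        assert h1 == pytest.approx(h2)

    def test_too_few_groups_rejected(self):
        with pytest.raises(axs.StatsError):
            axs.kruskal_wallis([[1, 2], [3, 4]])


class TestAnovaBonferroni:
    def test_identical_groups_f_zero(self):
        f, p, pairwise = axs.anova_bonferroni(
            {"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [1.0, 2.0]}
        )
        assert f == 0.0
        assert p == pytest.approx(1.0)
        assert all(v == 1.0 for v in pairwise.values())

    def test_two_groups_no_adjustment(self):
        from scipy.stats import ttest_ind

        g = {"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 5.0]}
        _, _, pairwise = axs.anova_bonferroni(g)
        raw = ttest_ind(g["a"], g["b"]).pvalue
        assert pairwise[("a", "b")] == pytest.approx(raw)

    def test_four_groups_factor_six(self):
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(0)
        g = {k: rng.normal(i, 1, 6).tolist() for i, k in enumerate("abcd")}
        _, _, pairwise = axs.anova_bonferroni(g)
        assert len(pairwise) == 6
        raw = ttest_ind(g["a"], g["b"]).pvalue
        assert pairwise[("a", "b")] == pytest.approx(min(raw * 6, 1.0))

    def test_degenerate_groups_rejected(self):
        with pytest.raises(axs.StatsError):
            axs.anova_bonferroni({"a": [1.0], "b": [1.0, 2.0]})
        with pytest.raises(axs.StatsError):
            axs.anova_bonferroni({"a": [1.0, 1.0], "b": [1.0, 1.0]})


class TestInnerWells:
    def test_96_well_plate_keeps_60(self):
        wells = axs.inner_wells(8, 12)
        assert len(wells) == 60
        assert wells[0] == "B2" and wells[-1] == "G11"
        assert "A1" not in wells and "H12" not in wells

    def test_minimal_plate(self):
        assert axs.inner_wells(3, 3) == ["B2"]

    def test_four_by_four(self):
        assert len(axs.inner_wells(4, 4)) == 4

    def test_too_small_rejected(self):
        with pytest.raises(axs.StatsError):
            axs.inner_wells(2, 12)
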