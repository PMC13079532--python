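import numpy as np
import pytest

from docseer.products import (
    ActionLevel,
    action_level,
    assemble_report,
    most_probable_tercile,
    render_markdown,
    tercile_bounds,
    tercile_climatology,
    tercile_probabilities,
)
from docseer.verification import SkillGrid


class TestTercileBounds:
    def test_bounds_strictly_inside_range(self):
        t1, t2, dg = tercile_bounds([1.0, 2.0, 3.0])
        assert 1.0 < t1 < t2 < 3.0 and not dg

    def test_uniform_sample_converges_to_thirds(self):
        rng = np.random.default_rng(4)
        t1, t2, _ = tercile_bounds(rng.uniform(0, 1, 200_000))
        assert t1 == pytest.approx(1 / 3, abs=0.01)
        assert t2 == pytest.approx(2 / 3, abs=0.01)

    def test_constant_sample_flagged_degenerate(self):
        t1, t2, dg = tercile_bounds([2.0, 2.0, 2.0, 2.0])
        assert dg and t1 == t2 == 2.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            tercile_bounds([1.0, 2.0])

    def test_climatology_covers_all_months(self):
        monthly = {(y, m): float(y % 5 + m) for y in range(2000, 2010)
                   for m in range(1, 13)}
        clim = tercile_climatology(monthly, range(2000, 2010), "doc")
        assert sorted(clim.bounds) == list(range(1, 13))


class TestTercileProbabilities:
    def test_all_members_below(self):
        fc = tercile_probabilities(np.zeros(6), (1.0, 2.0))
        assert fc.probabilities() == (1.0, 0.0, 0.0)
        assert fc.most_probable == "below-normal"

    def test_counting_example(self):
        """9 members: 1 below, 2 inside, 6 above → (1/9, 2/9, 6/9)."""
        members = np.array([0.5, 1.5, 1.8, 3.0, 3.1, 3.2, 3.3, 3.4, 3.5])
        fc = tercile_probabilities(members, (1.0, 2.0))
        assert fc.p_below == pytest.approx(1 / 9)
        assert fc.p_normal == pytest.approx(2 / 9)
        assert fc.p_above == pytest.approx(6 / 9)

    def test_bound_equal_member_counts_normal(self):
        fc = tercile_probabilities(np.array([2.0]), (1.0, 2.0))
        assert fc.p_normal == 1.0

    def test_probabilities_are_member_count_multiples(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            m = int(rng.integers(1, 30))
            fc = tercile_probabilities(rng.normal(0, 1, m), (-0.4, 0.4))
            for p in fc.probabilities():
                assert (p * m) == pytest.approx(round(p * m), abs=1e-9)
            assert sum(fc.probabilities()) == pytest.approx(1.0, abs=1e-12)

    def test_climatological_ensemble_is_calibrated(self):
        """Members drawn from the reference distribution land in each tercile
        about a third of the time."""
        rng = np.random.default_rng(10)
        ref = rng.normal(5, 2, 100_000)
        t1, t2, _ = tercile_bounds(ref)
        fc = tercile_probabilities(rng.normal(5, 2, 100_000), (t1, t2))
        for p in fc.probabilities():
            assert p == pytest.approx(1 / 3, abs=0.02)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            tercile_probabilities(np.array([]), (0.0, 1.0))


class TestActionLevels:
    @pytest.mark.parametrize(
        "pan,expected",
        [
            (0.0, ActionLevel.WATCH),
            (0.50, ActionLevel.WATCH),
            (0.599, ActionLevel.WATCH),
            (0.60, ActionLevel.PREPARE),
            (0.699, ActionLevel.PREPARE),
            (0.70, ActionLevel.ACT),
            (0.75, ActionLevel.ACT),
            (0.80, ActionLevel.ESCALATE),
            (1.0, ActionLevel.ESCALATE),
        ],
    )
    def test_threshold_semantics(self, pan, expected):
        assert action_level(pan) is expected

    def test_monotone_in_pan(self):
        order = [ActionLevel.WATCH, ActionLevel.PREPARE, ActionLevel.ACT,
                 ActionLevel.ESCALATE]
        levels = [order.index(action_level(p)) for p in np.linspace(0, 1, 101)]
        assert np.all(np.diff(levels) >= 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            action_level(1.2)


class TestMostProbable:
    def test_clear_winner(self):
        assert most_probable_tercile((0.1, 0.2, 0.7)) == "above-normal"

    def test_three_way_tie_resolves_normal(self):
        assert most_probable_tercile((1 / 3, 1 / 3, 1 / 3)) == "normal"

    def test_two_way_tie_with_normal_resolves_normal(self):
        assert most_probable_tercile((0.5, 0.5, 0.0)) == "normal"

    def test_below_above_tie_resolves_below(self):
        assert most_probable_tercile((0.5, 0.0, 0.5)) == "below-normal"


class TestReport:
    @pytest.fixture()
    def inputs(self):
        rng = np.random.default_rng(6)
        monthly = {(y, m): float(5 + np.cos(m) + 0.5 * (y % 3))
                   for y in range(2000, 2010) for m in range(1, 13)}
        clims = {var: tercile_climatology(monthly, range(2000, 2010), var)
                 for var in ("doc", "temperature", "precipitation", "streamflow")}
        # 9-member ensembles; DOC lead 1 built so pAN = 6/9 ≈ 0.667 → prepare
        t1, t2 = clims["doc"].bounds[12]
        doc_lead1 = np.concatenate([np.full(6, t2 + 1.0), np.full(3, (t1 + t2) / 2)])
        ensembles = {
            var: {ld: rng.normal(5, 1, 9) for ld in range(1, 5)}
            for var in ("temperature", "precipitation", "streamflow", "doc")
        }
        ensembles["doc"][1] = doc_lead1
        crpss = np.full((12, 7), np.nan)
        crpss[11, 0], crpss[11, 1], crpss[11, 2] = 0.7, 0.4, 0.1  # lead 4 missing
        grid = SkillGrid("doc", crpss, np.where(np.isfinite(crpss), 10, 0),
                         list(range(1, 13)))
        return ensembles, clims, grid

    def test_report_structure_and_thresholds(self, inputs):
        ensembles, clims, grid = inputs
        rep = assemble_report(2009, 12, ensembles, clims, grid)
        assert len(rep.leads) == 4
        for ld in rep.leads:
            assert sum(ld.doc.probabilities()) == pytest.approx(1.0, abs=1e-12)
        lead1 = rep.leads[0]
        assert lead1.doc.p_above == pytest.approx(6 / 9)
        assert lead1.doc_action is ActionLevel.PREPARE
        assert lead1.doc_skill is not None and lead1.doc_skill.value == "high"

    def test_missing_skill_cell_never_fabricated(self, inputs):
        ensembles, clims, grid = inputs
        rep = assemble_report(2009, 12, ensembles, clims, grid)
        assert rep.leads[3].doc_skill is None
        md = render_markdown(rep)
        assert "no skill information" in md

    def test_rendering_is_deterministic(self, inputs):
        ensembles, clims, grid = inputs
        rep = assemble_report(2009, 12, ensembles, clims, grid)
        assert render_markdown(rep) == render_markdown(rep)
        assert rep.to_json() == rep.to_json()

    def test_json_roundtrips(self, inputs, tmp_path):
        import json

        ensembles, clims, grid = inputs
        rep = assemble_report(2009, 12, ensembles, clims, grid)
        path = tmp_path / "report.json"
        rep.to_json(path)
        loaded = json.loads(path.read_text())
        assert loaded["init"] == "2009-12"
        assert len(loaded["leads"]) == 4
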