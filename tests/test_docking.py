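"""prm configuration, scored-SD parsing, ranking, convergence, surrogate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peplib.docking import (
    CavityConfig,
    ScoreRecord,
    parse_prm,
    parse_scored_sd,
    rank_and_select,
    score_convergence,
    surrogate_score,
    write_prm_config,
)
from peplib.errors import ConfigurationError, ParseError
from peplib.fixtures import make_poses_with_planted_interactions, make_scored_sd


@pytest.fixture
def ref_ligand(tmp_path):
    path = tmp_path / "ref.sdf"
    path.write_text("dummy\n")
    return path


class TestPrmConfig:
    def test_paper_defaults_written(self, tmp_path, ref_ligand):
        prm = tmp_path / "dock.prm"
        manifest = write_prm_config(prm, "receptor.mol2",
                                    CavityConfig(str(ref_ligand)))
        text = prm.read_text().lower()
        assert "radius 4.0" in text
        assert "receptor_flex 3.0" in text
        assert "rbtligandsitemapper" in text
        for key in ("small_sphere 1.0", "min_volume 100", "max_cavities 1",
                    "vol_incr 0.0", "gridstep 0.5"):
            assert key in text
        assert manifest["runs"] == 100

    def test_round_trip_parse(self, tmp_path, ref_ligand):
        prm = tmp_path / "dock.prm"
        cavity = CavityConfig(str(ref_ligand), radius=5.5, gridstep=0.4)
        write_prm_config(prm, "rec.mol2", cavity, runs=50)
        parsed = parse_prm(prm)
        mapper = parsed["_sections"]["MAPPER"]
        assert mapper["SITE_MAPPER"] == "RbtLigandSiteMapper"
        assert float(mapper["RADIUS"]) == 5.5
        assert float(mapper["GRIDSTEP"]) == 0.4
        assert float(parsed["RECEPTOR_FLEX"]) == 3.0

    def test_negative_radius_rejected(self, ref_ligand):
        with pytest.raises(ConfigurationError):
            CavityConfig(str(ref_ligand), radius=-1.0)

    def test_missing_reference_ligand(self, tmp_path):
        with pytest.raises(ConfigurationError):
            write_prm_config(tmp_path / "d.prm", "rec.mol2",
                             CavityConfig(str(tmp_path / "absent.sdf")))


class TestParseScoredSd:
    def test_multi_run_records(self, tmp_path):
        path = tmp_path / "scored.sdf"
        make_scored_sd(path, {"GSVW": -15.0, "AAAA": -10.0}, runs=4, seed=1)
        records = parse_scored_sd(path)
        assert len(records) == 8
        by_id = {}
        for rec in records:
            by_id.setdefault(rec.peptide_id, []).append(rec.run_index)
        assert by_id == {"AAAA": [1, 2, 3, 4], "GSVW": [1, 2, 3, 4]}
        assert all(r.inter_score == pytest.approx(r.score - 1.0)
                   for r in records)

    def test_non_numeric_score_raises_with_index(self, tmp_path):
        path = tmp_path / "scored.sdf"
        make_scored_sd(path, {"AA": -5.0}, runs=2, noise_sd=0.0, seed=0)
        path.write_text(path.read_text().replace("-5.0000", "abc", 1))
        with pytest.raises(ParseError) as err:
            parse_scored_sd(path)
        assert err.value.record_index == 0

    def test_missing_inter_tag_warns_and_keeps(self, tmp_path):
        path = tmp_path / "scored.sdf"
        make_scored_sd(path, {"AA": -5.0}, runs=1, noise_sd=0.0, seed=0)
        text = path.read_text()
        start = text.index("<SCORE.INTER>") - 3
        end = text.index("<RUN>") - 3
        path.write_text(text[:start] + text[end:])
        with pytest.warns(UserWarning, match="SCORE.INTER"):
            records = parse_scored_sd(path)
        assert len(records) == 1
        assert records[0].inter_score is None
        assert records[0].score == pytest.approx(-5.0)


def _records(scores: dict[str, list[float]]):
    return [
        ScoreRecord(peptide_id=pid, score=s, inter_score=s, run_index=i + 1)
        for pid, runs in scores.items()
        for i, s in enumerate(runs)
    ]


class TestRankAndSelect:
    def test_matches_exhaustive_sort_oracle(self):
        rng = np.random.default_rng(3)
        scores = {
            f"PEP{i:03d}": list(rng.normal(-10, 3, size=5)) for i in range(40)
        }
        ranked = rank_and_select(_records(scores), n=10)
        oracle = sorted(scores, key=lambda p: (min(scores[p]), p))[:10]
        assert ranked.sequences == oracle

    def test_tie_break_lexicographic(self):
        recs = _records({"CA": [-5.0], "AC": [-5.0], "BB": [-7.0]})
        ranked = rank_and_select(recs, n=3)
        assert ranked.sequences == ["BB", "AC", "CA"]

    def test_best_pose_is_minimum_across_runs(self):
        recs = _records({"AA": [-5.0, -9.0, -7.0]})
        ranked = rank_and_select(recs, n=1)
        assert ranked.records[0].score == -9.0

    def test_n_exceeding_peptides_warns_and_returns_all(self):
        with pytest.warns(UserWarning):
            ranked = rank_and_select(_records({"AA": [-1.0], "GG": [-2.0]}), n=5)
        assert len(ranked) == 2

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_ranking_property_random_fixtures(self, data):
        n_pep = data.draw(st.integers(2, 12))
        scores = {
            f"P{i:02d}": data.draw(
                st.lists(st.floats(-20, 0, allow_nan=False), min_size=1,
                         max_size=4)
            )
            for i in range(n_pep)
        }
        k = data.draw(st.integers(1, n_pep))
        ranked = rank_and_select(_records(scores), n=k)
        oracle = sorted(scores, key=lambda p: (min(scores[p]), p))[:k]
        assert ranked.sequences == oracle


class TestScoreConvergence:
    def test_running_minimum_single_peptide(self):
        recs = _records({"AA": [-5.0, -7.0, -6.0]})
        table = score_convergence(recs, key="total")
        assert list(table["mean_best_score"]) == [-5.0, -7.0, -7.0]

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(9)
        recs = _records({
            f"P{i}": list(rng.normal(-8, 2, size=20)) for i in range(30)
        })
        curve = list(score_convergence(recs, key="total")["mean_best_score"])
        assert all(a >= b - 1e-12 for a, b in zip(curve, curve[1:]))

    def test_full_budget_equals_ranking_minima(self):
        rng = np.random.default_rng(5)
        scores = {f"P{i}": list(rng.normal(-8, 2, size=6)) for i in range(10)}
        recs = _records(scores)
        table = score_convergence(recs, key="total")
        full = table[table.run_count == 6]["mean_best_score"].iloc[0]
        ranked = rank_and_select(recs, n=10)
        assert full == pytest.approx(
            np.mean([r.score for r in ranked.records])
        )

    def test_sample_fraction_reproducible(self):
        recs = _records({f"P{i:04d}": [-float(i)] for i in range(1000)})
        t1 = score_convergence(recs, sample_fraction=0.1, seed=4, key="total")
        t2 = score_convergence(recs, sample_fraction=0.1, seed=4, key="total")
        assert t1.equals(t2)
        assert t1["n_sampled"].iloc[0] == 100

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            score_convergence([], sample_fraction=0.5)


class TestSurrogateScore:
    def test_zero_interactions_scores_zero(self, receptor):
        poses, _ = make_poses_with_planted_interactions(receptor, [[]])
        rec = surrogate_score(poses[0], receptor)
        assert rec.score == 0.0

    def test_extra_hbond_strictly_improves(self, receptor):
        poses, _ = make_poses_with_planted_interactions(
            receptor,
            [[("hydrophobic", "A:MET252")],
             [("hydrophobic", "A:MET252"),
              ("hbond_acceptor_from_ligand", "A:THR250")]],
        )
        weak = surrogate_score(poses[0], receptor)
        strong = surrogate_score(poses[1], receptor)
        assert strong.score < weak.score

    def test_determinism(self, receptor):
        poses, _ = make_poses_with_planted_interactions(
            receptor, [[("pi_pi", "A:HIS435")]]
        )
        a = surrogate_score(poses[0], receptor)
        b = surrogate_score(poses[0], receptor)
        assert a.score == b.score

    def test_pose_outside_cavity_rejected(self, receptor):
        poses, _ = make_poses_with_planted_interactions(
            receptor, [[("pi_pi", "A:HIS435")]]
        )
        rec = surrogate_score(
            poses[0], receptor,
            cavity_center=np.array([0.0, 0.0, 0.0]), cavity_radius=2.0,
        )
        assert rec.rejected
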