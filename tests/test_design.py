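"""Scorefile parsing, selection cascade, PWM/consensus, resfiles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from knotopt import design as D
from knotopt import synth
from knotopt.peptides import CANONICAL_AA


class TestReadScorefile:
    def test_thousand_records(self):
        ds = D.read_scorefile(synth.gen_scorefile(n_designs=1000, seed=2))
        assert len(ds) == 1000
        assert all(r.sequence is not None for r in ds.records)

    def test_header_only_is_empty(self):
        ds = D.read_scorefile("SCORE: total_score ddg description\n")
        assert len(ds) == 0

    def test_nan_total_score_rejected_with_line(self):
        text = (
            "SCORE: total_score ddg description\n"
            "SCORE: -300.0 -40.0 design_0001\n"
            "SCORE: nan -41.0 design_0002\n"
        )
        with pytest.raises(D.ScorefileError, match="line 3"):
            D.read_scorefile(text)

    def test_missing_required_column(self):
        with pytest.raises(D.ScorefileError, match="ddg"):
            D.read_scorefile("SCORE: total_score description\n")

    def test_duplicate_tags_rejected(self):
        text = (
            "SCORE: total_score ddg description\n"
            "SCORE: -300.0 -40.0 dup\n"
            "SCORE: -301.0 -41.0 dup\n"
        )
        with pytest.raises(D.ScorefileError, match="dup"):
            D.read_scorefile(text)


def _brute_force_cascade(ds, n_score, n_ddg):
    df = pd.DataFrame(
        [(r.tag, r.total_score, r.ddg) for r in ds.records],
        columns=["tag", "total_score", "ddg"],
    )
    stage1 = df.sort_values(["total_score", "tag"], kind="stable").head(n_score)
    stage2 = stage1.sort_values(["ddg", "tag"], kind="stable").head(n_ddg)
    return list(stage2["tag"])


class TestSelectDesigns:
    def test_defaults_keep_twenty(self):
        ds = D.read_scorefile(synth.gen_scorefile(n_designs=1000, seed=4))
        assert len(D.select_designs(ds)) == 20

    def test_matches_brute_force_double_sort(self):
        for seed in (0, 1, 2):
            ds = D.read_scorefile(synth.gen_scorefile(n_designs=400, seed=seed))
            sel = D.select_designs(ds, n_score=50, n_ddg=10)
            assert sel.tags() == _brute_force_cascade(ds, 50, 10)

    def test_small_set_returned_whole(self):
        ds = D.read_scorefile(synth.gen_scorefile(n_designs=15, seed=5))
        sel = D.select_designs(ds)
        assert len(sel) == 15

    def test_idempotent(self):
        ds = D.read_scorefile(synth.gen_scorefile(n_designs=300, seed=6))
        once = D.select_designs(ds)
        twice = D.select_designs(once)
        assert twice.tags() == once.tags()

    def test_tie_break_by_tag(self):
        text = (
            "SCORE: total_score ddg description\n"
            "SCORE: -1.0 -1.0 b\n"
            "SCORE: -1.0 -1.0 a\n"
            "SCORE: -1.0 -1.0 c\n"
        )
        sel = D.select_designs(D.read_scorefile(text), n_score=2, n_ddg=2)
        assert sel.tags() == ["a", "b"]


class TestPWMConsensus:
    def test_identical_sequences_one_hot(self):
        pwm = D.build_pwm(["ACDEF"] * 20)
        assert pwm.n_sequences == 20
        assert np.allclose(pwm.freqs.max(axis=1), 1.0)
        assert np.allclose(pwm.information_content, math.log2(20))
        assert D.consensus(pwm) == "ACDEF"

    def test_uniform_position_zero_information(self):
        seqs = [aa + "C" for aa in CANONICAL_AA]  # position 1 uniform
        pwm = D.build_pwm(seqs)
        assert pwm.information_content.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert pwm.information_content.iloc[1] == pytest.approx(math.log2(20))

    def test_columns_sum_to_one_and_ic_bounds(self):
        rng = np.random.default_rng(8)
        seqs = ["".join(rng.choice(list(CANONICAL_AA), 12)) for _ in range(33)]
        pwm = D.build_pwm(seqs)
        assert np.allclose(pwm.freqs.sum(axis=1), 1.0, atol=1e-12)
        ic = pwm.information_content
        assert ((ic >= -1e-12) & (ic <= math.log2(20) + 1e-12)).all()

    def test_planted_majority_recovered(self):
        rng = np.random.default_rng(9)
        planted = "RKCW"
        seqs = []
        for _ in range(40):
            s = [
                aa if rng.random() < 0.7 else rng.choice(list(CANONICAL_AA))
                for aa in planted
            ]
            seqs.append("".join(s))
        assert D.consensus(D.build_pwm(seqs)) == planted

    def test_tie_breaks_alphabetically(self):
        pwm = D.build_pwm(["A", "C"])
        assert D.consensus(pwm) == "A"

    def test_ragged_input_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            D.build_pwm(["AC", "ACD"])


class TestResfile:
    def test_printed_round2_resfile_partition(self, resfile_text):
        spec = D.parse_resfile(resfile_text)
        assert spec.default_command == "PIKAA"
        assert spec.default_residues == CANONICAL_AA
        part = spec.partition()
        assert part["NATAA"] == [5, 6, 22, 24, 27, 29]
        assert part["PIKAA"] == [20, 28, 30]
        assert part["NOTAA"] == [1, 4, 7, 8, 13]
        assert spec.command_at(20, "E").residues == "R"
        assert spec.command_at(28, "E").residues == "E"
        assert spec.command_at(30, "E").residues == "L"
        assert all(
            spec.command_at(p, "E").residues == "ED" for p in (1, 4, 7, 8, 13)
        )

    def test_write_parse_identity_on_printed_file(self, resfile_text):
        spec = D.parse_resfile(resfile_text)
        assert D.parse_resfile(D.write_resfile(spec)) == spec

    def test_empty_body_all_default(self):
        spec = D.parse_resfile("NATAA\nstart\n")
        assert spec.default_command == "NATAA"
        assert spec.commands == []

    def test_unknown_command_reports_line(self):
        with pytest.raises(D.ResfileError, match="line 3"):
            D.parse_resfile("PIKAA AC\nstart\n4 E FROBNICATE\n")

    def test_body_before_start_rejected(self):
        with pytest.raises(D.ResfileError, match="before 'start'"):
            D.parse_resfile("4 E NATAA\nstart\n")

    @given(
        st.lists(
            st.tuples(
                st.integers(1, 30),
                st.sampled_from(["PIKAA", "NATAA", "NOTAA"]),
                st.text(alphabet=CANONICAL_AA, min_size=1, max_size=5),
            ),
            max_size=12,
        )
    )
    @settings(derandomize=True, max_examples=50)
    def test_random_spec_round_trip(self, raw):
        seen = set()
        commands = []
        for pos, cmd, residues in raw:
            if pos in seen:
                continue
            seen.add(pos)
            commands.append(
                D.ResfileCommand(pos, "E", cmd, "" if cmd == "NATAA" else residues)
            )
        spec = D.ResfileSpec(commands=commands)
        assert D.parse_resfile(D.write_resfile(spec)) == spec


class TestDeriveConstraints:
    def _paper_like_profile(self):
        import pandas as pd
        from knotopt.interface import ContactProfile

        values = pd.DataFrame(
            0.0,
            index=range(1, 31),
            columns=["lipid_head", "lipid_tail", "water", "channel"],
        )
        for pos in (1, 4, 7, 8, 13):
            values.loc[pos, "lipid_head"] = 0.9
        return ContactProfile.from_values(values, n_observations=1000)

    def test_reproduces_printed_command_partition(self, resfile_text):
        spec = D.derive_constraints(
            self._paper_like_profile(),
            fixed_native=[5, 6, 22, 24, 27, 29],
            fixed_identity={20: "R", 28: "E", 30: "L"},
            lipid_threshold=0.25,
        )
        printed = D.parse_resfile(resfile_text)
        assert spec.partition() == printed.partition()
        assert {c.res_id: c.residues for c in spec.commands if c.command == "PIKAA"} == {
            20: "R", 28: "E", 30: "L",
        }

    def test_threshold_above_one_rejected(self):
        with pytest.raises(ValueError, match="lipid_threshold"):
            D.derive_constraints(self._paper_like_profile(), lipid_threshold=1.01)

    def test_all_zero_profile_pins_only_cysteines(self):
        import pandas as pd
        from knotopt.interface import ContactProfile

        values = pd.DataFrame(
            0.0, index=range(1, 31),
            columns=["lipid_head", "lipid_tail", "water", "channel"],
        )
        profile = ContactProfile.from_values(values, 100)
        scaffold = "YCQKWMWTCDSERKCCEGMVCRLWCKKKLW"
        spec = D.derive_constraints(profile, scaffold_sequence=scaffold)
        part = spec.partition()
        assert part["NATAA"] == [2, 9, 15, 16, 21, 25]
        assert part["PIKAA"] == [] and part["NOTAA"] == []

    def test_conflicting_constraints_rejected(self):
        with pytest.raises(ValueError, match="identity-fixed and design-excluded"):
            D.derive_constraints(
                self._paper_like_profile(),
                fixed_identity={20: "R"},
                design_positions_exclude=[20],
            )


class TestPlantedMotifPipeline:
    def test_cascade_consensus_recovers_motif(self):
        text = synth.gen_scorefile(
            n_designs=500, planted_motif={20: "R", 28: "E"}, motif_enrichment=0.9,
            seed=12,
        )
        ds = D.read_scorefile(text)
        sel = D.select_designs(ds)
        cons = D.consensus(D.build_pwm(sel.sequences()))
        assert cons[19] == "R" and cons[27] == "E"

    def test_logo_renders(self, tmp_path):
        ds = D.read_scorefile(synth.gen_scorefile(n_designs=50, seed=13))
        pwm = D.build_pwm(D.select_designs(ds).sequences())
        out = tmp_path / "logo.png"
        D.plot_logo(pwm, out)
        assert out.stat().st_size > 0
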