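import math
import textwrap

import numpy as np
import pytest

from refmirna import (
    CtTable,
    InputOutputError,
    ReplicateSet,
    SimSpec,
    ValidationError,
    collapse_replicates,
    compare_group_ct,
    load_ct_table,
    load_panel,
    simulate_ct,
    summarize_group_ct,
    validate_panel,
    write_ct_table,
)
from conftest import make_table, random_table


def write_inputs(tmp_path, ct_text, meta_text):
    ct = tmp_path / "ct.csv"
    meta = tmp_path / "meta.csv"
    ct.write_text(textwrap.dedent(ct_text))
    meta.write_text(textwrap.dedent(meta_text))
    return ct, meta


META_4 = """\
    sample,group,condition
    s1,High,motility
    s2,High,motility
    s3,Low,motility
    s4,Low,motility
    """


class TestLoading:
    def test_wide_round_trip(self, tmp_path, rng):
        table = random_table(rng, k=7, n=10)
        ct_path, meta_path = tmp_path / "ct.csv", tmp_path / "meta.csv"
        write_ct_table(table, ct_path, meta_path)
        back = load_ct_table(ct_path, meta_path)
        assert back.candidates == table.candidates
        assert back.samples == table.samples
        # 6-decimal storage -> at least 6 significant digits back
        np.testing.assert_allclose(back.ct, table.ct, atol=5e-7)
        assert back.group_of == table.group_of

    def test_undetermined_cell_is_parse_error_naming_the_cell(self, tmp_path):
        ct, meta = write_inputs(
            tmp_path,
            """\
            candidate,s1,s2,s3,s4
            miRa,20,21,Undetermined,22
            miRb,25,26,27,28
            """,
            META_4,
        )
        with pytest.raises(InputOutputError, match="Undetermined.*miRa.*s3"):
            load_ct_table(ct, meta)

    def test_sample_missing_from_metadata(self, tmp_path):
        ct, meta = write_inputs(
            tmp_path,
            """\
            candidate,s1,s2,s3,s4
            miRa,20,21,22,23
            miRb,25,26,27,28
            """,
            """\
            sample,group,condition
            s1,High,motility
            s2,High,motility
            s3,Low,motility
            """,
        )
        with pytest.raises(ValidationError, match="s4"):
            load_ct_table(ct, meta)

    def test_ct_out_of_range_rejected(self, tmp_path):
        ct, meta = write_inputs(
            tmp_path,
            """\
            candidate,s1,s2,s3,s4
            miRa,20,21,22,50
            miRb,25,26,27,28
            """,
            META_4,
        )
        with pytest.raises(ValidationError, match="outside"):
            load_ct_table(ct, meta)

    def test_long_dialect_collapses_replicates(self, tmp_path):
        ct, meta = write_inputs(
            tmp_path,
            """\
            sample,candidate,replicate,ct
            s1,miRa,1,20.0
            s1,miRa,2,20.2
            s1,miRa,3,20.4
            s2,miRa,1,21.0
            s1,miRb,1,25.0
            s2,miRb,1,26.0
            s3,miRa,1,20.0
            s3,miRb,1,25.0
            s4,miRa,1,20.0
            s4,miRb,1,25.0
            """,
            META_4,
        )
        table = load_ct_table(ct, meta, dialect="long")
        assert table.ct[table.candidates.index("miRa"), 0] == pytest.approx(20.2)

    def test_duplicate_candidate_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            CtTable(["a", "a"], ["s1", "s2"], [[1, 2], [3, 4]], {"s1": "g", "s2": "g"})


class TestReplicates:
    def test_mean_and_flagging(self):
        table, flags = collapse_replicates(
            [
                ReplicateSet("s1", "m1", [20.0, 20.2, 20.4]),
                ReplicateSet("s1", "m2", [25.0]),
                ReplicateSet("s2", "m1", [20.0, 21.0]),
                ReplicateSet("s2", "m2", [25.0]),
            ],
            spread_threshold=0.5,
        )
        frame = table.to_frame()
        assert frame.loc["m1", "s1"] == pytest.approx(20.2)
        assert frame.loc["m2", "s1"] == pytest.approx(25.0)
        assert frame.loc["m1", "s2"] == pytest.approx(20.5)
        assert [(f["candidate"], f["sample"]) for f in flags] == [("m1", "s2")]

    def test_permutation_invariant(self, rng):
        reps = [20.1, 20.5, 19.9]
        base = ReplicateSet("s", "m", reps).mean
        for _ in range(5):
            perm = list(rng.permutation(reps))
            assert ReplicateSet("s", "m", perm).mean == pytest.approx(base)

    def test_empty_replicates_rejected(self):
        with pytest.raises(ValidationError):
            ReplicateSet("s1", "m1", [])

    def test_incomplete_matrix_rejected(self):
        with pytest.raises(ValidationError, match="missing pairs"):
            collapse_replicates(
                [
                    ReplicateSet("s1", "m1", [20.0]),
                    ReplicateSet("s2", "m1", [20.0]),
                    ReplicateSet("s1", "m2", [25.0]),
                ]
            )


class TestGroupSummary:
    def test_constant_group(self):
        table = make_table([[22.0] * 4, [24.0, 25.0, 26.0, 27.0]])
        summary = summarize_group_ct(table)
        row = summary[(summary.candidate == "A") & (summary.group == "G1")].iloc[0]
        assert row.mean_ct == 22.0 and row.sd_ct == 0.0 and row.sem_ct == 0.0

    def test_two_point_formula(self):
        table = make_table([[20.0, 22.0, 25.0, 27.0], [21.0, 21.0, 21.0, 21.0]])
        summary = summarize_group_ct(table)
        row = summary[(summary.candidate == "A") & (summary.group == "G1")].iloc[0]
        assert row.mean_ct == pytest.approx(21.0)
        assert row.sd_ct == pytest.approx(math.sqrt(2))
        assert row.sem_ct == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        table = random_table(rng)
        summary = summarize_group_ct(table)
        for _, row in summary.iterrows():
            i = table.candidates.index(row.candidate)
            vals = [
                table.ct[i, j]
                for j, s in enumerate(table.samples)
                if table.group_of[s] == row.group
            ]
            n = len(vals)
            mean = sum(vals) / n
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
            assert row.mean_ct == pytest.approx(mean, abs=1e-12)
            assert row.sd_ct == pytest.approx(sd, abs=1e-12)


class TestGroupComparison:
    def test_null_statistic(self):
        table = make_table([[20.0, 22.0, 20.0, 22.0], [25.0, 26.0, 25.0, 26.0]])
        res = compare_group_ct(table)
        assert res.loc[res.candidate == "A", "t"].iloc[0] == pytest.approx(0.0)
        assert res.loc[res.candidate == "A", "p"].iloc[0] == pytest.approx(1.0)

    def test_clear_separation_significant(self):
        table = make_table(
            [[10.1, 9.9, 10.1, 20.1, 19.9, 20.1], [25, 26, 25, 26, 25, 26]]
        )
        res = compare_group_ct(table)
        assert bool(res.loc[res.candidate == "A", "significant"].iloc[0])

    def test_type_i_error_rate_near_alpha(self):
        """Stable candidate, no group shift: rejection rate ~ 5% over 500 seeds."""
        rejections = 0
        n_sims = 500
        for seed in range(n_sims):
            table, _ = simulate_ct(
                SimSpec(k=3, sigma=(0.3, 0.3, 0.3), tau=0.0, n_replicates=1, seed=seed)
            )
            res = compare_group_ct(table)
            rejections += int(res["significant"].iloc[0])
        assert abs(rejections / n_sims - 0.05) <= 0.02

    def test_requires_two_groups(self):
        from refmirna import ContractError

        table = make_table([[20, 21, 22, 23], [25, 26, 27, 28]], groups=("G1", "G1"))
        with pytest.raises(ContractError):
            compare_group_ct(table)


class TestPanel:
    def test_packaged_panel_is_valid(self):
        panel = load_panel()
        report = validate_panel(panel)
        assert report["valid"].all()
        let7c = report[report.assay_name.str.contains("let-7c")].iloc[0]
        assert let7c.length == 22

    def test_dna_letter_in_mirna_flagged(self):
        from refmirna.ct_io import CandidatePanel, PanelEntry

        panel = CandidatePanel([PanelEntry("miR-x", "1_mir", "ACGTACGU")])
        report = validate_panel(panel)
        assert not report["valid"].iloc[0]
        assert "T" in report["problems"].iloc[0]

    def test_empty_sequence_flagged(self):
        from refmirna.ct_io import CandidatePanel, PanelEntry

        panel = CandidatePanel([PanelEntry("miR-x", "1_mir", "")])
        report = validate_panel(panel)
        assert not report["valid"].iloc[0]
        assert "empty" in report["problems"].iloc[0]
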