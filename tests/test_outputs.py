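import numpy as np
import pandas as pd
import pytest

from seedtox.annotate import AnnotatedCountTable
from seedtox.counting import CountTable, normalize_cpm
from seedtox.outputs import (
    bin_to_C,
    collapse_to_B,
    expand_to_D,
    expand_to_E,
    expand_to_F,
    mirna_content,
    position_frequency_matrix,
    round_half_away,
    write_output_A,
)


def _annotated(rows, counts_by_sample):
    """rows: list of (sequence, seed, viability, mirna, name)."""
    idx = [r[0] for r in rows]
    ann = pd.DataFrame(
        {
            "seed": [r[1] for r in rows],
            "viability": [r[2] for r in rows],
            "miRNA": [r[3] for r in rows],
            "RNAworld": None,
            "name": [r[4] for r in rows],
        },
        index=pd.Index(idx, name="sequence"),
    )
    counts = normalize_cpm(
        CountTable(raw=pd.DataFrame(counts_by_sample, index=idx))
    )
    return AnnotatedCountTable(ann=ann, counts=counts)


@pytest.fixture
def simple_table():
    rows = [
        ("A" * 20, "GGGGGC", 20.0, "mir-1", "mir-1"),
        ("C" * 20, "GGGGGC", 20.0, "mir-1", "mir-1"),
        ("G" * 20, "GGGGGC", 20.0, None, "tRNA-frag"),
        ("T" * 20, "AAAAAA", 95.0, "mir-2", "mir-2"),
    ]
    return _annotated(rows, {"s1": [100, 200, 50, 650], "s2": [10, 20, 30, 940]})


def test_round_half_away():
    assert round_half_away(0.5) == 1
    assert round_half_away(49.5) == 50
    assert round_half_away(-0.5) == -1
    assert round_half_away(1.49) == 1
    np.testing.assert_array_equal(round_half_away(np.array([5.0, 0.499, 1.5])), [5, 0, 2])


class TestOutputA:
    def test_row_count_and_header(self, simple_table, tmp_path):
        path = write_output_A(simple_table, "rawCounts", tmp_path)
        df = pd.read_csv(path, sep="\t")
        assert len(df) == 4
        assert list(df.columns[:6]) == ["sequence", "seed", "viability", "miRNA", "RNAworld", "name"]
        assert path.name == "A_rawCounts.txt"

    def test_norm_columns_sum_to_1e6(self, simple_table, tmp_path):
        path = write_output_A(simple_table, "normCounts", tmp_path)
        df = pd.read_csv(path, sep="\t")
        assert df["s1"].sum() == pytest.approx(1_000_000)
        assert df["s2"].sum() == pytest.approx(1_000_000)

    def test_unknown_flavor(self, simple_table, tmp_path):
        with pytest.raises(ValueError):
            write_output_A(simple_table, "other", tmp_path)


class TestCollapseB:
    def test_same_seed_same_name_sums(self):
        table = _annotated(
            [
                ("A" * 20, "GGGGGC", 20.0, "mir-1", "mir-1"),
                ("C" * 20, "GGGGGC", 20.0, "mir-1", "mir-1"),
            ],
            {"s1": [100, 200]},
        )
        b, seed_keyed = collapse_to_B(table)
        assert len(b) == 1
        assert b["s1"].iloc[0] == pytest.approx(1_000_000)

    def test_same_seed_different_names(self, simple_table):
        b, seed_keyed = collapse_to_B(simple_table)
        gg = b[b["seed"] == "GGGGGC"]
        assert len(gg) == 2  # mir-1 and tRNA-frag rows
        assert len(seed_keyed) == 2  # GGGGGC and AAAAAA
        assert seed_keyed.set_index("seed").loc["GGGGGC", "s1"] == pytest.approx(
            gg["s1"].sum()
        )

    def test_empty_input(self):
        table = _annotated([], {"s1": []})
        b, seed_keyed = collapse_to_B(table)
        assert len(b) == 0 and len(seed_keyed) == 0

    def test_conservation_a_to_b(self, simple_table):
        b, _ = collapse_to_B(simple_table)
        for s in ("s1", "s2"):
            assert b[s].sum() == pytest.approx(simple_table.counts.norm[s].sum())


class TestBinC:
    def test_rounding_to_bin(self):
        b = pd.DataFrame(
            {"seed": ["GGGGGC"], "name": ["x"], "viability": [49.5], "s1": [10.0]}
        )
        c = bin_to_C(b, (0, 100))
        assert c.set_index("bin").loc[50, "s1"] == 10.0

    def test_two_rows_same_bin(self):
        b = pd.DataFrame(
            {
                "seed": ["AAAAAA", "AAAAAC"],
                "name": ["x", "y"],
                "viability": [20.2, 20.4],
                "s1": [5.0, 7.0],
            }
        )
        c = bin_to_C(b, (0, 100))
        assert c.set_index("bin").loc[20, "s1"] == 12.0

    def test_full_range_even_when_zero(self):
        b = pd.DataFrame(
            {"seed": ["AAAAAA"], "name": ["x"], "viability": [50.0], "s1": [1.0]}
        )
        c = bin_to_C(b, (10, 110))
        assert list(c["bin"]) == list(range(10, 111))
        assert (c.loc[c["bin"] != 50, "s1"] == 0).all()

    def test_conservation_b_to_c(self, simple_table):
        b, _ = collapse_to_B(simple_table)
        c = bin_to_C(b, (0, 120))
        for s in ("s1", "s2"):
            assert c[s].sum() == pytest.approx(b[s].sum())


def _b(rows):
    """rows: (seed, viability, count)"""
    return pd.DataFrame(
        {
            "seed": [r[0] for r in rows],
            "name": ["x"] * len(rows),
            "viability": [r[1] for r in rows],
            "s1": [float(r[2]) for r in rows],
        }
    )


class TestExpandD:
    def test_worked_example_5000(self):
        d = expand_to_D(_b([("GGGGGC", 80.0, 5000)]), per="replicate")
        assert len(d) == 5
        assert (d["viability"] == 80.0).all()

    def test_sub_500_rounds_to_zero(self):
        assert len(expand_to_D(_b([("GGGGGC", 80.0, 499)]), per="replicate")) == 0

    def test_sum_of_rescaled(self):
        d = expand_to_D(_b([("GGGGGC", 80.0, 2000), ("AAAAAA", 90.0, 3000)]), per="replicate")
        assert len(d) == 5

    def test_group_average(self):
        b = _b([("GGGGGC", 80.0, 4000)])
        b["s2"] = 2000.0
        d = expand_to_D(b, per="avg", groups={"g": ["s1", "s2"]})
        assert len(d) == 3  # mean(4000, 2000) / 1000 = 3
        assert set(d["unit"]) == {"g"}


class TestExpandE:
    def test_seed_payload(self):
        e = expand_to_E(_b([("GGGGGC", 80.0, 5000)]), per="replicate")
        assert len(e) == 5
        assert (e["seed"] == "GGGGGC").all()

    def test_rounding_half_up(self):
        assert len(expand_to_E(_b([("GGGGGC", 80.0, 1500)]), per="replicate")) == 2

    def test_empty(self):
        assert len(expand_to_E(_b([]), per="replicate")) == 0


class TestExpandF:
    def test_worked_example_30_rows(self):
        f = expand_to_F(_b([("GGGGGC", 80.0, 5000)]), per="replicate")
        assert len(f) == 30
        assert sorted(f["position"].unique()) == [1, 2, 3, 4, 5, 6]

    def test_below_1000_omitted(self):
        assert len(expand_to_F(_b([("GGGGGC", 80.0, 999)]), per="replicate")) == 0

    def test_6n_formula(self):
        f = expand_to_F(
            _b([("GGGGGC", 80.0, 1000), ("AAAAAA", 90.0, 2000)]), per="replicate"
        )
        assert len(f) == 6 * (1 + 2)

    def test_nucleotides_match_seed(self):
        f = expand_to_F(_b([("GAGGUA", 70.0, 1000)]), per="replicate")
        by_pos = f.sort_values("position")["nucleotide"].tolist()
        assert by_pos == list("GAGGUA")

    def test_instance_ids_unique_per_instance(self):
        f = expand_to_F(_b([("GGGGGC", 80.0, 5000)]), per="replicate")
        assert f.groupby("instance_id").size().eq(6).all()
        assert f["instance_id"].nunique() == 5

    def test_d_and_f_asymmetry_at_sub_1000(self):
        # D keeps a 600-count row (rounds to 1); F omits it entirely
        b = _b([("GGGGGC", 80.0, 600)])
        assert len(expand_to_D(b, per="replicate")) == 1
        assert len(expand_to_F(b, per="replicate")) == 0


class TestPFM:
    def test_single_seed(self):
        e = pd.DataFrame({"unit": "s1", "seed": ["GGGGGC"] * 3})
        pfm = position_frequency_matrix(e)
        assert pfm.loc["G"].tolist() == [1, 1, 1, 1, 1, 0]
        assert pfm.loc["C"].tolist() == [0, 0, 0, 0, 0, 1]

    def test_columns_sum_to_one(self, rng):
        seeds = ["".join(rng.choice(list("ACGU"), 6)) for _ in range(50)]
        pfm = position_frequency_matrix(pd.DataFrame({"unit": "s1", "seed": seeds}))
        np.testing.assert_allclose(pfm.sum(axis=0), 1.0)

    def test_uniform_seeds_near_quarter(self, rng):
        seeds = ["".join(rng.choice(list("ACGU"), 6)) for _ in range(4000)]
        pfm = position_frequency_matrix(pd.DataFrame({"unit": "s1", "seed": seeds}))
        assert (np.abs(pfm.to_numpy() - 0.25) < 0.03).all()

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            position_frequency_matrix(pd.DataFrame({"unit": [], "seed": []}))


class TestMirnaContent:
    def test_all_assigned(self):
        table = _annotated(
            [("A" * 20, "GGGGGC", 20.0, "mir-1", "mir-1")], {"s1": [5]}
        )
        assert mirna_content(table)["s1"] == pytest.approx(100.0)

    def test_half_mass(self):
        table = _annotated(
            [
                ("A" * 20, "GGGGGC", 20.0, "mir-1", "mir-1"),
                ("C" * 20, "GGGGGC", 20.0, None, "unknown"),
            ],
            {"s1": [5, 5]},
        )
        assert mirna_content(table)["s1"] == pytest.approx(50.0)

    def test_zero_total_errors(self):
        table = _annotated(
            [("A" * 20, "GGGGGC", 20.0, "mir-1", "mir-1")], {"s1": [0]}
        )
        with pytest.raises(ValueError):
            mirna_content(table)


class TestDifferentialBranchValues:
    def test_up_down_split_uses_absolute_delta(self):
        table = _annotated(
            [
                ("A" * 20, "GGGGGC", 20.0, None, "x"),
                ("C" * 20, "AAAAAA", 95.0, None, "y"),
            ],
            {"s1": [1, 1]},
        )
        table.ann["delta"] = [1500.0, -2500.0]
        table.ann["direction"] = ["Up", "Down"]
        b, _ = collapse_to_B(table, use_delta=True)
        up = b.set_index("seed")["Up"]
        down = b.set_index("seed")["Down"]
        assert up.loc["GGGGGC"] == 1500.0 and down.loc["GGGGGC"] == 0.0
        assert down.loc["AAAAAA"] == 2500.0 and up.loc["AAAAAA"] == 0.0
        assert (b[["Up", "Down"]].to_numpy() >= 0).all()
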