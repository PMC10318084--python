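"""Summary-statistics I/O, clumping, proxy lookup and harmonisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fitmr as fm
from conftest import make_table


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

TSV_HEADER = "rsid\tchr\tbp\tea\toa\teaf\tbeta\tse\tp\tn\n"
DIALECT = {"variant_id": "rsid", "chrom": "chr", "pos": "bp",
           "effect_allele": "ea", "other_allele": "oa", "pval": "p"}


def write_tsv(path, rows):
    path.write_text(TSV_HEADER + "".join("\t".join(map(str, r)) + "\n" for r in rows))


def test_read_with_dialect(tmp_path):
    f = tmp_path / "gwas.tsv"
    write_tsv(f, [("rs1", 1, 100, "A", "G", 0.3, 0.1, 0.01, 1e-8, 1000),
                  ("rs2", 1, 200, "C", "T", 0.2, -0.1, 0.02, 1e-6, 1000),
                  ("rs3", 2, 300, "G", "A", 0.4, 0.05, 0.01, 1e-4, 1000)])
    t = fm.read_summary_table(f, dialect=DIALECT)
    assert len(t) == 3
    assert t.get("rs2").beta == -0.1


def test_invalid_rows_rejected_not_fatal(tmp_path, caplog):
    f = tmp_path / "gwas.tsv"
    write_tsv(f, [("rs1", 1, 100, "A", "G", 0.3, 0.1, 0.0, 1e-8, 1000),   # se = 0
                  ("rs2", 1, 200, "C", "T", 1.2, -0.1, 0.02, 1e-6, 1000),  # eaf > 1
                  ("rs3", 2, 300, "G", "A", 0.4, 0.05, 0.01, 1e-4, 1000)])
    with caplog.at_level("WARNING", logger="fitmr"):
        t = fm.read_summary_table(f, dialect=DIALECT)
    assert len(t) == 1
    assert sum("variant_dropped" in r.message for r in caplog.records) == 2


def test_all_rows_rejected_is_error(tmp_path):
    f = tmp_path / "gwas.tsv"
    write_tsv(f, [("rs1", 1, 100, "A", "G", 0.3, 0.1, 0.0, 1e-8, 1000)])
    with pytest.raises(fm.SumstatsError, match="rejected"):
        fm.read_summary_table(f, dialect=DIALECT)


def test_missing_column_is_configuration_error(tmp_path):
    f = tmp_path / "gwas.tsv"
    f.write_text("rsid\tchr\n" "rs1\t1\n")
    with pytest.raises(fm.SumstatsError, match="mandatory column"):
        fm.read_summary_table(f, dialect=DIALECT)


def test_write_read_roundtrip(tmp_path, three_variant_table):
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    fm.write_summary_table(three_variant_table, p1)
    again = fm.read_summary_table(p1, trait_label=three_variant_table.trait_label)
    fm.write_summary_table(again, p2)
    assert p1.read_bytes() == p2.read_bytes()
    pd.testing.assert_frame_equal(three_variant_table.df, again.df,
                                  check_dtype=False)


# ---------------------------------------------------------------------------
# distance clumping
# ---------------------------------------------------------------------------

def test_clump_greedy_hand_trace(three_variant_table):
    out = fm.distance_clump(three_variant_table, window=1_000_000, p_max=1e-5)
    assert set(out.df["pos"]) == {1_000_000, 3_000_000}


@pytest.mark.parametrize("rows,expected", [
    ([("rs1", "1", 100, "A", "G", 0.3, 0.1, 0.01, 1e-10, 1000)], {"rs1"}),
    ([("rs1", "1", 100, "A", "G", 0.3, 0.1, 0.01, 1e-10, 1000),
      ("rs2", "2", 101, "C", "T", 0.3, 0.1, 0.01, 1e-9, 1000)], {"rs1", "rs2"}),
])
def test_clump_small_cases(rows, expected):
    out = fm.distance_clump(make_table(rows), window=1_000_000, p_max=1e-5)
    assert set(out.df["variant_id"]) == expected


def test_clump_empty_after_p_filter(three_variant_table):
    out = fm.distance_clump(three_variant_table, p_max=1e-20)
    assert len(out) == 0


@settings(max_examples=25, deadline=None)
@given(perm=st.permutations(range(6)))
def test_clump_order_invariant(perm):
    rows = [(f"rs{i}", "1", 500_000 * (i + 1), "A", "G", 0.3,
             0.1, 0.01, p, 1000)
            for i, p in enumerate([1e-10, 1e-9, 1e-12, 1e-8, 1e-11, 1e-7])]
    base = fm.distance_clump(make_table(rows), p_max=1e-5)
    shuffled = fm.distance_clump(make_table([rows[i] for i in perm]), p_max=1e-5)
    assert list(base.df["variant_id"]) == list(shuffled.df["variant_id"])


# ---------------------------------------------------------------------------
# proxy lookup
# ---------------------------------------------------------------------------

def outcome_with(p_by_id):
    rows = [(vid, "1", 100 + i, "A", "G", 0.3, 0.1, 0.01, p, 1000)
            for i, (vid, p) in enumerate(p_by_id.items())]
    return make_table(rows, label="outcome")


def test_find_proxy_smallest_p_wins():
    ld = fm.LdReference()
    ld.add("target", "rsA", 0.9)
    ld.add("target", "rsB", 0.85)
    out = outcome_with({"rsA": 1e-8, "rsB": 1e-12})
    assert fm.find_proxy("target", out, ld) == "rsB"


def test_find_proxy_none_below_threshold():
    ld = fm.LdReference()
    ld.add("target", "rsA", 0.5)
    assert fm.find_proxy("target", outcome_with({"rsA": 1e-8}), ld) is None


def test_find_proxy_tie_breaks_to_higher_r2_then_id():
    ld = fm.LdReference()
    ld.add("target", "rsA", 0.85)
    ld.add("target", "rsB", 0.95)
    out = outcome_with({"rsA": 1e-8, "rsB": 1e-8})
    assert fm.find_proxy("target", out, ld) == "rsB"
    ld2 = fm.LdReference()
    ld2.add("target", "rsA", 0.9)
    ld2.add("target", "rsB", 0.9)
    assert fm.find_proxy("target", out, ld2) == "rsA"


def test_dprime_gate():
    ld = fm.LdReference()
    ld.add("target", "rsA", 0.9, dprime=0.5)  # high r2 but low D'
    assert fm.find_proxy("target", outcome_with({"rsA": 1e-8}), ld) is None


# ---------------------------------------------------------------------------
# harmonisation
# ---------------------------------------------------------------------------

def test_swapped_alleles_negate_outcome():
    exp = make_table([("rs1", "1", 100, "A", "G", 0.3, 0.1, 0.01, 1e-8, 1000)])
    out = make_table([("rs1", "1", 100, "G", "A", 0.7, 0.05, 0.02, 1e-3, 1000)],
                     label="outcome")
    h = fm.harmonise_pair(exp, out)
    row = h.df.iloc[0]
    assert row["beta_out"] == -0.05
    assert row["allele_flipped"]
    assert row["se_out"] == 0.02  # flip preserves the standard error


def test_negative_exposure_reorients_both():
    exp = make_table([("rs1", "1", 100, "A", "G", 0.3, -0.1, 0.01, 1e-8, 1000)])
    out = make_table([("rs1", "1", 100, "A", "G", 0.3, 0.05, 0.02, 1e-3, 1000)],
                     label="outcome")
    h = fm.harmonise_pair(exp, out)
    row = h.df.iloc[0]
    assert row["beta_exp"] == pytest.approx(0.1)
    assert row["beta_out"] == pytest.approx(-0.05)
    assert row["effect_allele"] == "G"
    assert row["eaf"] == pytest.approx(0.7)


def test_palindromic_midfrequency_dropped():
    exp = make_table([("rs1", "1", 100, "A", "T", 0.50, 0.1, 0.01, 1e-8, 1000)])
    out = make_table([("rs1", "1", 100, "A", "T", 0.50, 0.05, 0.02, 1e-3, 1000)],
                     label="outcome")
    h = fm.harmonise_pair(exp, out)
    assert len(h) == 0
    assert list(h.dropped["reason"]) == ["palindromic"]


def test_palindromic_frequency_alignment():
    # exposure eaf 0.1 but outcome reports 0.9 for the same label: strand flip
    exp = make_table([("rs1", "1", 100, "A", "T", 0.10, 0.1, 0.01, 1e-8, 1000)])
    out = make_table([("rs1", "1", 100, "A", "T", 0.90, 0.05, 0.02, 1e-3, 1000)],
                     label="outcome")
    h = fm.harmonise_pair(exp, out)
    assert h.df.iloc[0]["beta_out"] == pytest.approx(-0.05)
    assert h.df.iloc[0]["strand_flipped"]


def test_incompatible_alleles_dropped():
    exp = make_table([("rs1", "1", 100, "A", "G", 0.3, 0.1, 0.01, 1e-8, 1000)])
    out = make_table([("rs1", "1", 100, "A", "C", 0.3, 0.05, 0.02, 1e-3, 1000)],
                     label="outcome")
    h = fm.harmonise_pair(exp, out)
    assert len(h) == 0
    assert list(h.dropped["reason"]) == ["allele_mismatch"]


def test_proxy_used_when_target_absent():
    exp = make_table([("rs1", "1", 100, "A", "G", 0.2, 0.1, 0.01, 1e-8, 1000)])
    out = make_table([("rsP", "1", 150, "C", "T", 0.25, 0.07, 0.02, 1e-4, 1000)],
                     label="outcome")
    ld = fm.LdReference()
    ld.add("rs1", "rsP", 0.9, dprime=0.95)
    h = fm.harmonise_pair(exp, out, ld_ref=ld, use_proxies=True)
    assert len(h) == 1
    assert h.df.iloc[0]["proxy_id"] == "rsP"
    assert h.df.iloc[0]["beta_out"] == pytest.approx(0.07)


def test_harmonisation_idempotent():
    sim = fm.scenario_params("causal", seed=11)
    arch = fm.simulate_architecture(sim)
    tabs = fm.simulate_summary_stats(arch, sim)
    h1 = fm.harmonise_pair(tabs["exposure"], tabs["outcome"])
    # rebuild tables from the harmonised orientation and re-harmonise
    exp2 = make_table([(r["variant_id"], "1", i + 1, r["effect_allele"],
                        r["other_allele"], r["eaf"], r["beta_exp"], r["se_exp"],
                        0.5, r["n_exp"])
                       for i, r in h1.df.iterrows()])
    out2 = make_table([(r["variant_id"], "1", i + 1, r["effect_allele"],
                        r["other_allele"], r["eaf"], r["beta_out"], r["se_out"],
                        0.5, r["n_out"])
                       for i, r in h1.df.iterrows()], label="outcome")
    h2 = fm.harmonise_pair(exp2, out2)
    np.testing.assert_allclose(h2.df["beta_exp"], h1.df["beta_exp"])
    np.testing.assert_allclose(h2.df["beta_out"], h1.df["beta_out"])
    assert not h2.df["allele_flipped"].any()


def test_add_mediator_aligns_and_drops():
    sim = fm.scenario_params("mediation", seed=5)
    arch = fm.simulate_architecture(sim)
    tabs = fm.simulate_summary_stats(arch, sim)
    h = fm.harmonise_pair(tabs["exposure"], tabs["outcome"])
    hm = fm.add_mediator(h, tabs["mediator"])
    assert hm.mediator_labels == ["mediator"]
    assert len(hm) == len(h)
    # mediator beta aligned to the exposure-increasing allele: flipping the
    # exposure allele in the source data flips the attached mediator effect
    med = tabs["mediator"].df.set_index("variant_id")
    row = hm.df.iloc[0]
    src = med.loc[row["variant_id"]]
    expected = src["beta"] if src["effect_allele"] == row["effect_allele"] else -src["beta"]
    assert row["beta_med_mediator"] == pytest.approx(expected)
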