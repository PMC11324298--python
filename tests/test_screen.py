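"""Candidate funnel filters and the HLA panel selection rule."""

import numpy as np
import pandas as pd
import pytest

from adductscan.binder import percentile_rank, score_peptide
from adductscan.screen import (
    ScreenConfig,
    enumerate_kmers,
    filter_overexpressed,
    map_orthologs,
    read_allele_frequencies_tsv,
    screen_candidates,
    select_hla_alleles,
    write_candidates_tsv,
)
from adductscan.synthetic import PlantSpec, gen_proteome


def expr_table(rows):
    return pd.DataFrame(rows, columns=["protein", "tissue", "level"])


@pytest.mark.parametrize("kidney, other_max, kept", [
    (40.0, 9.0, True),    # fold 4.44 > 4
    (40.0, 10.0, False),  # fold exactly 4: strictly-greater rule drops it
    (5.0, 0.0, True),     # infinite-fold convention
    (0.0, 0.0, False),
])
def test_filter_overexpressed_boundaries(kidney, other_max, kept):
    table = expr_table([("P1", "kidney", kidney), ("P1", "liver", other_max),
                        ("P1", "lung", other_max / 2 if other_max else 0.0)])
    passing, folds = filter_overexpressed(table)
    assert ("P1" in passing) is kept


def test_filter_overexpressed_denominator_rules_and_missing_target(caplog):
    table = expr_table([("P1", "kidney", 30.0), ("P1", "liver", 10.0),
                        ("P1", "lung", 2.0), ("P2", "liver", 5.0)])
    passing_max, folds_max = filter_overexpressed(table, denominator="max")
    assert folds_max["P1"] == pytest.approx(3.0)
    passing_mean, folds_mean = filter_overexpressed(table, denominator="mean")
    assert folds_mean["P1"] == pytest.approx(5.0)
    assert "P1" in passing_mean and "P1" not in passing_max
    assert "P2" not in folds_max  # missing kidney row: excluded, logged
    assert "P2" in caplog.text


@pytest.mark.parametrize("ids, table, mapped, dropped", [
    ({"H1", "H2"}, [("H1", "m1")], {"m1"}, {"H2"}),
    ({"H1", "H3"}, [("H1", "m1"), ("H3", "m1")], {"m1"}, set()),  # dedup
    ({"H1"}, [], set(), {"H1"}),
])
def test_map_orthologs(ids, table, mapped, dropped):
    df = pd.DataFrame(table, columns=["source", "target"])
    got_mapped, got_dropped = map_orthologs(ids, df)
    assert (got_mapped, got_dropped) == (mapped, dropped)


@pytest.mark.parametrize("length, k, n", [(9, 9, 1), (11, 9, 3), (8, 9, 0)])
def test_enumerate_kmers_window_count(length, k, n):
    kmers = enumerate_kmers("A" * length, k=k)
    assert len(kmers) == n
    if kmers:
        assert kmers[0][0] == 1 and kmers[-1][0] == length - k + 1
    with pytest.raises(ValueError):
        enumerate_kmers("AAAA", k=0)


@pytest.fixture(scope="module")
def planted():
    spec = PlantSpec(seed=42)
    fx = gen_proteome(spec)
    config = ScreenConfig(seed=42)
    df = screen_candidates(fx.sequences, fx.expression, fx.orthologs,
                           fx.allele, fx.pssm, spec.favorable_positions, config)
    return spec, fx, config, df


def test_screen_recovers_planted_candidates_exactly(planted):
    spec, fx, _, df = planted
    got = set(map(tuple, df.loc[df["pass_all"],
                                ["protein", "start", "peptide"]]
                  .itertuples(index=False)))
    truth = set(map(tuple, fx.truth[["protein", "start", "peptide"]]
                    .itertuples(index=False)))
    assert got == truth


def test_screen_output_is_subset_of_mapped_kmers(planted):
    spec, fx, _, df = planted
    allowed = set()
    mapped = set(fx.orthologs["target"])
    for pid, seq in fx.sequences.items():
        if pid in mapped:
            allowed |= {(pid, s, p) for s, p in enumerate_kmers(seq, 9)}
    emitted = set(map(tuple, df[["protein", "start", "peptide"]]
                      .itertuples(index=False)))
    assert emitted <= allowed


def test_screen_flags_audit_independently(planted):
    """Post-hoc oracle: every fully-passing record re-satisfies all three
    filter predicates when re-evaluated from the raw inputs."""
    spec, fx, config, df = planted
    passing_expr, folds = filter_overexpressed(fx.expression)
    from adductscan.binder import background_scores
    bg = background_scores(fx.pssm, n=config.background_size,
                           rng=np.random.default_rng([config.seed, 7919]))
    for row in df[df["pass_all"]].itertuples():
        assert row.fold_change > config.fold_threshold
        rank = percentile_rank(score_peptide(row.peptide, fx.pssm), bg)
        assert rank <= config.rank_threshold
        lys = {i for i, aa in enumerate(row.peptide, start=1) if aa == "K"}
        assert lys & spec.favorable_positions


def test_screen_idempotent_on_its_own_passing_proteins(planted):
    spec, fx, config, df = planted
    keep = set(df.loc[df["pass_all"], "protein"])
    sub = {k: v for k, v in fx.sequences.items() if k in keep}
    df2 = screen_candidates(sub, fx.expression, fx.orthologs, fx.allele,
                            fx.pssm, spec.favorable_positions, config)
    got = df2.loc[df2["pass_all"]].reset_index(drop=True)
    want = df.loc[df["pass_all"]].reset_index(drop=True)
    pd.testing.assert_frame_equal(got, want)


def test_screen_output_tsv_byte_identical(planted, tmp_path):
    spec, fx, config, df = planted
    df2 = screen_candidates(fx.sequences, fx.expression, fx.orthologs,
                            fx.allele, fx.pssm, spec.favorable_positions,
                            config)
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_candidates_tsv(df, p1)
    write_candidates_tsv(df2, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_screen_no_lysine_proteome_yields_nothing(planted):
    spec, fx, config, _ = planted
    stripped = {k: v.replace("K", "A") for k, v in fx.sequences.items()}
    df = screen_candidates(stripped, fx.expression, fx.orthologs, fx.allele,
                           fx.pssm, spec.favorable_positions, config)
    assert not df["pass_all"].any()


def test_screen_zero_rank_threshold_rejects_everything(planted):
    spec, fx, _, _ = planted
    config = ScreenConfig(seed=42, rank_threshold=-1.0)
    df = screen_candidates(fx.sequences, fx.expression, fx.orthologs,
                           fx.allele, fx.pssm, spec.favorable_positions, config)
    assert not df["pass_all"].any()


def test_screen_input_validation(planted):
    spec, fx, config, _ = planted
    with pytest.raises(ValueError, match="empty"):
        screen_candidates({}, fx.expression, fx.orthologs, fx.allele,
                          fx.pssm, spec.favorable_positions, config)
    with pytest.raises(ValueError, match="favorable"):
        screen_candidates(fx.sequences, fx.expression, fx.orthologs,
                          fx.allele, fx.pssm, [], config)


def freq_table(rows):
    return pd.DataFrame(rows, columns=["population", "allele", "frequency"])


def test_select_hla_union_with_duplicates():
    table = freq_table([
        ("EUR", "A*02:01", 0.45), ("EUR", "B*07:02", 0.20),
        ("CHN", "A*02:01", 0.35), ("CHN", "A*11:01", 0.30),
    ])
    panel, prov = select_hla_alleles(table)
    assert panel == ["A*02:01", "A*11:01", "B*07:02"]
    assert prov["A*02:01"] == ["CHN", "EUR"]


def test_select_hla_threshold_and_truncation():
    rows = [("EUR", f"A*{i:02d}:01", 0.06 + 0.01 * i) for i in range(12)]
    panel, _ = select_hla_alleles(freq_table(rows), top_n=10)
    assert len(panel) == 10
    # the two lowest-frequency alleles fall off the top-10
    assert "A*00:01" not in panel and "A*01:01" not in panel
    assert select_hla_alleles(freq_table(rows), min_freq=1.0)[0] == []


def test_select_hla_strict_min_freq_and_tie_break():
    table = freq_table([("P", "B*08:01", 0.05), ("P", "A*01:01", 0.07),
                        ("P", "A*02:01", 0.07)])
    panel, _ = select_hla_alleles(table, min_freq=0.05, top_n=1)
    assert panel == ["A*01:01"]  # 0.05 excluded (strict), tie by name


def test_frequency_table_validation(tmp_path):
    bad = tmp_path / "f.tsv"
    bad.write_text("population\tallele\tfrequency\nP\tA\t1.5\n")
    with pytest.raises(ValueError, match="0, 1"):
        read_allele_frequencies_tsv(bad)
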