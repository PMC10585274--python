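import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrmediate import (
    DataError,
    DomainError,
    InstrumentSet,
    PairwiseLD,
    clump,
    f_statistic,
    filter_weak,
    select_by_pvalue,
    select_instruments,
    snp_r2,
)
from mrmediate.io import frame_to_records

from conftest import make_frame


# ---------------------------------------------------------------- p-value gate
def test_select_by_pvalue_keeps_only_below_threshold():
    frame = make_frame([{"pval": 1e-6}, {"pval": 1e-4}, {"pval": 1e-2}])
    kept = select_by_pvalue(frame, 5e-5)
    assert [r.snp_id for r in kept] == ["rs1"]


def test_select_by_pvalue_threshold_one_keeps_everything():
    frame = make_frame([{"pval": 0.2}, {"pval": 0.9}])
    assert len(select_by_pvalue(frame, 1.0)) == 2


def test_select_by_pvalue_empty_result_warns(caplog):
    frame = make_frame([{"pval": 0.5}])
    with caplog.at_level("WARNING"):
        kept = select_by_pvalue(frame, 5e-5)
    assert kept == [] and "no records below" in caplog.text


def test_select_by_pvalue_is_idempotent():
    frame = make_frame([{"pval": p} for p in (1e-9, 1e-6, 1e-3, 0.4)])
    once = select_by_pvalue(frame, 1e-4)
    twice = select_by_pvalue([r for r in once], 1e-4)
    assert once == twice


# ---------------------------------------------------------------- clumping
def _ld_from_pairs(ids, pairs):
    ld = PairwiseLD(ids)
    for a, b, r2 in pairs:
        ld.set_r2(a, b, r2)
    return ld


def test_clump_keeps_best_snp_in_tight_ld_cluster():
    frame = make_frame(
        [
            {"pval": 1e-8, "pos": 1_000_000},
            {"pval": 1e-6, "pos": 1_500_000},
            {"pval": 1e-5, "pos": 2_000_000},
        ]
    )
    ld = _ld_from_pairs(
        ["rs1", "rs2", "rs3"],
        [("rs1", "rs2", 0.5), ("rs1", "rs3", 0.5), ("rs2", "rs3", 0.5)],
    )
    kept = clump(frame, ld, r2_threshold=0.001, window_bp=10_000_000)
    assert [r.snp_id for r in kept] == ["rs1"]


def test_clump_retains_pairs_outside_window_or_below_r2():
    # 20 Mb apart: distance rule protects despite high r²
    far = make_frame([{"pval": 1e-8, "pos": 1_000_000}, {"pval": 1e-6, "pos": 21_000_000}])
    ld = _ld_from_pairs(["rs1", "rs2"], [("rs1", "rs2", 0.9)])
    assert len(clump(far, ld, window_bp=10_000_000)) == 2
    # 1 Mb apart but r² below threshold
    near = make_frame([{"pval": 1e-8, "pos": 1_000_000}, {"pval": 1e-6, "pos": 2_000_000}])
    ld2 = _ld_from_pairs(["rs1", "rs2"], [("rs1", "rs2", 0.0005)])
    assert len(clump(near, ld2, r2_threshold=0.001)) == 2


def test_clump_missing_snp_names_the_offender():
    frame = make_frame([{}, {}])
    ld = PairwiseLD(["rs1"])
    with pytest.raises(DataError, match="rs2"):
        clump(frame, ld)


def _random_instance(rng, n):
    rows = []
    for i in range(n):
        rows.append(
            {
                "chrom": str(rng.integers(1, 3)),
                "pos": int(rng.integers(1, 3_000_000)),
                "pval": float(rng.choice([1e-8, 1e-7, 1e-6, 1e-5]) * rng.integers(1, 4)),
            }
        )
    frame = make_frame(rows)
    ids = list(frame["snp_id"])
    ld = PairwiseLD(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.5:
                ld.set_r2(ids[i], ids[j], float(rng.random()))
    return frame, ld


def _brute_force_clump(records, ld, r2_threshold, window_bp):
    """Enumerate all subsets; return the unique one that is independent and
    p-value-dominant (every excluded SNP conflicts with a better kept SNP)."""
    recs = list(records)
    key = lambda r: (r.pval, r.chrom, r.pos, r.snp_id)

    def conflict(a, b):
        return (
            a.chrom == b.chrom
            and abs(a.pos - b.pos) <= window_bp
            and ld.r2(a.snp_id, b.snp_id) >= r2_threshold
        )

    solutions = []
    for mask in range(1 << len(recs)):
        chosen = [r for i, r in enumerate(recs) if mask >> i & 1]
        rest = [r for i, r in enumerate(recs) if not mask >> i & 1]
        independent = all(
            not conflict(a, b) for k, a in enumerate(chosen) for b in chosen[k + 1 :]
        )
        dominant = all(
            any(conflict(c, r) and key(c) < key(r) for c in chosen) for r in rest
        )
        if independent and dominant:
            solutions.append(chosen)
    assert len(solutions) == 1
    return sorted(r.snp_id for r in solutions[0])


def test_clump_matches_brute_force_on_small_instances(rng):
    for _ in range(60):
        n = int(rng.integers(2, 9))
        frame, ld = _random_instance(rng, n)
        greedy = clump(frame, ld, r2_threshold=0.3, window_bp=1_000_000)
        oracle = _brute_force_clump(
            frame_to_records(frame), ld, r2_threshold=0.3, window_bp=1_000_000
        )
        assert sorted(r.snp_id for r in greedy) == oracle


def test_clump_is_invariant_to_row_order(rng):
    frame, ld = _random_instance(rng, 10)
    shuffled = frame.sample(frac=1.0, random_state=5).reset_index(drop=True)
    a = [r.snp_id for r in clump(frame, ld, r2_threshold=0.3, window_bp=1_000_000)]
    b = [r.snp_id for r in clump(shuffled, ld, r2_threshold=0.3, window_bp=1_000_000)]
    assert a == b


# ---------------------------------------------------------------- strength
def test_snp_r2_printed_formula_hand_value():
    rec = frame_to_records(make_frame([{"eaf": 0.5, "beta": 0.004, "se": 0.01}]))[0]
    assert snp_r2(rec, mode="printed") == pytest.approx(0.08)  # 2*0.25*0.16


def test_snp_r2_vanishes_with_null_effect_or_extreme_eaf():
    null = frame_to_records(make_frame([{"beta": 0.0}]))[0]
    assert snp_r2(null, mode="printed") == 0.0
    assert snp_r2(null, mode="normalized") == 0.0
    rare = frame_to_records(make_frame([{"eaf": 1e-9}]))[0]
    assert snp_r2(rare, mode="printed") == pytest.approx(0.0, abs=1e-6)


def test_snp_r2_normalized_is_bounded():
    rec = frame_to_records(make_frame([{"beta": 5.0, "se": 0.01, "n": 100.0}]))[0]
    assert snp_r2(rec, mode="printed") > 1.0  # the shorthand can exceed 1
    assert 0.0 < snp_r2(rec, mode="normalized") < 1.0


def test_f_statistic_hand_values():
    assert f_statistic(0.05, 450_000, 50) == pytest.approx((0.05 / 50) / (0.95 / 449_949))
    assert f_statistic(0.0, 1000, 5) == 0.0
    assert f_statistic(0.5, 3, 1) == pytest.approx(1.0)


def test_f_statistic_domain_errors():
    with pytest.raises(DomainError):
        f_statistic(1.0, 1000, 5)
    with pytest.raises(DomainError):
        f_statistic(0.1, 5, 5)


def test_filter_weak_leaves_strong_set_unchanged(caplog):
    frame = make_frame([{"beta": 0.05, "se": 0.005, "n": 50_000.0} for _ in range(5)])
    iset = InstrumentSet(exposure_name="x", records=frame_to_records(frame))
    with caplog.at_level("INFO"):
        out = filter_weak(iset, f_min=10)
    assert [r.snp_id for r in out.records] == [r.snp_id for r in iset.records]
    assert out.f_stat >= 10
    assert "set unchanged" in caplog.text


def test_filter_weak_drops_weakest_until_f_reaches_threshold():
    # two moderate SNPs plus one nearly-null one whose inclusion dilutes F
    frame = make_frame(
        [
            {"beta": 0.04, "se": 0.01, "n": 100.0},
            {"beta": 0.04, "se": 0.01, "n": 100.0},
            {"beta": 0.001, "se": 0.01, "n": 100.0},
        ]
    )
    iset = InstrumentSet(exposure_name="x", records=frame_to_records(frame))
    weak_f = filter_weak(iset, f_min=0.0).f_stat  # no filtering, just measure
    assert weak_f < 13
    out = filter_weak(iset, f_min=13)
    assert len(out.records) == 2
    assert out.f_stat >= 13
    assert "rs3" not in [r.snp_id for r in out.records]


def test_select_instruments_orders_by_pvalue(small_study):
    iset = select_instruments(
        small_study.exposure_stats, ld_matrix=small_study.pairwise_ld()
    )
    pvals = [r.pval for r in iset.records]
    assert pvals == sorted(pvals)
    assert all(p < 5e-5 for p in pvals)
    assert iset.f_stat > 10


@settings(deadline=None, max_examples=25)
@given(threshold=st.floats(min_value=1e-10, max_value=1.0))
def test_pvalue_gate_is_exact(threshold):
    frame = make_frame([{"pval": p} for p in (1e-9, 5e-5, 1e-4, 0.05, 1.0)])
    kept = {r.snp_id for r in select_by_pvalue(frame, threshold)}
    expected = {f"rs{i+1}" for i, p in enumerate((1e-9, 5e-5, 1e-4, 0.05, 1.0)) if p < threshold}
    assert kept == expected
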