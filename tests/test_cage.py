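"""CAGE tag clustering, TPM normalization and promoter comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from promdel import (
    BelowFloorError,
    InputError,
    SimConfig,
    TagTable,
    cluster_tags,
    compare_samples,
    normalize_tpm,
    promoter_activity,
    promoter_fold,
    sample_ratio,
    simulate_cage,
    with_deletion_halved_1b,
)
from promdel.datasets import load_promoter_tpm, load_promoter_windows


def _table(rows, total_mapped, sample="s"):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])
    return TagTable(sample_id=sample, records=df, total_mapped=total_mapped)


# ------------------------------------------------------------- TPM


@pytest.mark.parametrize(
    "count,total,tpm",
    [(117, 10**7, 11.7), (0, 100, 0.0), (500, 500, 1e6)],
)
def test_tpm_normalization(count, total, tpm):
    assert normalize_tpm(count, total) == pytest.approx(tpm)


def test_tpm_needs_positive_library():
    with pytest.raises(InputError):
        normalize_tpm(10, 0)


@given(count=st.integers(0, 10**6), total=st.integers(1, 10**8), k=st.integers(1, 50))
def test_tpm_invariant_under_uniform_scaling(count, total, k):
    if count > total:
        count = total
    assert normalize_tpm(count * k, total * k) == pytest.approx(
        normalize_tpm(count, total)
    )


# -------------------------------------------------------- clustering


def test_empty_table_gives_no_clusters():
    assert cluster_tags(_table([], 1000)) == []


def test_gap_rule_splits_clusters():
    t = _table(
        [("c", 100, "+", 5000), ("c", 105, "+", 5000), ("c", 160, "+", 5000)],
        100_000,
    )
    clusters = cluster_tags(t, max_gap=20)
    spans = [(c.start, c.end) for c in clusters]
    assert spans == [(100, 105), (160, 160)]


def test_strands_cluster_separately():
    t = _table([("c", 100, "+", 1000), ("c", 101, "-", 1000)], 2000)
    assert len(cluster_tags(t, max_gap=20)) == 2


def test_density_filter_is_strict():
    # width 10, 0.5 TPM -> 0.05 TPM/base: omitted
    t = _table([("c", 100, "+", 25), ("c", 109, "+", 25)], 10**8)
    assert cluster_tags(t, max_gap=20, min_density=0.1) == []
    kept = cluster_tags(t, max_gap=20, min_density=0)
    assert len(kept) == 1 and kept[0].tpm == pytest.approx(0.5)


def test_boundary_density_survives_float_rounding():
    # a single tag worth exactly 0.1 TPM has density exactly 0.1: kept
    t = _table([("c", 100, "+", 1)], 10**7)
    assert len(cluster_tags(t)) == 1


def test_unsorted_records_rejected():
    df = pd.DataFrame(
        [("c", 200, "+", 1), ("c", 100, "+", 1)],
        columns=["chrom", "pos", "strand", "count"],
    )
    with pytest.raises(InputError):
        cluster_tags(TagTable("s", df, 1000))


def test_prefilter_tpm_mass_is_conserved():
    gen = np.random.default_rng(3)
    pos = np.sort(gen.integers(1, 5000, size=200))
    rows = [("c", int(p), "+", int(c)) for p, c in zip(pos, gen.integers(1, 50, 200))]
    table = _table(rows, 10**6)
    clusters = cluster_tags(table, max_gap=20, min_density=0)
    total_tags = sum(r[3] for r in rows)
    assert sum(c.tpm for c in clusters) == pytest.approx(
        1e6 * total_tags / table.total_mapped
    )
    assert sum(c.tag_count for c in clusters) == total_tags


def test_clustering_idempotent_under_reclustering():
    gen = np.random.default_rng(4)
    pos = np.sort(gen.integers(1, 2000, size=50))
    rows = [("c", int(p), "+", 1) for p in pos]
    table = _table(rows, 10**5)
    once = cluster_tags(table, min_density=0)
    # re-feed cluster peaks+counts: collapsing members cannot move boundaries
    spans1 = [(c.start, c.end, c.tag_count) for c in once]
    again = cluster_tags(table, min_density=0)
    assert spans1 == [(c.start, c.end, c.tag_count) for c in again]


# ------------------------------------------------- promoter activity


def test_activity_sums_same_strand_overlaps_only():
    windows = pd.DataFrame(
        [{"name": "P", "chrom": "c", "start": 90, "end": 120, "strand": "+"}]
    )
    t = _table(
        [("c", 100, "+", 40), ("c", 500, "+", 40), ("c", 100, "-", 40)], 10**6
    )
    acts = promoter_activity(cluster_tags(t), windows, "s")
    assert acts[0].tpm == pytest.approx(40.0)  # only the same-strand overlap


def test_activity_below_floor_renders_as_floor():
    windows = pd.DataFrame(
        [{"name": "P", "chrom": "c", "start": 90, "end": 120, "strand": "+"}]
    )
    acts = promoter_activity([], windows, "s")
    assert acts[0].tpm == 0.0 and acts[0].below_floor
    assert acts[0].render() == "<0.1"


def test_overlapping_windows_assign_by_peak():
    windows = pd.DataFrame(
        [
            {"name": "L", "chrom": "c", "start": 50, "end": 110, "strand": "+"},
            {"name": "R", "chrom": "c", "start": 100, "end": 160, "strand": "+"},
        ]
    )
    # cluster spans 95-130 but peaks at 120: credit R only
    t = _table(
        [("c", 95, "+", 10), ("c", 105, "+", 10), ("c", 120, "+", 100), ("c", 130, "+", 10)],
        10**6,
    )
    acts = {a.promoter: a.tpm for a in promoter_activity(cluster_tags(t), windows, "s")}
    assert acts["R"] == pytest.approx(130.0)
    assert acts["L"] == 0.0


# ------------------------------------------------------ folds/ratios


def test_promoter_fold_reproduces_blood_table():
    tpm = load_promoter_tpm().set_index("promoter")
    assert promoter_fold(tpm.loc["APC-1B", "control1"], tpm.loc["APC-1A", "control1"]) == 44.5
    assert sample_ratio(tpm.loc["APC-1B", "patient"], tpm.loc["APC-1B", "control1"]) == 39
    assert sample_ratio(tpm.loc["APC-1B", "patient"], tpm.loc["APC-1B", "control2"]) == 45
    assert bool(tpm.loc["APC-1A", "control2_below_floor"])


def test_fold_undefined_below_floor():
    with pytest.raises(BelowFloorError):
        promoter_fold(26.18, 0.09)


def test_fold_and_ratio_identities():
    assert promoter_fold(3.3, 3.3) == 1.0
    assert sample_ratio(7.7, 7.7) == 100
    with pytest.raises(InputError):
        sample_ratio(1.0, 0.0)


def test_compare_samples_flags_floor_control():
    from promdel import PromoterActivity

    acts = [
        PromoterActivity("patient", "APC-1B", 11.70, False),
        PromoterActivity("patient", "APC-1A", 1.72, False),
        PromoterActivity("c1", "APC-1B", 30.28, False),
        PromoterActivity("c1", "APC-1A", 0.68, False),
        PromoterActivity("c2", "APC-1B", 26.18, False),
        PromoterActivity("c2", "APC-1A", 0.05, True),
    ]
    rep = compare_samples(acts, "patient", ["c1", "c2"]).set_index("control")
    assert rep.loc["c1", "fold_vs_APC_1A"] == 44.5
    assert np.isnan(rep.loc["c2", "fold_vs_APC_1A"])
    assert bool(rep.loc["c2", "reference_below_floor"])
    assert rep.loc["c1", "patient_pct_of_control"] == 39
    assert rep.loc["c2", "patient_pct_of_control"] == 45


# ----------------------------------------------------- end to end


def test_simulated_halving_recovered():
    """Halving the APC-1B tag rate in the patient library halves the
    measured promoter TPM within 3 Poisson standard errors."""
    cfg = SimConfig(seed=21)
    windows = load_promoter_windows()
    ctl = simulate_cage(cfg, "control1")
    pat = simulate_cage(with_deletion_halved_1b(cfg), "patient")
    a_ctl = {a.promoter: a.tpm for a in promoter_activity(cluster_tags(ctl), windows, "c")}
    a_pat = {a.promoter: a.tpm for a in promoter_activity(cluster_tags(pat), windows, "p")}
    rate = cfg.promoter_rates["APC-1B"]
    ratio = a_pat["APC-1B"] / a_ctl["APC-1B"]
    se = 0.5 * np.sqrt(1 / (rate / 2) + 1 / rate)  # delta-method SE of the ratio
    assert abs(ratio - 0.5) <= 3 * se


def test_single_promoter_tpm_recovers_rate():
    cfg = SimConfig(
        seed=8,
        promoter_rates={"APC-1B": 2000.0},
        background_rate=0.0,
    )
    table = simulate_cage(cfg, "s")
    clusters = cluster_tags(table)
    assert len(clusters) == 1
    expected = 1e6 * 2000.0 / cfg.library_size
    se = 1e6 * np.sqrt(2000.0) / cfg.library_size
    assert abs(clusters[0].tpm - expected) <= 3 * se
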