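"""Beta-posterior variant scoring and pathogenicity triage."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from promdel import (
    CallerConfig,
    GeneThresholds,
    InputError,
    PileupColumn,
    SimConfig,
    beta_posterior,
    call_variants,
    classify_table,
    classify_variant,
    simulate_pileup,
    variant_score,
)
from promdel.datasets import load_variant_table

from _oracles import beta_survival_quadrature


@pytest.mark.parametrize(
    "alt,depth,a0,b0,expected",
    [
        (0, 0, 1, 1, (1, 1)),  # no data returns the prior
        (10, 30, 1, 1, (11, 21)),
        (0, 100, 1, 1, (1, 101)),
        (5, 9, 0.5, 0.5, (5.5, 4.5)),
    ],
)
def test_beta_posterior_conjugate_update(alt, depth, a0, b0, expected):
    assert beta_posterior(alt, depth, a0, b0) == expected


def test_beta_posterior_rejects_bad_input():
    with pytest.raises(InputError):
        beta_posterior(5, 3)
    with pytest.raises(InputError):
        beta_posterior(1, 2, prior_a=0.0)


def test_score_closed_form_for_flat_shape():
    # Beta(1, b) survival at theta is (1 - theta)^b
    for b in (1, 5, 101, 200):
        for theta in (0.01, 0.05, 0.3):
            assert variant_score((1, b), theta) == pytest.approx(
                (1 - theta) ** b, abs=1e-12
            )


def test_score_matches_quadrature():
    for a in (1, 2, 11, 50, 200):
        for b in (1, 21, 101, 200):
            for theta in (0.01, 0.05, 0.2, 0.5):
                assert variant_score((a, b), theta) == pytest.approx(
                    beta_survival_quadrature(a, b, theta), abs=1e-8
                )


def test_score_approaches_one_as_theta_vanishes():
    assert variant_score((11, 21), 1e-12) == pytest.approx(1.0, abs=1e-9)


@given(
    depth=st.integers(1, 200),
    alt=st.integers(0, 200),
    extra=st.integers(1, 50),
)
def test_score_monotone_in_alt_and_depth(depth, alt, extra):
    """More supporting reads can only raise the score; more covering reads at
    fixed support can only lower it."""
    alt = min(alt, depth)
    up_alt = variant_score(beta_posterior(min(alt + 1, depth), depth))
    base = variant_score(beta_posterior(alt, depth))
    deeper = variant_score(beta_posterior(alt, depth + extra))
    assert up_alt >= base - 1e-12
    assert deeper <= base + 1e-12


def _col(pos, ref, counts, chrom="c1"):
    return PileupColumn(chrom=chrom, pos=pos, ref_base=ref, counts=counts)


def test_call_threshold_is_strict():
    col = _col(1, "A", {"A": 20, "C": 10})
    score = variant_score(beta_posterior(10, 30))
    at_threshold = CallerConfig(call_threshold=score)
    below = CallerConfig(call_threshold=score - 1e-9)
    assert not call_variants([col], at_threshold)[0].called  # equality: no call
    assert call_variants([col], below)[0].called


def test_call_variants_calls_clear_het():
    calls = call_variants([_col(5, "A", {"A": 20, "C": 10})])
    assert calls[0].called and calls[0].alt == "C" and calls[0].score > 0.9


def test_all_reference_column_yields_no_candidate():
    assert call_variants([_col(1, "G", {"G": 30})]) == []


def test_depth_floor_blocks_shallow_calls():
    # 3/4 alt reads score far above 0.9 but depth 4 < min_depth 8
    calls = call_variants([_col(1, "A", {"A": 1, "T": 3})])
    assert calls[0].score > 0.9 and not calls[0].called


def test_multiallelic_pick_max_count_then_lexicographic():
    calls = call_variants([_col(1, "A", {"A": 10, "C": 9, "G": 9, "T": 2})])
    assert calls[0].alt == "C"  # tie at 9 between C and G -> lexicographic


def test_indel_alleles_scored_like_snvs():
    calls = call_variants([_col(1, "A", {"A": 15, "+AG": 15})])
    assert calls[0].called and calls[0].alt == "+AG"


def test_unsorted_columns_rejected():
    cols = [_col(5, "A", {"A": 10}), _col(2, "C", {"C": 10})]
    with pytest.raises(InputError):
        call_variants(cols)


def test_screen_on_simulated_pileup_recall_and_false_calls():
    """At ~30x depth and 1% error the caller finds every injected het site
    and mis-calls fewer than 1 in 1000 error-only positions."""
    cfg = SimConfig(
        seed=3, region_length_bp=100_000, deletion_interval=None, error_rate=0.01
    )
    calls = call_variants(simulate_pileup(cfg))
    het_pos = {p for p, _, _ in cfg.het_sites}
    called_pos = {c.pos for c in calls if c.called}
    assert het_pos <= called_pos
    n_false = len(called_pos - het_pos)
    assert n_false / (cfg.region_length_bp - len(het_pos)) < 1e-3


# ---------------------------------------------------------------- triage


def test_database_status_wins():
    assert classify_variant("nonsynonymous", "non-pathologic", 0.0, "APC")[0] == (
        "non-pathologic"
    )
    assert classify_variant("synonymous", "pathologic", None, "APC")[0] == (
        "candidate-pathologic"
    )


def test_frequency_rule_is_strict_per_gene():
    t = GeneThresholds()
    # MUTYH cutoff 0.05: above -> non-pathologic, at/below -> VUS
    assert classify_variant("nonsynonymous", None, 0.30, "MUTYH", t)[0] == "non-pathologic"
    assert classify_variant("nonsynonymous", None, 0.05, "MUTYH", t)[0] == "VUS"
    # APC cutoff 0.01
    assert classify_variant("nonsynonymous", None, 0.02, "APC", t)[0] == "non-pathologic"
    assert classify_variant("nonsynonymous", None, 0.0017, "NTHL1", t)[0] == "VUS"


def test_missing_af_flags_vus():
    label, flags = classify_variant("nonsynonymous", None, None, "POLE")
    assert label == "VUS" and "no-AF" in flags


def test_synonymous_uncharacterized_is_non_pathologic():
    assert classify_variant("synonymous", None, None, "POLE")[0] == "non-pathologic"


def test_polyposis_panel_triage():
    """The packaged 15-variant polyposis-gene screen: 14 non-pathologic
    (12 synonymous, one database-annotated missense, one common MUTYH
    missense) and the rare NTHL1 missense as the single VUS."""
    table = classify_table(load_variant_table())
    counts = table["classification"].value_counts()
    assert counts["non-pathologic"] == 14
    assert counts["VUS"] == 1
    assert table.loc[table.rsid == "rs200420874", "classification"].item() == "VUS"
    assert (
        table.loc[table.rsid == "rs3219489", "classification"].item() == "non-pathologic"
    )
    assert (
        table.loc[table.rsid == "rs2229992", "classification"].item() == "non-pathologic"
    )


def test_vectorised_scores_match_scalar():
    a = np.array([1.0, 11.0, 3.0])
    b = np.array([101.0, 21.0, 29.0])
    bulk = variant_score((a, b), 0.05)
    for i in range(3):
        assert bulk[i] == pytest.approx(variant_score((a[i], b[i]), 0.05), abs=1e-14)
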