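"""Enrichment-score pipeline: filtering, frequencies, ES, logos, ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcphage import (
    CloneRecord,
    FitnessModel,
    SelectionConfig,
    conserved_positions,
    emit_reads,
    enrichment_score,
    es_matrix,
    export_heatmap,
    logo_matrix,
    position_frequencies,
    rank_clones,
    read_es_csv,
    render_logo,
    reverse_translate,
    sample_naive_library,
    simulate_campaign,
    translate_and_filter,
)
from dcphage.enrichment import ESMatrix
from dcphage.simulate import RoundCounts


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "f0,f1,expected",
    [
        (0.2, 0.2, 0.0),
        (0.2, 0.0, -1.0),
        (0.0, 0.3, 0.3),
        (0.05, 0.5, (0.5 - 0.05) / (1 - 0.05)),
        (0.0, 0.0, 0.0),
        (1.0, 1.0, 0.0),
        (0.0, 1.0, 1.0),
    ],
)
def test_enrichment_score_values(f0, f1, expected):
    assert enrichment_score(f0, f1) == pytest.approx(expected, abs=1e-12)


def test_enrichment_score_rejects_out_of_range():
    with pytest.raises(ValueError):
        enrichment_score(-0.1, 0.5)
    with pytest.raises(ValueError):
        enrichment_score(0.5, 1.5)


@given(
    f0=st.floats(min_value=0, max_value=1, allow_nan=False),
    f1=st.floats(min_value=0, max_value=1, allow_nan=False),
)
@settings(derandomize=True, max_examples=300)
def test_enrichment_score_range_and_sign(f0, f1):
    es = enrichment_score(f0, f1)
    assert -1 <= es <= 1
    if f1 > f0:
        assert es > 0
    elif f1 < f0:
        assert es < 0
    else:
        assert es == 0


def test_enrichment_score_grid_sweep():
    grid = np.linspace(0, 1, 101)
    for f0 in grid:
        for f1 in grid:
            es = enrichment_score(f0, f1)
            assert -1 <= es <= 1
            if f1 > f0:
                assert es > 0
            elif f1 < f0:
                assert es < 0
            else:
                assert es == 0


def test_enrichment_score_continuity_at_the_branch_point():
    for f0 in [0.1, 0.5, 0.9]:
        assert abs(enrichment_score(f0, f0 + 1e-6)) < 1e-4
        assert abs(enrichment_score(f0, f0 - 1e-6)) < 1e-4


# ---------------------------------------------------------------------------
# filtering and frequency matrices
# ---------------------------------------------------------------------------

def test_translate_and_filter_accepts_clean_simulator_output(loop5_design):
    rc = sample_naive_library(loop5_design, 1000, seed=4)
    reads = emit_reads(rc, loop5_design, error_rate=0.0, seed=0)
    records = translate_and_filter(reads, loop5_design)
    assert sum(r.count for r in records if r.valid) == 1000
    assert all(r.valid for r in records)


def test_translate_and_filter_rejection_reasons(loop5_design, eeti):
    broken_cys = eeti.template[:8] + "R" + eeti.template[9:]  # Cys9 -> Arg
    stop_read = reverse_translate(eeti.template)[:-6] + "TAATGA"
    short = eeti.template[:20]
    records = translate_and_filter(
        [reverse_translate(broken_cys), stop_read, reverse_translate(short)],
        loop5_design,
    )
    reasons = {r.reason for r in records if not r.valid}
    assert len(records) == 3 and not any(r.valid for r in records)
    assert any("cysteine" in r for r in reasons)
    assert any("stop" in r for r in reasons)
    assert any("length" in r for r in reasons)


def test_translate_and_filter_rejects_mixed_input(loop5_design, eeti):
    with pytest.raises(ValueError, match="mixed"):
        translate_and_filter([eeti.template, reverse_translate(eeti.template)], loop5_design)


def test_position_frequencies_tiny_cases():
    fm = position_frequencies([CloneRecord("ACD", 10)])
    assert fm.values.loc[1, "A"] == 1.0
    assert fm.values.loc[2, "C"] == 1.0
    assert fm.values.loc[3, "D"] == 1.0
    fm2 = position_frequencies([CloneRecord("AAA", 1), CloneRecord("AAC", 1)])
    assert fm2.values.loc[3, "A"] == 0.5 and fm2.values.loc[3, "C"] == 0.5


def test_position_frequencies_weighting_modes():
    records = [CloneRecord("AA", 9), CloneRecord("AC", 1)]
    by_count = position_frequencies(records, weighting="count")
    by_unique = position_frequencies(records, weighting="unique")
    assert by_count.values.loc[2, "C"] == pytest.approx(0.1)
    assert by_unique.values.loc[2, "C"] == pytest.approx(0.5)


def test_position_frequencies_refuses_mixed_lengths_silently():
    records = [CloneRecord("AA", 1), CloneRecord("AAA", 1)]
    with pytest.raises(ValueError, match="length"):
        position_frequencies(records)
    fm = position_frequencies(records, length=2)
    assert fm.length == 2 and fm.total == 1


def test_position_frequencies_permutation_equivariant(loop5_design):
    rc = sample_naive_library(loop5_design, 500, seed=8)
    reads = emit_reads(rc, loop5_design, 0.0, seed=0)
    a = position_frequencies(translate_and_filter(reads, loop5_design))
    b = position_frequencies(translate_and_filter(list(reversed(reads)), loop5_design))
    pd.testing.assert_frame_equal(a.values, b.values)


def test_naive_frequencies_close_to_design_profiles(loop5_design):
    from dcphage import positional_profiles

    n = 50_000
    rc = sample_naive_library(loop5_design, n, seed=12)
    records = [CloneRecord(s, c) for s, c in rc.counts.items()]
    fm = position_frequencies(records)
    (cls,) = positional_profiles(loop5_design).keys()
    profiles = positional_profiles(loop5_design)[cls]
    se = math.sqrt((1 / 19) * (18 / 19) / n)
    # 4 SE for a max-over-95-cells bound (per-cell 3 SE crosses by chance)
    for pos in range(22, 27):
        prof = profiles[pos - 1].condition_on_sense()
        for aa in prof.support:
            assert abs(fm.values.loc[pos, aa] - float(prof[aa])) < 4 * se + 1e-12


# ---------------------------------------------------------------------------
# ES matrices, heatmap export, ranking, conservation, logos
# ---------------------------------------------------------------------------

def _freq(records, **kw):
    return position_frequencies(records, **kw)


def test_es_matrix_zero_when_pools_identical():
    records = [CloneRecord("ACD", 5), CloneRecord("ACE", 5)]
    f = _freq(records)
    es = es_matrix(f, f)
    assert (es.values.to_numpy() == 0).all()


def test_es_matrix_refuses_cross_length_comparison():
    f2 = _freq([CloneRecord("AC", 1)])
    f3 = _freq([CloneRecord("ACD", 1)])
    with pytest.raises(ValueError, match="length"):
        es_matrix(f2, f3)


def test_es_matrix_matches_scalar_formula():
    f0 = _freq([CloneRecord("AA", 3), CloneRecord("CA", 1)])
    f1 = _freq([CloneRecord("AA", 1), CloneRecord("CA", 3)])
    es = es_matrix(f0, f1)
    for pos in (1, 2):
        for aa in "AC":
            assert es.values.loc[pos, aa] == pytest.approx(
                enrichment_score(f0.values.loc[pos, aa], f1.values.loc[pos, aa])
            )


def test_heatmap_export_roundtrip(tmp_path):
    f0 = _freq([CloneRecord("AC", 2), CloneRecord("CC", 2)])
    f1 = _freq([CloneRecord("AC", 1), CloneRecord("CC", 3)])
    es = es_matrix(f0, f1)
    csv_path, png_path = export_heatmap(es, tmp_path / "es")
    assert png_path.exists() and png_path.stat().st_size > 0
    back = read_es_csv(csv_path)
    pd.testing.assert_frame_equal(back.values, es.values)


def test_rank_clones_basics():
    df = rank_clones([RoundCounts(0, {"AAA": 3, "CCC": 1})])
    assert df.loc["AAA", "rank"] == 1
    assert df.loc["AAA", "round_0"] == pytest.approx(0.75)
    single = rank_clones([RoundCounts(0, {"AAA": 4})])
    assert single.loc["AAA", "round_0"] == 1.0 and single.loc["AAA", "rank"] == 1


def test_rank_clones_tie_broken_lexicographically():
    df = rank_clones([RoundCounts(0, {"CCC": 2, "AAA": 2})])
    assert list(df.index) == ["AAA", "CCC"]


def test_conserved_positions_tiny_matrices():
    cols = list("ACDE")
    vals = pd.DataFrame(0.0, index=pd.RangeIndex(1, 3, name="position"), columns=cols)
    assert conserved_positions(ESMatrix(vals.copy()), "AA", 0.8) == set()
    vals.loc[1, ["C", "D", "E"]] = -1.0
    assert conserved_positions(ESMatrix(vals), "AA", 0.8) == {1}


def test_logo_matrix_modes():
    records = [CloneRecord("AAA", 1), CloneRecord("AAC", 1)]
    freq_logo = logo_matrix(records, mode="frequency")
    assert freq_logo.values.loc[3, "A"] == pytest.approx(0.5)
    bits = logo_matrix([CloneRecord("WW", 7)], mode="information_bits")
    assert bits.values.loc[1, "W"] == pytest.approx(math.log2(20))
    # a uniform 20-residue column carries zero information
    uniform = [CloneRecord(a, 1) for a in "ACDEFGHIKLMNPQRSTVWY"]
    flat = logo_matrix(uniform, mode="information_bits")
    assert flat.values.loc[1].sum() == pytest.approx(0.0, abs=1e-12)


def test_render_logo_writes_image(tmp_path):
    logo = logo_matrix([CloneRecord("ACD", 2), CloneRecord("AWD", 1)])
    out = render_logo(logo, tmp_path / "logo.png")
    assert out.exists() and out.stat().st_size > 0


# ---------------------------------------------------------------------------
# end-to-end pipeline properties (small scale)
# ---------------------------------------------------------------------------

def _campaign_es(design, fitness, cfg, sorted_round=-1):
    camp = simulate_campaign(design, fitness, cfg)
    f0 = _freq(translate_and_filter(emit_reads(camp[0], design, 0.0, cfg.seed + 100), design, 0))
    f1 = _freq(translate_and_filter(emit_reads(camp[sorted_round], design, 0.0, cfg.seed + 200), design, cfg.rounds))
    return camp, es_matrix(f0, f1)


def test_engineered_preferences_recovered_by_argmax_es(loop5_design):
    # read the ES against round 2: per-position marginals are cleanest
    # before the recombination-free pool collapses onto whole clones
    prefs = {22: "W", 23: "R", 24: "D", 25: "F", 26: "K"}
    cfg = SelectionConfig(rounds=3, naive_size=20_000, depth=20_000, seed=21)
    _, es = _campaign_es(loop5_design, FitnessModel.from_preferences(prefs, 2.0), cfg, sorted_round=2)
    assert all(es.values.loc[i].idxmax() == aa for i, aa in prefs.items())


def test_hard_gated_positions_called_conserved(loop5_design, eeti):
    # conservation is read from an NNK-walking pool (single-position
    # variants of the parent), as jointly gating several positions in a
    # fully random pool leaves no survivors
    from dcphage import sample_nnk_walk_library

    gate_positions = [22, 24, 25, 26]
    walk = sample_nnk_walk_library(loop5_design, eeti.template, range(22, 27), 20_000, seed=22)
    cfg = SelectionConfig(rounds=3, naive_size=20_000, depth=20_000, seed=22)
    camp = simulate_campaign(
        loop5_design, FitnessModel.gated(eeti.template, gate_positions), cfg, initial=walk
    )
    f0 = _freq(translate_and_filter(emit_reads(camp[0], loop5_design, 0.0, 7), loop5_design, 0))
    f1 = _freq(translate_and_filter(emit_reads(camp[-1], loop5_design, 0.0, 8), loop5_design, 3))
    es = es_matrix(f0, f1)
    assert conserved_positions(es, eeti.template, 0.8) == set(gate_positions)


def test_favored_clone_rank_trajectory(loop5_design, eeti):
    fav = eeti.template[:21] + "YYYYY" + eeti.template[26:]
    cfg = SelectionConfig(rounds=4, naive_size=10_000, depth=20_000, seed=23)
    camp = simulate_campaign(
        loop5_design, FitnessModel.favored_clone(fav, 100.0), cfg, spike_in={fav: 10}
    )
    df = rank_clones(camp)
    fracs = [df.loc[fav, f"round_{i}"] for i in range(5)]
    assert all(b > a for a, b in zip(fracs, fracs[1:]))
    assert df.loc[fav, "rank"] == 1
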