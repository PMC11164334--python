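"""Consensus indices against hand-computed oracles and the fixture."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ethnosurvey import (UseReport, age_use_regression, category_summary,
                         ci, dense_rank, descriptive_frequencies,
                         format_table2, format_table3, frequency_of_citation,
                         icf, novelty_count, rfc, species_summary, truncate,
                         use_report_count)
from ethnosurvey.core_data import PresenceMatrix


# ---------------------------------------------------------------------------
# elementary index formulas


@pytest.mark.parametrize("nur,nt,expected", [
    (32, 12, 0.64),   # metabolic
    (9, 4, 0.62),     # musculoskeletal
    (9, 6, 0.37),     # liver
    (16, 10, 0.40),   # nervous
    (5, 5, 0.0),
])
def test_icf_formula_and_table_formatting(nur, nt, expected):
    value = icf(nur, nt)
    assert value.status == "ok"
    assert format_table2(value.value) == pytest.approx(expected)


def test_icf_undefined_and_suppressed_cases():
    assert icf(1, 1).status == "undefined"
    assert icf(0, 0).status == "undefined"
    assert icf(2, 2).status == "suppressed"    # the "-" cells
    assert icf(3, 4).status == "suppressed"    # Nt exceeds Nur
    with pytest.raises(ValueError):
        icf(-1, 0)


@pytest.mark.parametrize("fc,n,expected", [(21, 21, 1.0), (0, 21, 0.0)])
def test_rfc_limits(fc, n, expected):
    assert rfc(fc, n) == expected


def test_rfc_prints_with_truncation():
    assert format_table3(rfc(14, 21)) == 0.6666
    with pytest.raises(ValueError):
        rfc(22, 21)


@pytest.mark.parametrize("ur,n,expected", [
    (26, 21, 1.2380), (21, 21, 1.0), (0, 21, 0.0), (20, 21, 0.9523),
])
def test_ci_prints_with_truncation(ur, n, expected):
    assert format_table3(ci(ur, n)) == pytest.approx(expected)


@pytest.mark.parametrize("values,expected", [
    ([0.6666, 0.6666, 0.5714], [1, 1, 2]),
    ([5, 4, 3], [1, 2, 3]),
    ([7, 7, 7], [1, 1, 1]),
])
def test_dense_rank(values, expected):
    assert dense_rank(values) == expected


@given(st.lists(st.integers(0, 5), min_size=1, max_size=30))
def test_dense_rank_is_a_surjection_onto_prefix(values):
    ranks = dense_rank(values)
    assert set(ranks) == set(range(1, len(set(values)) + 1))


def test_truncation_matches_printed_digits():
    assert truncate(20 / 21, 4) == 0.9523
    assert truncate(26 / 21, 4) == 1.2380
    assert truncate(100 * 69 / 141, 2) == 48.93


# ---------------------------------------------------------------------------
# counting semantics


def test_fc_counts_distinct_informants():
    reports = [UseReport(f"I{i:02d}", 1, "dig") for i in range(14)]
    assert frequency_of_citation(reports, 1) == 14
    assert frequency_of_citation(reports, 2) == 0
    with pytest.raises(KeyError):
        frequency_of_citation(reports, 2, known_codes={1})


def test_one_informant_many_categories_is_one_fc_many_ur():
    reports = [UseReport("I01", 1, c) for c in ("dig", "met", "ner")]
    assert frequency_of_citation(reports, 1) == 1
    assert use_report_count(reports, 1) == 3


# ---------------------------------------------------------------------------
# dataset-level summaries vs a naive triple-loop oracle


def _oracle_counts(dataset):
    triples = {(r.informant_id, r.species_code, r.category_id)
               for r in dataset.use_reports}
    fc, ur, nur, nt = {}, {}, {}, {}
    for s in dataset.species:
        fc[s.code] = len({i for i, sc, _ in triples if sc == s.code})
        ur[s.code] = len({(i, u) for i, sc, u in triples if sc == s.code})
    for c in dataset.categories:
        nur[c.id] = len({t for t in triples if t[2] == c.id})
        nt[c.id] = len({sc for _, sc, u in triples if u == c.id})
    return fc, ur, nur, nt


@pytest.mark.parametrize("seed", range(5))
def test_pipeline_equals_triple_loop_oracle(seed):
    from ethnosurvey import SimConfig, simulate_survey

    dataset, _ = simulate_survey(SimConfig(n_informants=12, n_species=25,
                                           n_categories=5, seed=seed,
                                           citation_rate=0.15))
    assert len(dataset.use_reports) <= 200
    fc, ur, nur, nt = _oracle_counts(dataset)
    for ss in species_summary(dataset):
        assert ss.fc == fc[ss.species_code]
        assert ss.ur == ur[ss.species_code]
    for cs in category_summary(dataset):
        assert cs.nur == nur[cs.category_id]
        assert cs.nt == nt[cs.category_id]


def test_conservation_and_order_invariants(shahrbabak):
    dataset, _ = shahrbabak
    cats = category_summary(dataset)
    assert sum(c.nur for c in cats) == len(dataset.use_reports)
    assert sum(c.citation_share for c in cats) == pytest.approx(100.0)
    for ss in species_summary(dataset):
        assert ss.ur >= ss.fc
        assert ss.ci >= ss.rfc
        assert 0 <= ss.rfc <= 1


def test_fixture_category_table(shahrbabak):
    dataset, _ = shahrbabak
    cs = {c.category_id: c for c in category_summary(dataset)}
    assert sum(c.nur for c in cs.values()) == 222
    assert truncate(cs["met"].citation_share, 2) == 14.41
    assert (cs["dig"].nur, cs["dig"].nt) == (62, 38)
    # rows whose printed ICF disagrees with the formula stay as computed
    assert format_table2(cs["dig"].icf.value) == 0.39
    assert format_table2(cs["cold"].icf.value) == 0.39


def test_fixture_species_rankings(shahrbabak):
    dataset, _ = shahrbabak
    ss = {s.species_code: s for s in species_summary(dataset)}
    top_rfc = [c for c, s in ss.items() if s.rfc_rank == 1]
    assert sorted(top_rfc) == [112, 119]          # two species tie at 0.6666
    assert ss[25].ci_rank == 1                    # Artemisia aucheri
    assert format_table3(ss[119].rfc) == 0.6666


def test_single_category_share_is_total():
    from ethnosurvey import SimConfig, simulate_survey

    dataset, _ = simulate_survey(SimConfig(n_informants=8, n_species=10,
                                           n_categories=1, seed=3,
                                           citation_rate=0.3))
    cats = category_summary(dataset)
    assert len(cats) == 1 and cats[0].citation_share == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# descriptive frequencies


def test_fixture_descriptive_frequencies(shahrbabak):
    dataset, _ = shahrbabak
    freq = descriptive_frequencies(dataset)
    assert freq.family_counts["Apiaceae"] == 16
    assert freq.family_counts["Fabaceae"] == 17
    assert freq.family_counts["Asteraceae"] == 13
    assert len(freq.family_counts) == 43
    assert truncate(freq.lifeform_percentages["Th"], 2) == 48.93
    assert truncate(freq.lifeform_percentages["G"], 2) == 21.98
    for table in (freq.part_percentages, freq.preparation_percentages,
                  freq.lifeform_percentages):
        assert sum(table.values()) == pytest.approx(100.0)
    assert freq.denominators["species"] == 141


def test_single_species_lifeform_share():
    from ethnosurvey import SimConfig, simulate_survey

    dataset, _ = simulate_survey(SimConfig(n_informants=3, n_species=1,
                                           n_categories=2, seed=0,
                                           citation_rate=0.5))
    freq = descriptive_frequencies(dataset)
    assert list(freq.lifeform_percentages.values()) == [100.0]


# ---------------------------------------------------------------------------
# age-knowledge regression


def _dataset_with_counts(counts_by_score):
    from ethnosurvey.core_data import (AilmentCategory, Dataset, Informant,
                                       SpeciesRecord, UseReport)

    ages = {1: 30, 2: 45, 3: 55, 4: 65, 5: 75}
    informants, reports = [], []
    species = [SpeciesRecord(j, "f", "s", "v", ("leaf",), ("use",),
                             ("decoction",), "oral", "Th", "1")
               for j in range(1, 30)]
    for k, (score, count) in enumerate(counts_by_score):
        iid = f"I{k:02d}"
        informants.append(Informant(iid, ages[score]))
        reports.extend(UseReport(iid, j + 1, "c") for j in range(count))
    return Dataset(informants, species, reports, [AilmentCategory("c", "c")])


def test_regression_exact_line_has_unit_r_squared():
    d = _dataset_with_counts([(1, 2), (2, 4), (3, 6), (4, 8), (5, 10)])
    fit = age_use_regression(d)
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.slope == pytest.approx(2.0)


def test_regression_constant_response_has_zero_r_squared():
    d = _dataset_with_counts([(1, 5), (2, 5), (3, 5), (4, 5), (5, 5)])
    assert age_use_regression(d).r_squared == pytest.approx(0.0)


def test_regression_degenerate_design_errors():
    d = _dataset_with_counts([(3, 1), (3, 2), (3, 3)])
    with pytest.raises(ValueError, match="variance"):
        age_use_regression(d)


def test_regression_recovers_simulated_slope():
    from ethnosurvey import SimConfig, simulate_survey

    cfg = SimConfig(n_informants=120, n_species=80, n_categories=6, seed=11,
                    citation_rate=0.15, age_knowledge_slope=4.0)
    dataset, _ = simulate_survey(cfg)
    fit = age_use_regression(dataset)
    assert fit.slope > 0
    assert abs(fit.slope - cfg.age_knowledge_slope) <= 2 * fit.stderr


def test_fixture_age_knowledge_trend_is_positive(shahrbabak):
    dataset, _ = shahrbabak
    fit = age_use_regression(dataset)
    assert fit.slope > 0 and fit.p_value < 0.05


# ---------------------------------------------------------------------------
# novelty


def test_novelty_on_fixture_matrix(shahrbabak):
    _, matrix = shahrbabak
    count, codes = novelty_count(matrix)
    assert count == 57
    assert codes == sorted(c for c, flag in matrix.novel_flags.items() if flag)


@pytest.mark.parametrize("fill,expected", [(0, 10), (1, 0)])
def test_novelty_degenerate_matrices(fill, expected):
    m = PresenceMatrix(list(range(1, 11)), ["A", "B"],
                       [[fill, fill] for _ in range(10)])
    assert novelty_count(m)[0] == expected


# ---------------------------------------------------------------------------
# property: defined ICF stays in [0, 1]


@given(nur=st.integers(2, 500), nt=st.integers(1, 500))
@settings(max_examples=200)
def test_icf_bounded_when_defined(nur, nt):
    """Any category with citations uses at least one species, so Nt >= 1;
    within that domain a defined ICF always lies in [0, 1]."""
    value = icf(nur, min(nt, nur))
    if value.status == "ok":
        assert 0.0 <= value.value <= 1.0
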