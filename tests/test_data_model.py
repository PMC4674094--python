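import logging
import math

import numpy as np
import pytest

from ddref_lq.data_model import (
    AnimalRecord,
    FilterConfig,
    SchemaError,
    StratumKey,
    TreatmentGroup,
    ValidationError,
    apply_inclusion_filters,
    build_strata,
    read_animal_table,
    read_group_table,
    stratify_observations,
    subset_acute,
    subset_comparison,
    summarize_groups,
    write_animal_table,
    write_group_table,
)
from ddref_lq.validation import make_observation

from conftest import make_animal


# ---------------------------------------------------------------------------
# CSV I/O

def test_animal_table_round_trip(tmp_path):
    records = [
        make_animal("a1", lifespan=812.375, total_dose=0.5, dose_rate=0.1),
        make_animal("a2", group_id="g1", lifespan=640.0001, total_dose=1.5,
                    fractions=10, fraction_interval=1.0),
        make_animal("a3", group_id="g2", lifespan=901.25, event=False),
    ]
    path = tmp_path / "animals.csv"
    write_animal_table(records, path)
    assert read_animal_table(path) == records


def test_group_table_round_trip(tmp_path):
    groups = [
        make_observation(
            StratumKey("B6CF1", "F", "100"), f"g{i}", d, f, y=1.2e-3 + 1e-5 * i,
            variance=2.5e-12,
        ).group
        for i, (d, f) in enumerate([(0.0, 1), (0.75, 1), (1.5, 10)])
    ]
    path = tmp_path / "groups.csv"
    write_group_table(groups, path)
    assert read_group_table(path) == groups


def test_non_positive_lifespan_names_the_row(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        "animal_id,group_id,study_id,strain,sex,age_first_exposure,lifespan,"
        "total_dose,fractions\n"
        "a1,g1,s1,X,F,100,800,0,1\n"
        "a2,g1,s1,X,F,100,0,0,1\n"
    )
    with pytest.raises(ValidationError, match="row 3"):
        read_animal_table(path)


def test_missing_mandatory_column_names_it(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("animal_id,group_id,study_id,strain,sex,lifespan,total_dose\na,g,s,X,F,800,0\n")
    with pytest.raises(SchemaError, match="age_first_exposure"):
        read_animal_table(path)


def test_single_exposure_dialect_defaults_fractions(tmp_path, caplog):
    path = tmp_path / "dialect.csv"
    path.write_text(
        "animal_id,group_id,study_id,strain,sex,age_first_exposure,lifespan,"
        "total_dose,single_exposure\n"
        "a1,g1,s1,X,F,100,800,0.5,true\n"
    )
    with caplog.at_level(logging.WARNING):
        records = read_animal_table(path)
    assert records[0].fractions == 1
    assert any("single_exposure" in m for m in caplog.messages)


def test_column_aliases_accepted(tmp_path):
    path = tmp_path / "alias.csv"
    path.write_text(
        "animal_id,group,study,strain,gender,age,lifespan,dose,fractions\n"
        "a1,g1,s1,X,F,100,800,0.5,1\n"
    )
    rec = read_animal_table(path)[0]
    assert rec.sex == "F" and rec.total_dose == 0.5 and rec.group_id == "g1"


def test_invalid_record_fields_rejected():
    with pytest.raises(ValidationError):
        make_animal(lifespan=-1.0)
    with pytest.raises(ValidationError):
        make_animal(total_dose=-0.5)
    with pytest.raises(ValidationError):
        make_animal(fractions=0)


# ---------------------------------------------------------------------------
# Inclusion-filter cascade

def _cascade_fixture():
    """12 engineered groups; each rule removes a known set."""
    animals = []

    def add_group(gid, study, strain, dose, n=5, **kw):
        for i in range(n):
            animals.append(
                make_animal(
                    f"{gid}_{i}", group_id=gid, study_id=study, strain=strain,
                    total_dose=dose, **kw,
                )
            )

    # stratum A (strain X): 7 groups, 4 removed one per rule
    add_group("A0", "S1", "X", 0.0)
    add_group("A1", "S1", "X", 0.5)
    add_group("A2", "S1", "X", 1.0)
    add_group("A3", "S1", "X", 1.6)  # over the dose cutoff
    add_group("A4", "S1", "X", 0.5, exposure_mode="internal")
    add_group("A5", "S1", "X", 0.5, let_class="high", radiation_quality="neutron")
    add_group("A6", "S1", "X", 0.5, other_treatment=True)
    # stratum B: only 2 groups -> dropped by the >=3 rule
    add_group("B0", "S2", "Y", 0.0)
    add_group("B1", "S2", "Y", 1.0)
    # stratum C: 3 clean groups
    add_group("C0", "S3", "Z", 0.0)
    add_group("C1", "S3", "Z", 0.5)
    add_group("C2", "S3", "Z", 1.0)
    return animals


def test_cascade_hand_counted_tally():
    animals = _cascade_fixture()
    kept, report = apply_inclusion_filters(animals)
    tally = [(s.groups, s.animals) for s in report]
    assert tally == [
        (12, 60),  # individual data available
        (11, 55),  # external exposures (drops A4)
        (10, 50),  # low-LET whole-body (drops A5)
        (9, 45),   # dose <= 1.5 Gy (drops A3)
        (8, 40),   # no other treatments (drops A6)
        (6, 30),   # >= 3 groups per stratum (drops B0, B1)
    ]
    assert {r.group_id for r in kept} == {"A0", "A1", "A2", "C0", "C1", "C2"}


def test_overdose_group_removed_at_dose_step():
    animals = _cascade_fixture()
    _, report = apply_inclusion_filters(animals)
    before, after = report[2], report[3]
    assert before.groups - after.groups == 1  # exactly A3


def test_cascade_is_monotone(paper_shaped):
    animals, _ = paper_shaped
    _, report = apply_inclusion_filters(animals)
    for prev, cur in zip(report, report[1:]):
        assert cur.studies <= prev.studies
        assert cur.groups <= prev.groups
        assert cur.animals <= prev.animals


def test_compliant_fixture_passes_unchanged(paper_shaped):
    animals, _ = paper_shaped
    kept, report = apply_inclusion_filters(animals)
    assert len(kept) == len(animals)
    assert report[0].animals == report[-1].animals


# ---------------------------------------------------------------------------
# Group summaries

def test_summary_arithmetic_two_animals():
    animals = [
        make_animal("a1", lifespan=400.0),
        make_animal("a2", lifespan=600.0),
    ]
    (obs,) = summarize_groups(animals)
    assert obs.group.mean_lifespan == 500.0
    assert obs.group.sem_lifespan == pytest.approx(100.0)
    assert obs.y == pytest.approx(0.002)
    assert obs.variance == pytest.approx(100.0**2 / 500.0**4)  # 1.6e-7
    assert obs.weight == pytest.approx(1.0 / obs.variance)


def test_degenerate_groups_excluded(caplog):
    animals = [
        make_animal("a1", group_id="solo", lifespan=700.0),
        make_animal("a2", group_id="tied", lifespan=500.0),
        make_animal("a3", group_id="tied", lifespan=500.0),
        make_animal("a4", group_id="ok", lifespan=400.0),
        make_animal("a5", group_id="ok", lifespan=600.0),
    ]
    with caplog.at_level(logging.WARNING):
        obs = summarize_groups(animals)
    assert [o.group.group_id for o in obs] == ["ok"]


def test_summaries_match_independent_recomputation(paper_shaped):
    import pandas as pd

    animals, observations = paper_shaped
    df = pd.DataFrame(
        {"group": [a.group_id for a in animals], "t": [a.lifespan for a in animals]}
    )
    expected = df.groupby("group")["t"].agg(["mean", "sem", "count"])
    for obs in observations[:20]:
        row = expected.loc[obs.group.group_id]
        assert obs.group.mean_lifespan == pytest.approx(row["mean"])
        assert obs.group.sem_lifespan == pytest.approx(row["sem"])
        assert obs.y * obs.group.mean_lifespan == pytest.approx(1.0, abs=1e-15)


# ---------------------------------------------------------------------------
# Stratification and subsets

def _group(gid, strain, sex, dose, fractions=1, study="S1"):
    return make_observation(
        StratumKey(strain, sex, "100"), gid, dose, fractions,
        y=1.2e-3, variance=1e-9, study_id=study,
    ).group


def test_build_strata_cartesian():
    groups = [
        _group(f"g{i}", strain, sex, 0.5)
        for i, (strain, sex) in enumerate(
            [("X", "F"), ("X", "M"), ("Y", "F"), ("Y", "M")]
        )
    ]
    strata = build_strata(groups)
    assert len(strata) == 4


def test_build_strata_empty():
    assert build_strata([]) == {}


def test_by_study_drops_foreign_controls():
    groups = [
        _group("ctrl", "X", "F", 0.0, study="S_other"),
        _group("d1", "X", "F", 0.5, study="S1"),
        _group("d2", "X", "F", 1.0, study="S1"),
        _group("d3", "X", "F", 1.5, study="S1"),
    ]
    pooled = build_strata(groups, by_study=False)
    assert len(pooled) == 1 and len(next(iter(pooled.values()))) == 4
    split = build_strata(groups, by_study=True)
    # the control came from a different study: its singleton stratum is dropped
    assert len(split) == 1
    kept = {g.group_id for g in next(iter(split.values()))}
    assert kept == {"d1", "d2", "d3"}


def _strata_obs(spec):
    """spec: {stratum_name: [(dose, fractions), ...]}"""
    strata = {}
    for name, rows in spec.items():
        key = StratumKey(name, "F", "100")
        strata[key] = [
            make_observation(key, f"{name}{j}", d, f, y=1.2e-3, variance=1e-9)
            for j, (d, f) in enumerate(rows)
        ]
    return strata


def test_subset_acute_keeps_single_fraction_groups():
    strata = _strata_obs({"A": [(0.0, 1), (0.5, 1), (1.0, 1), (1.0, 10)]})
    out = subset_acute(strata)
    (kept,) = out.values()
    assert all(o.group.fractions == 1 for o in kept)
    assert len(kept) == 3


def test_subset_acute_drops_underfilled_strata():
    strata = _strata_obs({"A": [(0.0, 1), (0.5, 10), (1.0, 20), (1.5, 30)]})
    assert subset_acute(strata) == {}


def test_subset_acute_identity_on_all_acute():
    strata = _strata_obs({"A": [(0.0, 1), (0.5, 1), (1.0, 1)]})
    assert subset_acute(strata) == strata


def test_subset_comparison_requires_both_exposure_types():
    strata = _strata_obs(
        {
            "both": [(0.0, 1), (0.5, 1), (1.0, 10)],
            "acute_only": [(0.0, 1), (0.5, 1), (1.0, 1)],
            "protracted_only": [(0.0, 1), (0.5, 10), (1.0, 20)],
        }
    )
    out = subset_comparison(strata)
    assert [k.strain for k in out] == ["both"]
    # qualifying strata keep all groups, controls included
    assert len(next(iter(out.values()))) == 3


def test_subsets_idempotent(paper_shaped):
    _, observations = paper_shaped
    strata = stratify_observations(observations)
    acute = subset_acute(strata)
    comp = subset_comparison(strata)
    assert subset_acute(acute) == acute
    assert subset_comparison(comp) == comp


def test_paper_shaped_fixture_structure(paper_shaped):
    _, observations = paper_shaped
    strata = stratify_observations(observations)
    assert len(strata) == 16
    assert len(subset_comparison(strata)) == 4
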