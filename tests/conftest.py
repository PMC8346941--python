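"""Shared fixtures: small hand-built cohorts and record factories."""

from __future__ import annotations

import pytest

from hbref.records import IndividualRecord


def make_child(**kw) -> IndividualRecord:
    """A healthy-by-default child record; override any field."""
    base = dict(
        survey_id="S01", group="child", age=30.0, sex="male", hb=11.5,
        ferritin=30.0, vita=30.0, crp=0.2, agp=0.5, malaria="negative",
    )
    base.update(kw)
    return IndividualRecord(**base)


def make_woman(**kw) -> IndividualRecord:
    """A healthy-by-default woman record; override any field."""
    base = dict(
        survey_id="S01", group="woman", age=30.0, sex="female", hb=13.0,
        ferritin=40.0, vita=30.0, crp=0.2, agp=0.5, malaria="negative",
    )
    base.update(kw)
    return IndividualRecord(**base)


@pytest.fixture
def child_factory():
    return make_child


@pytest.fixture
def woman_factory():
    return make_woman


@pytest.fixture
def twelve_record_panel():
    """Hand-set panel whose healthy subset was enumerated by hand.

    Rule-by-rule walk-through (child thresholds: ferritin >= 12,
    vita >= 20.1, crp <= 0.5, agp <= 1, no malaria):

    idx  ferritin  vita   crp   agp   malaria     healthy?  why
    0    30        30     0.2   0.5   negative    yes
    1    12.0      30     0.2   0.5   negative    yes       ferritin boundary inclusive
    2    11.9      30     0.2   0.5   negative    no        iron deficient
    3    30        20.1   0.2   0.5   negative    yes       vita boundary inclusive
    4    30        20.0   0.2   0.5   negative    no        vitamin A deficient
    5    30        None   0.2   0.5   negative    yes       vita unmeasured never excludes
    6    30        30     0.5   0.5   negative    yes       crp boundary inclusive
    7    30        30     0.51  0.5   negative    no        inflamed (CRP)
    8    30        30     0.2   1.01  negative    no        inflamed (AGP)
    9    30        30     0.2   None  negative    yes       AGP unmeasured, CRP passes
    10   30        30     0.2   0.5   positive    no        malaria
    11   30        30     0.2   0.5   unmeasured  yes       malaria unmeasured never excludes
    """
    rows = [
        dict(ferritin=30.0),
        dict(ferritin=12.0),
        dict(ferritin=11.9),
        dict(vita=20.1),
        dict(vita=20.0),
        dict(vita=None),
        dict(crp=0.5),
        dict(crp=0.51),
        dict(agp=1.01),
        dict(agp=None),
        dict(malaria="positive"),
        dict(malaria="unmeasured"),
    ]
    records = [make_child(hb=10.0 + 0.1 * i, **row) for i, row in enumerate(rows)]
    healthy_idx = [0, 1, 3, 5, 6, 9, 11]
    return records, healthy_idx
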