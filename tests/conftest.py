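import logging

import numpy as np
import pytest

from dyadnet.data_model import FocalRecord, Individual
from dyadnet.synthetic import GeneratorConfig, GroupSpec, generate_focal_stream, generate_roster

logging.getLogger("dyadnet").setLevel(logging.ERROR)


def make_individual(iid, sex="F", age=10.0, group="g1", line=None, mother=None):
    return Individual(
        id=iid, sex=sex, age_years=age, group_id=group,
        maternal_line=line or iid, mother_id=mother,
    )


@pytest.fixture(scope="session")
def small_roster():
    """Four individuals in one group: two maternal sisters and two outsiders."""
    return [
        make_individual("amy", "F", 12.0, line="A", mother="mum"),
        make_individual("ben", "M", 8.0, line="B"),
        make_individual("cal", "M", 20.0, line="C"),
        make_individual("dot", "F", 15.0, line="A", mother="mum"),
    ]


@pytest.fixture(scope="session")
def two_group_data():
    """A small two-group synthetic dataset shared by the slower model tests."""
    cfg = GeneratorConfig(
        seed=101,
        groups=(GroupSpec("g1", 5, 5, 7), GroupSpec("g2", 5, 5, 7)),
        n_days=25,
        target_focals_per_individual=20,
        p_close_given_party=0.25,
    )
    roster = generate_roster(cfg)
    records = generate_focal_stream(roster, cfg)
    return cfg, roster, records


def random_records(rng, roster, n_days, p=0.3):
    """Arbitrary (not model-based) focal records for property tests."""
    from datetime import date, timedelta

    ids = [ind.id for ind in roster]
    by_group = {}
    for ind in roster:
        by_group.setdefault(ind.group_id, []).append(ind.id)
    records = []
    for d in range(n_days):
        day = date(2013, 7, 1) + timedelta(days=d)
        for iid in ids:
            if rng.random() < 0.7:  # focal sampled today
                group_ids = [x for x in by_group[next(i.group_id for i in roster if i.id == iid)] if x != iid]
                w10 = {x for x in group_ids if rng.random() < p}
                w1 = {x for x in w10 if rng.random() < 0.5}
                grm = {x for x in w1 if rng.random() < 0.5}
                records.append(
                    FocalRecord(date=day, focal_id=iid, within10m=frozenset(w10),
                                within1m=frozenset(w1), grooming=frozenset(grm))
                )
    return records
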