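"""Synthetic rosters and focal-record streams with known dyadic structure.

The generator emulates the observation process of a two-group focal-sampling
study: each day a randomized subset of individuals is sampled, and for every
focal sample each possible same-group partner joins the 10 m party with
probability

    inv_logit(beta0 + beta_sextype[group, sex_type] + beta_kin * kin
              + beta_age * |age_a - age_b| + u_i + u_j),

where ``u ~ Normal(0, sigma_indiv^2)`` are per-individual gregariousness
intercepts held fixed over the season. Partners in the party enter the 1 m
circle independently with ``p_close_given_party`` and grooming is drawn only
from the 1 m circle with ``p_groom_given_close``, so the three observation
streams are nested exactly as the downstream analysis assumes. Ground-truth
probabilities are exposed so tests can compare realized frequencies against
the generating model.
"""
from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from datetime import date as Date
from datetime import timedelta
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .data_model import (
    Dyad,
    FocalRecord,
    Individual,
    dyad_sex_type,
    make_dyad,
)

__all__ = [
    "GroupSpec",
    "GeneratorConfig",
    "generate_roster",
    "generate_focal_stream",
    "gregariousness",
    "true_dyad_probability",
    "group1_like_config",
    "two_group_config",
]


@dataclass(frozen=True)
class GroupSpec:
    group_id: str
    n_males: int
    n_females: int
    n_maternal_lines: int

    @property
    def size(self) -> int:
        return self.n_males + self.n_females


def _default_groups() -> tuple:
    # Two-group demographics mirroring the study site: a 22-member group with
    # an even sex ratio and a 39-member, female-biased group. Maternal-line
    # counts chosen so the kin-dyad fractions come out near 17/231 and 35/741.
    return (
        GroupSpec("g1", n_males=11, n_females=11, n_maternal_lines=9),
        GroupSpec("g2", n_males=10, n_females=29, n_maternal_lines=14),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic observation process.

    Defaults emulate the season the analysis targets: ~60 observation days
    with each individual focal-sampled on enough days to accumulate about
    20 five-minute focals, baseline party-association odds of
    ``inv_logit(-1.7) ~ 0.15`` per focal sample (dyadic party indices around
    0.1-0.15 per season), a positive maternal-kinship effect, a weak negative
    age-distance effect, and moderate between-individual gregariousness
    spread. The close-proximity and grooming conditionals are set so that
    more than half of the direct-association indices and about three
    quarters of the grooming indices are zero over a season, the sparse
    regime that motivates the hurdle models.
    """

    groups: tuple = field(default_factory=_default_groups)
    n_days: int = 60
    focals_per_individual_per_day: int = 1
    target_focals_per_individual: Optional[float] = 20.0
    beta0: float = -1.7
    beta_sextype_by_group: Dict[Tuple[str, str], float] = field(default_factory=dict)
    beta_kin: float = 1.0
    beta_age: float = -0.01
    sigma_indiv: float = 0.4
    p_close_given_party: float = 0.08
    p_groom_given_close: float = 0.5
    age_range: Tuple[float, float] = (4.0, 40.0)
    start_date: Date = Date(2013, 7, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        for p in (self.p_close_given_party, self.p_groom_given_close):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.sigma_indiv < 0:
            raise ValueError("sigma_indiv must be non-negative")
        if self.focals_per_individual_per_day < 0:
            raise ValueError("focals_per_individual_per_day must be non-negative")
        for g in self.groups:
            if g.size < 2:
                raise ValueError(f"group {g.group_id} must have at least 2 members")
            if g.n_maternal_lines > g.size:
                raise ValueError(
                    f"group {g.group_id}: n_maternal_lines ({g.n_maternal_lines}) exceeds group size ({g.size})"
                )
            if g.n_maternal_lines < 1:
                raise ValueError(f"group {g.group_id}: need at least one maternal line")

    def sextype_effect(self, group_id: str, sex_type: str) -> float:
        return self.beta_sextype_by_group.get((group_id, sex_type), 0.0)


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, stream]))


def inv_logit(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def generate_roster(config: GeneratorConfig) -> list:
    """Deterministic (given seed) roster over the configured groups.

    Ages are uniform over ``age_range``; maternal lines are assigned by
    cycling individuals through the configured number of lines, the oldest
    member of each line being declared the mother of the rest (so every
    same-line pair is kin: mother-offspring or maternal siblings).
    """
    rng = _rng(config, 0)
    roster: list = []
    for g in config.groups:
        n = g.size
        sexes = ["M"] * g.n_males + ["F"] * g.n_females
        ages = rng.uniform(config.age_range[0], config.age_range[1], size=n)
        rng.shuffle(sexes)
        line_labels = [f"{g.group_id}{string.ascii_uppercase[i % 26]}{i // 26}" for i in range(g.n_maternal_lines)]
        line_of = [line_labels[i % g.n_maternal_lines] for i in range(n)]
        ids = [f"{g.group_id}_{i:02d}" for i in range(n)]
        # oldest per line is the matriarch (mother of the other members)
        by_line: dict = {}
        for i in range(n):
            by_line.setdefault(line_of[i], []).append(i)
        mother_of: dict = {}
        for members in by_line.values():
            members.sort(key=lambda i: -ages[i])
            matriarch = members[0]
            for i in members[1:]:
                mother_of[i] = ids[matriarch]
        for i in range(n):
            roster.append(
                Individual(
                    id=ids[i],
                    sex=sexes[i],
                    age_years=float(ages[i]),
                    group_id=g.group_id,
                    maternal_line=line_of[i],
                    mother_id=mother_of.get(i),
                )
            )
    return roster


def gregariousness(roster: Sequence[Individual], config: GeneratorConfig) -> dict:
    """The per-individual random intercepts the stream generator uses.

    Deterministic given the config seed and the sorted id set, so tests can
    condition on the realized ``u`` when checking Monte-Carlo frequencies.
    """
    rng = _rng(config, 1)
    ids = sorted(ind.id for ind in roster)
    u = rng.normal(0.0, config.sigma_indiv, size=len(ids)) if config.sigma_indiv > 0 else np.zeros(len(ids))
    return dict(zip(ids, u.tolist()))


def true_dyad_probability(dyad: Dyad, u_a: float, u_b: float, config: GeneratorConfig) -> float:
    """Per-focal-sample probability that the dyad shares the 10 m party."""
    eta = (
        config.beta0
        + config.sextype_effect(dyad.group_id, dyad.sex_type)
        + config.beta_kin * (1.0 if dyad.kin else 0.0)
        + config.beta_age * dyad.age_diff
        + u_a
        + u_b
    )
    return inv_logit(eta)


def generate_focal_stream(roster: Sequence[Individual], config: GeneratorConfig) -> list:
    """Simulate the focal-sampling season for *roster* under *config*.

    Each day, every individual is scheduled as focal with the probability
    needed to hit ``target_focals_per_individual`` in expectation (or on
    every day if the target is None); the focal order within a day is
    randomized. Output is deterministic given the config seed.
    """
    rng = _rng(config, 2)
    u = gregariousness(roster, config)
    active = sorted(ind for ind in roster if not ind.excluded)
    by_group: dict = {}
    for ind in active:
        by_group.setdefault(ind.group_id, []).append(ind)

    per_day = config.focals_per_individual_per_day
    if config.target_focals_per_individual is None or per_day == 0:
        p_focal = 1.0
    else:
        p_focal = min(1.0, config.target_focals_per_individual / (config.n_days * max(per_day, 1)))

    # pre-compute dyadic party probabilities
    prob: dict = {}
    for members in by_group.values():
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                d = make_dyad(a, b)
                prob[(d.member_a, d.member_b)] = true_dyad_probability(d, u[d.member_a], u[d.member_b], config)

    records: list = []
    for day_idx in range(config.n_days):
        day = config.start_date + timedelta(days=day_idx)
        focals: list = []
        for ind in active:
            if rng.random() < p_focal:
                focals.extend([ind] * per_day)
        order = rng.permutation(len(focals))
        for k in order:
            focal = focals[k]
            partners = [m for m in by_group[focal.group_id] if m.id != focal.id]
            w10 = set()
            w1 = set()
            grm = set()
            for m in partners:
                key = (focal.id, m.id) if focal.id < m.id else (m.id, focal.id)
                if rng.random() < prob[key]:
                    w10.add(m.id)
                    if rng.random() < config.p_close_given_party:
                        w1.add(m.id)
                        if rng.random() < config.p_groom_given_close:
                            grm.add(m.id)
            records.append(
                FocalRecord(
                    date=day,
                    focal_id=focal.id,
                    within10m=frozenset(w10),
                    within1m=frozenset(w1),
                    grooming=frozenset(grm),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Convenience configurations


def group1_like_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """A single 11 M + 11 F group under the default observation process."""
    kwargs = dict(groups=(GroupSpec("g1", 11, 11, 9),), seed=seed)
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


def two_group_config(
    n_males: int,
    n_females: int,
    seed: int = 0,
    ff_group_effect: float = 0.0,
    **overrides,
) -> GeneratorConfig:
    """Two equally sized groups, optionally with an FF-only effect in group 1.

    ``ff_group_effect`` is added to the log-odds of party association for
    female-female dyads of group ``g1`` only — the group-by-dyad-sex
    interaction the permutation test targets.
    """
    n_lines = max(1, (n_males + n_females) * 2 // 5)
    groups = (
        GroupSpec("g1", n_males, n_females, n_lines),
        GroupSpec("g2", n_males, n_females, n_lines),
    )
    effects = {("g1", "FF"): ff_group_effect} if ff_group_effect else {}
    kwargs = dict(groups=groups, seed=seed, beta_sextype_by_group=effects)
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)
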