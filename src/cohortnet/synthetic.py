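"""Synthetic weekly cohort generator.

Emulates the statistical structure of an early-forming student interaction
network: a cohort of ~140-170 students split over seven recitation/lab
sections, weekly "who did you talk with about problem solving" digraphs in
which roughly half of each week's links are new relative to the preceding
week, a growing fraction of re-established links as students return to
partners they liked, declining survey participation over the course, strong
section homophily with weaker gender homophily, and an end-of-course grade
attribute that is independent of who works with whom.

The generator is the test bed for every downstream stage; its defaults are
the cohort conditions the analysis assumes, not tuning knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import AttributeTable, WeeklyNetwork, simplify

import pandas as pd

__all__ = ["CohortConfig", "generate_attributes", "generate_weekly_networks", "generate_cohort"]

#: Danish 7-step scale; -3 and 00 are fail grades.
DEFAULT_GRADE_VOCABULARY = ("-3", "00", "02", "4", "7", "10", "12")
DEFAULT_GRADE_WEIGHTS = (0.03, 0.07, 0.15, 0.20, 0.30, 0.15, 0.10)


def _default_participation(n_weeks: int) -> tuple:
    # Participation (fraction of students naming anyone) declines roughly
    # linearly from ~78% to ~48% over a 7-week course.
    return tuple(np.round(np.linspace(0.78, 0.48, n_weeks), 4))


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    persistence is the probability that an emitted link re-uses one of the
    student's previously used out-links; homophily weights are multiplicative
    preferences (>=1) for same-category partners when drawing a new partner.
    """

    n_students: int = 160
    n_sections: int = 7
    gender_split: float = 0.3  # probability of category "F"
    grade_vocabulary: tuple = DEFAULT_GRADE_VOCABULARY
    grade_weights: tuple = DEFAULT_GRADE_WEIGHTS
    n_weeks: int = 7
    mean_out_degree: float = 5.0
    persistence: float = 0.85
    homophily_section: float = 8.0
    homophily_gender: float = 2.0
    participation: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.participation is None:
            object.__setattr__(self, "participation", _default_participation(self.n_weeks))
        object.__setattr__(self, "participation", tuple(float(p) for p in self.participation))
        object.__setattr__(self, "grade_weights", tuple(float(w) for w in self.grade_weights))
        object.__setattr__(self, "grade_vocabulary", tuple(str(g) for g in self.grade_vocabulary))
        if self.n_students < 2:
            raise ValueError("n_students must be >= 2")
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")
        if not 0.0 <= self.gender_split <= 1.0:
            raise ValueError("gender_split must be a probability")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must be a probability")
        if self.homophily_section < 1.0 or self.homophily_gender < 1.0:
            raise ValueError("homophily weights must be >= 1")
        if len(self.grade_weights) != len(self.grade_vocabulary):
            raise ValueError("grade_weights and grade_vocabulary lengths differ")
        if len(self.participation) != self.n_weeks:
            raise ValueError("participation must have one probability per week")
        if any(not 0.0 <= p <= 1.0 for p in self.participation):
            raise ValueError("participation entries must be probabilities")
        if self.mean_out_degree < 0:
            raise ValueError("mean_out_degree must be >= 0")

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=int(seed))


def _ids(n: int) -> list:
    width = len(str(n))
    return [f"S{i:0{width}d}" for i in range(1, n + 1)]


def generate_attributes(cfg: CohortConfig) -> AttributeTable:
    """Draw the cohort's attribute table.

    Sections are balanced within +/-1 (students are pre-assigned to sections
    administratively, so assignment is a random permutation round-robin);
    gender is i.i.d. Bernoulli(gender_split); grade is i.i.d. from the grade
    weights, independent of section and gender by construction.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    ids = _ids(cfg.n_students)
    order = rng.permutation(cfg.n_students)
    section = np.empty(cfg.n_students, dtype=int)
    section[order] = np.arange(cfg.n_students) % cfg.n_sections + 1
    gender = np.where(rng.random(cfg.n_students) < cfg.gender_split, "F", "M")
    weights = np.asarray(cfg.grade_weights, dtype=float)
    grade_idx = rng.choice(len(weights), size=cfg.n_students, p=weights / weights.sum())
    grade = np.asarray(cfg.grade_vocabulary, dtype=object)[grade_idx]
    df = pd.DataFrame(
        {"gender": gender, "section": section.astype(str), "grade": grade}, index=pd.Index(ids, name="id")
    )
    vocab = {
        "gender": ("F", "M"),
        "section": tuple(str(s) for s in range(1, cfg.n_sections + 1)),
        "grade": tuple(cfg.grade_vocabulary),
    }
    return AttributeTable(data=df, vocabularies=vocab)


def _partner_probs(cfg: CohortConfig, attrs: AttributeTable, ids: Sequence) -> np.ndarray:
    """Row-stochastic matrix of new-partner choice probabilities."""
    sec = attrs.data.loc[ids, "section"].to_numpy()
    gen = attrs.data.loc[ids, "gender"].to_numpy()
    w = np.where(sec[:, None] == sec[None, :], cfg.homophily_section, 1.0)
    w = w * np.where(gen[:, None] == gen[None, :], cfg.homophily_gender, 1.0)
    np.fill_diagonal(w, 0.0)
    return w / w.sum(axis=1, keepdims=True)


def generate_weekly_networks(cfg: CohortConfig, attrs: AttributeTable) -> list:
    """Simulate the weekly naming networks.

    Each week every student is independently active with that week's
    participation probability.  An active student emits Poisson(mean
    out-degree) namings; each naming re-uses a uniformly chosen previous
    out-partner with probability ``persistence`` (when any exist) and
    otherwise draws a new partner with probability proportional to the
    homophily weights.  Weeks are simplified (no self-loops or duplicate
    pairs) and labelled 1..n_weeks.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    ids = list(attrs.data.index)
    n = len(ids)
    probs = _partner_probs(cfg, attrs, ids)
    history = [set() for _ in range(n)]
    networks = []
    for t in range(cfg.n_weeks):
        active = rng.random(n) < cfg.participation[t]
        edges = []
        week_partners = [set() for _ in range(n)]
        for i in np.flatnonzero(active):
            k = rng.poisson(cfg.mean_out_degree)
            if k == 0:
                continue
            past = sorted(history[i])
            use_past = rng.random(k) < cfg.persistence if past else np.zeros(k, dtype=bool)
            n_new = int(k - use_past.sum())
            new_partners = rng.choice(n, size=n_new, p=probs[i]) if n_new else []
            for j in new_partners:
                week_partners[i].add(int(j))
            if past:
                for j in rng.choice(len(past), size=int(use_past.sum())):
                    week_partners[i].add(past[int(j)])
            edges.extend((ids[i], ids[j]) for j in sorted(week_partners[i]))
        networks.append(simplify(WeeklyNetwork.from_edges(t + 1, edges)))
        for i in range(n):
            history[i] |= week_partners[i]
    return networks


def generate_cohort(cfg: CohortConfig):
    """Convenience wrapper: attribute table plus the weekly network sequence."""
    attrs = generate_attributes(cfg)
    return attrs, generate_weekly_networks(cfg, attrs)
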