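"""Synthetic survey generator with known ground truth.

Emulates the citation structure of a small ethnobotanical field survey:
N informants, S species, U ailment categories; each informant cites each
species with a per-informant probability (older informants cite more when the
age-knowledge slope is positive), and every citation lands in one or more
categories.  A tunable coupling rho ties a species' preparation (liniment vs
other) to its mode-of-application class, which gives the mode-prediction task
a known Bayes accuracy of max(rho, 1 - rho).

Ground-truth counters (FC, UR, Nur, Nt) are recorded from the realized draws
during generation, independently of the event-level pipeline, so the two
aggregation paths can be compared exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_data import (AilmentCategory, Dataset, Informant, SpeciesRecord,
                        UseReport, age_to_score)
from .indices import (CategoryStats, SpeciesStats, ci, dense_rank, icf, rfc)

_PARTS = ["leaf", "seed", "fruit", "flower", "aerial parts", "root", "stem"]
_PREPS_ORAL = ["decoction", "infusion", "powder", "freshly cooked"]
_LIFE_FORMS = ["Th", "G", "H", "P", "C"]


@dataclass
class SimConfig:
    """Study conditions for one simulated survey.

    Defaults mirror the field study the package models: 21 informants aged
    28-81, 141 species, 14 ailment categories, and a citation rate chosen so
    the expected number of use reports is a few hundred.
    """

    n_informants: int = 21
    n_species: int = 141
    n_categories: int = 14
    seed: int = 0
    citation_rate: float | Sequence[float] = 0.055   # per (informant, species)
    extra_categories_mean: float = 0.35   # Poisson mean beyond the first category
    preparation_mode_coupling: float = 0.9  # P(liniment -> topical), P(other -> oral)
    liniment_rate: float = 0.14           # share of species prepared as liniment
    age_low: int = 28
    age_high: int = 81
    age_knowledge_slope: float = 0.0      # expected extra use reports per score unit

    def validate(self) -> None:
        if min(self.n_informants, self.n_species, self.n_categories) < 1:
            raise ValueError("counts must be >= 1")
        rates = np.atleast_1d(np.asarray(self.citation_rate, dtype=float))
        if rates.size not in (1, self.n_species):
            raise ValueError("citation_rate must be scalar or one per species")
        if np.any((rates < 0) | (rates > 1)):
            raise ValueError("citation_rate outside [0, 1]")
        if not 0 <= self.preparation_mode_coupling <= 1:
            raise ValueError("coupling rho outside [0, 1]")
        if not 0 <= self.liniment_rate <= 1:
            raise ValueError("liniment_rate outside [0, 1]")
        if not 18 <= self.age_low <= self.age_high <= 120:
            raise ValueError("invalid age range")


@dataclass
class SyntheticTruth:
    fc: dict[int, int]
    ur: dict[int, int]
    nur: dict[str, int]
    nt: dict[str, int]
    class_labels: dict[int, str]          # species code -> mode
    bayes_accuracy: float
    category_map: dict[str, str] = field(default_factory=dict)


def simulate_survey(config: SimConfig) -> tuple[Dataset, SyntheticTruth]:
    """Draw one survey; identical seeds give identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    informants = []
    for i in range(config.n_informants):
        informants.append(Informant(
            id=f"S{i + 1:03d}",
            age=int(rng.integers(config.age_low, config.age_high + 1)),
            gender="female" if i % 2 == 0 else "male"))

    cat_ids = [f"c{j + 1:02d}" for j in range(config.n_categories)]
    categories = [AilmentCategory(cid, f"synthetic category {cid}")
                  for cid in cat_ids]
    category_map = {f"use {cid}": cid for cid in cat_ids}

    rho = config.preparation_mode_coupling
    species = []
    labels: dict[int, str] = {}
    primary_cat: dict[int, str] = {}
    n_families = max(3, config.n_species // 3)
    for code in range(1, config.n_species + 1):
        liniment = rng.random() < config.liniment_rate
        prep = "liniment" if liniment else str(rng.choice(_PREPS_ORAL))
        if liniment:
            mode = "topical" if rng.random() < rho else "oral"
        else:
            mode = "oral" if rng.random() < rho else "topical"
        labels[code] = mode
        cid = cat_ids[int(rng.integers(config.n_categories))]
        primary_cat[code] = cid
        species.append(SpeciesRecord(
            code=code,
            family=f"family{int(rng.integers(n_families)) + 1:02d}",
            scientific_name=f"Species simulatum {code}",
            vernacular_name=f"plant-{code}",
            parts_used=(str(rng.choice(_PARTS)),),
            medicinal_uses=(f"use {cid}",),
            preparation=(prep,),
            mode_of_application=mode,
            life_form=str(rng.choice(_LIFE_FORMS)),
            voucher_no=str(1000 + code)))

    rates = np.broadcast_to(np.atleast_1d(
        np.asarray(config.citation_rate, dtype=float)), (config.n_species,))
    # each citation spawns 1 + Poisson(extra) use reports, so the citation-
    # probability shift is scaled down to keep the slope in report units
    reports_per_citation = 1.0 + config.extra_categories_mean
    slope_per_species = (config.age_knowledge_slope
                         / (config.n_species * reports_per_citation))

    fc = {code: 0 for code in labels}
    ur = {code: 0 for code in labels}
    nur = {cid: 0 for cid in cat_ids}
    nt_sets: dict[str, set[int]] = {cid: set() for cid in cat_ids}
    reports: list[UseReport] = []

    for inf in informants:
        shift = slope_per_species * (age_to_score(inf.age) - 3)
        for s_idx, code in enumerate(sorted(labels)):
            p = float(np.clip(rates[s_idx] + shift, 0.0, 1.0))
            if rng.random() >= p:
                continue
            k = 1 + int(rng.poisson(config.extra_categories_mean))
            k = min(k, config.n_categories)
            cats = [primary_cat[code]]
            if k > 1:
                others = [c for c in cat_ids if c != primary_cat[code]]
                extra = rng.choice(len(others), size=k - 1, replace=False)
                cats.extend(others[j] for j in sorted(extra))
            fc[code] += 1
            for cid in cats:
                reports.append(UseReport(inf.id, code, cid))
                ur[code] += 1
                nur[cid] += 1
                nt_sets[cid].add(code)

    truth = SyntheticTruth(
        fc=fc, ur=ur, nur=nur,
        nt={cid: len(s) for cid, s in nt_sets.items()},
        class_labels=labels,
        bayes_accuracy=max(rho, 1 - rho),
        category_map=category_map)
    dataset = Dataset(informants=informants, species=species,
                      use_reports=reports, categories=categories)
    return dataset, truth


def ground_truth_indices(truth: SyntheticTruth, n_informants: int,
                         ) -> tuple[list[CategoryStats], list[SpeciesStats]]:
    """Indices computed straight from the realized counters, bypassing the
    pipeline's event-level aggregation (the independent second path)."""
    total = sum(truth.nur.values())
    cat_stats = [CategoryStats(cid, truth.nur[cid], truth.nt[cid],
                               icf(truth.nur[cid], truth.nt[cid]),
                               100.0 * truth.nur[cid] / total if total else 0.0)
                 for cid in sorted(truth.nur)]
    codes = sorted(truth.fc)
    rfc_vals = [rfc(truth.fc[c], n_informants) for c in codes]
    ci_vals = [ci(truth.ur[c], n_informants) for c in codes]
    rfc_ranks = dense_rank(rfc_vals)
    ci_ranks = dense_rank(ci_vals)
    sp_stats = [SpeciesStats(c, truth.fc[c], truth.ur[c], rv, cv, rr, cr)
                for c, rv, cv, rr, cr in
                zip(codes, rfc_vals, ci_vals, rfc_ranks, ci_ranks)]
    return cat_stats, sp_stats
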