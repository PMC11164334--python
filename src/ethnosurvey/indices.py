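"""Consensus indices, rankings, frequency tables, age-knowledge regression
and the novelty (presence/absence) analysis.

Definitions, with N the roster size (not the number of citing informants):

* FC(s)  — frequency of citation: distinct informants citing species *s*.
* RFC(s) — FC / N, in [0, 1].
* UR(s)  — use reports: distinct (informant, category) citations of *s*;
  CI(s) = UR / N can exceed 1.
* ICF(u) — informant consensus factor (Nur - Nt) / (Nur - 1) for ailment
  category *u*, where Nur counts citations in the category and Nt the distinct
  species used for it.  Near 1 means informants agree on few species.

Computation is full precision; presentation helpers reproduce the survey
report's printing conventions (truncation toward zero: 2 decimals for
category/per-cent tables, 4 decimals for the species index table).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .core_data import Dataset, PresenceMatrix, UseReport, dedupe_reports
from .preprocessing import species_parts, species_preparations

# ---------------------------------------------------------------------------
# printing conventions


def truncate(x: float, decimals: int) -> float:
    """Truncate toward zero at ``decimals`` places (0.9523 from 20/21)."""
    q = 10 ** decimals
    eps = 1e-9 if x >= 0 else -1e-9
    return math.trunc(x * q + eps) / q


def round_half_up(x: float, decimals: int = 2) -> float:
    q = 10 ** decimals
    return math.floor(x * q + 0.5) / q


def format_table2(x: float) -> float:
    """Category-table style: truncate at 2 decimals (0.64 from 20/31)."""
    return truncate(x, 2)


def format_table3(x: float) -> float:
    """Species-index style: truncate at 4 decimals (1.2380 from 26/21)."""
    return truncate(x, 4)


# ---------------------------------------------------------------------------
# elementary indices


def frequency_of_citation(reports: Iterable[UseReport], species_code: int,
                          known_codes: set[int] | None = None) -> int:
    """Number of distinct informants with at least one report for the species."""
    if known_codes is not None and species_code not in known_codes:
        raise KeyError(f"unknown species code {species_code}")
    return len({r.informant_id for r in reports if r.species_code == species_code})


def use_report_count(reports: Iterable[UseReport], species_code: int,
                     known_codes: set[int] | None = None) -> int:
    """Number of distinct (informant, category) citation pairs for the species."""
    if known_codes is not None and species_code not in known_codes:
        raise KeyError(f"unknown species code {species_code}")
    return len({(r.informant_id, r.category_id)
                for r in reports if r.species_code == species_code})


def rfc(fc: int, n_informants: int) -> float:
    if n_informants < 1:
        raise ValueError("need at least one informant")
    if not 0 <= fc <= n_informants:
        raise ValueError(f"FC={fc} inconsistent with N={n_informants}")
    return fc / n_informants


def ci(ur: int, n_informants: int) -> float:
    if n_informants < 1:
        raise ValueError("need at least one informant")
    if ur < 0:
        raise ValueError("negative use-report count")
    return ur / n_informants


@dataclass(frozen=True)
class IcfValue:
    value: float | None
    status: str           # "ok" | "undefined" | "suppressed"
    reason: str = ""

    def __float__(self) -> float:
        if self.value is None:
            raise ValueError(f"ICF {self.status}: {self.reason}")
        return self.value


def icf(nur: int, nt: int) -> IcfValue:
    """(Nur - Nt) / (Nur - 1); undefined for Nur <= 1, suppressed (mirroring
    the report's "-" cells) for Nur = 2 or Nt > Nur."""
    if nur < 0 or nt < 0:
        raise ValueError("negative counts")
    if nur <= 1:
        return IcfValue(None, "undefined", "fewer than two citations")
    if nt > nur:
        return IcfValue(None, "suppressed", f"Nt={nt} exceeds Nur={nur}")
    if nur == 2:
        return IcfValue(None, "suppressed", "only two citations")
    return IcfValue((nur - nt) / (nur - 1), "ok")


def dense_rank(values: Sequence[float], descending: bool = True) -> list[int]:
    """Equal values share a rank; the next distinct value gets rank+1."""
    if len(values) == 0:
        raise ValueError("empty value sequence")
    distinct = sorted(set(values), reverse=descending)
    lookup = {v: i + 1 for i, v in enumerate(distinct)}
    return [lookup[v] for v in values]


# ---------------------------------------------------------------------------
# dataset-level summaries


@dataclass
class CategoryStats:
    category_id: str
    nur: int
    nt: int
    icf: IcfValue
    citation_share: float  # percent of all citations


@dataclass
class SpeciesStats:
    species_code: int
    fc: int
    ur: int
    rfc: float
    ci: float
    rfc_rank: int
    ci_rank: int


def category_summary(d: Dataset) -> list[CategoryStats]:
    reports = dedupe_reports(d.use_reports)
    if not reports:
        raise ValueError("no use reports to summarize")
    total = len(reports)
    out = []
    for cat in d.categories:
        in_cat = [r for r in reports if r.category_id == cat.id]
        nur = len(in_cat)
        nt = len({r.species_code for r in in_cat})
        out.append(CategoryStats(cat.id, nur, nt, icf(nur, nt),
                                 100.0 * nur / total))
    return out


def species_summary(d: Dataset) -> list[SpeciesStats]:
    reports = dedupe_reports(d.use_reports)
    n = d.n_informants
    rows = []
    for s in d.species:
        fc = frequency_of_citation(reports, s.code)
        ur = use_report_count(reports, s.code)
        rows.append((s.code, fc, ur, rfc(fc, n), ci(ur, n)))
    rfc_ranks = dense_rank([r[3] for r in rows])
    ci_ranks = dense_rank([r[4] for r in rows])
    return [SpeciesStats(code, fc, ur, rf, cv, rr, cr)
            for (code, fc, ur, rf, cv), rr, cr in zip(rows, rfc_ranks, ci_ranks)]


@dataclass
class FrequencyReport:
    family_counts: dict[str, int]
    part_percentages: dict[str, float]
    preparation_percentages: dict[str, float]
    lifeform_percentages: dict[str, float]
    denominators: dict[str, int]


def descriptive_frequencies(d: Dataset) -> FrequencyReport:
    """Family counts and life-form shares are per species; part and
    preparation shares are per label *mention* (a species contributes one
    mention per distinct label), the only denominator under which the
    multi-part rows can sum to 100%."""
    n_species = len(d.species)
    fam: dict[str, int] = {}
    lf: dict[str, int] = {}
    part_mentions: dict[str, int] = {}
    prep_mentions: dict[str, int] = {}
    for s in d.species:
        fam[s.family] = fam.get(s.family, 0) + 1
        lf[s.life_form] = lf.get(s.life_form, 0) + 1
        for p in species_parts(s):
            part_mentions[p] = part_mentions.get(p, 0) + 1
        for p in species_preparations(s):
            prep_mentions[p] = prep_mentions.get(p, 0) + 1
    n_part = sum(part_mentions.values())
    n_prep = sum(prep_mentions.values())
    return FrequencyReport(
        family_counts=dict(sorted(fam.items(), key=lambda kv: (-kv[1], kv[0]))),
        part_percentages={k: 100.0 * v / n_part for k, v in
                          sorted(part_mentions.items(), key=lambda kv: -kv[1])},
        preparation_percentages={k: 100.0 * v / n_prep for k, v in
                                 sorted(prep_mentions.items(), key=lambda kv: -kv[1])},
        lifeform_percentages={k: 100.0 * v / n_species for k, v in
                              sorted(lf.items(), key=lambda kv: -kv[1])},
        denominators={"species": n_species, "part_mentions": n_part,
                      "preparation_mentions": n_prep},
    )


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float
    n: int


def age_use_regression(d: Dataset) -> RegressionResult:
    """OLS of per-informant use-report count on the 1-5 age score.

    The predictor is the binned score, not raw age; the p-value is the
    standard two-sided t-test on the slope.
    """
    reports = dedupe_reports(d.use_reports)
    counts = {i.id: 0 for i in d.informants}
    for r in reports:
        counts[r.informant_id] += 1
    x = [i.age_score for i in d.informants]
    y = [counts[i.id] for i in d.informants]
    if len(x) < 3:
        raise ValueError("need at least three informants")
    if len(set(x)) == 1:
        raise ValueError("degenerate design: zero variance in age score")
    if len(set(y)) == 1:
        # constant response: slope 0 with nothing explained
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, 0.0, len(x))
    fit = stats.linregress(x, y)
    return RegressionResult(fit.slope, fit.intercept, fit.rvalue ** 2,
                            fit.pvalue, fit.stderr, len(x))


def novelty_count(m: PresenceMatrix) -> tuple[int, list[int]]:
    """Species never reported by any prior study: all-zero presence rows."""
    codes = [c for c, row in zip(m.species_codes, m.cells) if sum(row) == 0]
    return len(codes), sorted(codes)
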