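"""Step 1 of the pipeline: text canonicalization and feature selection.

Survey spreadsheets mix case, stray spaces and trailing punctuation
("Oral,Topical", "topical", "Decoction,").  Classification needs one clean
nominal value per cell, one record per species, and no identifier columns
(scientific name, vernacular name, voucher number carry no predictive signal).
The single record whose mode-of-application class is missing is dropped and
logged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .core_data import Dataset, SpeciesRecord

log = logging.getLogger(__name__)

MISSING = "missing"

#: canonical plant-part vocabulary; "oil of X" / "juice of X" collapse to the
#: derived-product label
PART_VOCAB = [
    "leaf", "seed", "fruit", "flower", "aerial parts", "root", "resin", "gum",
    "corm", "stem", "whole plant", "skin", "capsule", "rhizome", "latex",
    "oil", "juice",
]

PREPARATION_VOCAB = [
    "decoction", "infusion", "liniment", "powder", "freshly cooked",
    "raw eating", "moisturized in water", "mix seeds with water", "syrup",
    "smoke", "none",
]

FEATURE_NAMES = ["family", "part_used", "preparation", "life_form", "use_category"]


def normalize_text(raw: str | None) -> str:
    """Lowercase, strip, collapse internal whitespace, drop trailing
    punctuation; empty input maps to the sentinel ``"missing"``."""
    if raw is None:
        return MISSING
    s = re.sub(r"\s+", " ", str(raw).strip()).lower()
    s = re.sub(r"\s*,\s*", ", ", s)          # one space after list commas
    s = s.rstrip(" .,;:")
    return s if s else MISSING


def canonicalize_mode(raw: str) -> str:
    """Collapse mode-of-application variants to {oral, topical, both, missing}.

    Cells mentioning both routes ("Oral,Topical", "Topical, oral") map to
    ``both``; "-" or an empty cell maps to ``missing``.  Any other token is a
    canonicalization error.
    """
    s = normalize_text(raw)
    if s in (MISSING, "-"):
        return MISSING
    has_oral = "oral" in s
    has_topical = "topical" in s
    if has_oral and has_topical:
        return "both"
    if has_oral:
        return "oral"
    if has_topical:
        return "topical"
    if s == "both":
        return "both"
    raise ValueError(f"unrecognized mode of application {raw!r}")


def canonicalize_part(raw: str) -> str:
    """Map one part phrase to the canonical vocabulary ("Oil of fruit" ->
    "oil"; unknown phrases are kept normalized rather than rejected)."""
    s = normalize_text(raw)
    if s.startswith("oil of") or s == "oil":
        return "oil"
    if s.startswith("juice of") or s == "juice":
        return "juice"
    return s


def canonicalize_preparation(raw: str) -> str:
    """Normalize one preparation phrase; parentheticals such as
    "Decoction (with yogurt)" reduce to the base method."""
    s = normalize_text(raw)
    s = re.sub(r"\s*\(.*\)$", "", s).strip()
    if s in ("-", MISSING, ""):
        return "none"
    return s


def species_parts(s: SpeciesRecord) -> tuple[str, ...]:
    return tuple(sorted({canonicalize_part(p) for p in s.parts_used}))


def species_preparations(s: SpeciesRecord) -> tuple[str, ...]:
    return tuple(sorted({canonicalize_preparation(p) for p in s.preparation}))


@dataclass
class FeatureTable:
    """One record per species: nominal features plus the class label."""

    feature_names: list[str]
    records: list[dict]            # feature name -> nominal value
    classes: list[str]             # aligned with records
    dropped_codes: list[int] = field(default_factory=list)
    encoding: str = "nominal"

    def __len__(self) -> int:
        return len(self.records)

    def vocabulary(self, feature: str) -> list[str]:
        return sorted({r[feature] for r in self.records})


def primary_category(s: SpeciesRecord, category_map: dict[str, str]) -> str:
    """The species' first-listed medicinal use mapped through the
    phrase-to-category table; unmapped phrases yield the missing sentinel."""
    for use in s.medicinal_uses:
        key = normalize_text(use)
        if key in category_map:
            return category_map[key]
    return MISSING


def preprocess(d: Dataset, category_map: dict[str, str],
               encoding: str = "nominal") -> FeatureTable:
    """Build the classifier's feature table from a validated dataset.

    ``encoding="nominal"`` keeps each normalized multi-valued cell as one
    nominal value (sorted ``;``-joined set); ``"multihot"`` expands parts and
    preparations into per-vocabulary binary indicator features.
    """
    if encoding not in ("nominal", "multihot"):
        raise ValueError(f"unknown encoding {encoding!r}")

    records, classes, dropped = [], [], []
    for s in d.species:
        mode = canonicalize_mode(s.mode_of_application)
        if mode == MISSING:
            dropped.append(s.code)
            log.info("dropping species %d (%s): missing mode of application",
                     s.code, s.scientific_name)
            continue
        parts = species_parts(s)
        preps = species_preparations(s)
        rec = {
            "family": normalize_text(s.family),
            "life_form": s.life_form,
            "use_category": primary_category(s, category_map),
        }
        if encoding == "nominal":
            rec["part_used"] = ";".join(parts) or MISSING
            rec["preparation"] = ";".join(preps) or MISSING
        else:
            for p in PART_VOCAB:
                rec[f"part={p}"] = "1" if p in parts else "0"
            for p in PREPARATION_VOCAB:
                rec[f"prep={p}"] = "1" if p in preps else "0"
        records.append(rec)
        classes.append(mode)

    if not records:
        raise ValueError("preprocessing produced an empty feature table")

    if encoding == "nominal":
        names = list(FEATURE_NAMES)
    else:
        names = (["family", "life_form", "use_category"]
                 + [f"part={p}" for p in PART_VOCAB]
                 + [f"prep={p}" for p in PREPARATION_VOCAB])
    return FeatureTable(feature_names=names, records=records, classes=classes,
                        dropped_codes=dropped, encoding=encoding)


def feature_table_to_frame(t: FeatureTable):
    """FeatureTable as a pandas DataFrame with a ``mode_of_application``
    class column (the CSV layout the CLI writes)."""
    import pandas as pd

    df = pd.DataFrame(t.records, columns=t.feature_names)
    df["mode_of_application"] = t.classes
    return df
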