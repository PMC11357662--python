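"""Most-advanced-finding classification and screening-cohort eligibility filters.

Each participant's colonoscopy record is reduced to the most advanced finding:

    CRC > advanced precancerous lesion > non-advanced adenoma
        > excluded polyp only > no finding

where an adenoma is advanced if it is >= 1 cm, has tubulovillous or villous
components, or high-grade dysplasia; a sessile serrated polyp is advanced if
>= 1 cm. Hyperplastic polyps, non-defined polyps and small serrated lesions
do not count as neoplasms: participants carrying only those are excluded from
the comparison groups altogether.

Eligibility mirrors an average-risk screening population: ages 50-79, no CRC
or IBD history, no colonoscopy in the preceding five years, adequate bowel
preparation and a complete (coecum-reached) examination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AmbiguousFindingWarning

FINDING_KINDS = frozenset({
    "CRC", "adenoma", "sessile_serrated_polyp", "hyperplastic_polyp",
    "non_defined_polyp", "serrated_lesion",
})

# Outcome classes ordered from most to least severe.
CRC = "CRC"
ADVANCED = "advanced_precancerous_lesion"
NON_ADVANCED = "non_advanced_adenoma"
POLYP_ONLY = "excluded_polyp_only"
NO_FINDING = "no_finding"
SEVERITY = (CRC, ADVANCED, NON_ADVANCED, POLYP_ONLY, NO_FINDING)

ANY_NEOPLASM = frozenset({CRC, ADVANCED, NON_ADVANCED})
ADVANCED_NEOPLASM = frozenset({CRC, ADVANCED})


@dataclass(frozen=True)
class Finding:
    """One colonoscopy finding: lesion kind, size and histology flags."""

    kind: str
    size_cm: float | None = None
    tubulovillous_or_villous: bool = False
    high_grade_dysplasia: bool = False

    def __post_init__(self):
        if self.kind not in FINDING_KINDS:
            raise ValueError(f"unknown finding kind {self.kind!r}")
        if self.size_cm is not None and self.size_cm < 0:
            raise ValueError(f"negative lesion size {self.size_cm}")


@dataclass(frozen=True)
class OutcomeClass:
    """Most advanced finding with the derived analysis groupings."""

    value: str

    def __post_init__(self):
        if self.value not in SEVERITY:
            raise ValueError(f"unknown outcome class {self.value!r}")

    @property
    def any_neoplasm(self) -> bool:
        return self.value in ANY_NEOPLASM

    @property
    def advanced_neoplasm(self) -> bool:
        return self.value in ADVANCED_NEOPLASM


def _finding_class(f: Finding) -> str:
    size_known_ge1 = f.size_cm is not None and f.size_cm >= 1.0
    if f.kind == "CRC":
        return CRC
    if f.kind == "adenoma":
        # Unknown size counts as non-advanced unless histology flags are set.
        if size_known_ge1 or f.tubulovillous_or_villous or f.high_grade_dysplasia:
            return ADVANCED
        return NON_ADVANCED
    if f.kind == "sessile_serrated_polyp":
        return ADVANCED if size_known_ge1 else POLYP_ONLY
    if f.kind == "serrated_lesion":
        if size_known_ge1:
            warnings.warn(
                "serrated lesion >= 1 cm that is not a sessile serrated polyp: "
                "classification not fully specified; treated as excluded polyp",
                AmbiguousFindingWarning, stacklevel=3,
            )
        return POLYP_ONLY
    # hyperplastic_polyp, non_defined_polyp
    return POLYP_ONLY


def classify_finding(findings) -> OutcomeClass:
    """Reduce a (possibly empty) findings list to the most advanced class."""
    best = NO_FINDING
    order = {c: i for i, c in enumerate(SEVERITY)}
    for f in findings:
        if not isinstance(f, Finding):
            f = Finding(**f)
        c = _finding_class(f)
        if order[c] < order[best]:
            best = c
    return OutcomeClass(best)


@dataclass
class ExclusionResult:
    kept: pd.DataFrame
    tallies: dict[str, int]
    n_input: int = 0
    rules: tuple = field(default_factory=tuple)

    @property
    def n_kept(self) -> int:
        return len(self.kept)


#: Exclusion rules in the order they are applied; each participant is tallied
#: under the first rule that removes them.
EXCLUSION_RULES = (
    "missing_meat_info",
    "polyp_only_finding",
    "age_out_of_range",
    "crc_or_ibd_history",
    "recent_colonoscopy",
    "inadequate_bowel_prep",
    "incomplete_colonoscopy",
    "not_genotyped",
)


def apply_exclusions(records: pd.DataFrame, require_genotyped: bool = False,
                     recent_colonoscopy_inclusive: bool = False) -> ExclusionResult:
    """Apply the eligibility filters in order; return kept rows and a tally.

    Expected columns: ``meat_info_complete``, ``outcome_class``, ``age``,
    ``history_crc``, ``history_ibd``, ``last_colonoscopy_years_ago`` (NaN when
    never), ``bowel_prep_adequate``, ``coecum_reached`` and, when
    ``require_genotyped``, ``genotyped``.

    A colonoscopy exactly 5.0 years ago is kept by default ("preceding five
    years" read strictly); set ``recent_colonoscopy_inclusive`` to exclude it.
    """
    df = records
    last = pd.to_numeric(df["last_colonoscopy_years_ago"], errors="coerce")
    recent = (last <= 5.0) if recent_colonoscopy_inclusive else (last < 5.0)
    predicates = {
        "missing_meat_info": ~df["meat_info_complete"].astype(bool),
        "polyp_only_finding": df["outcome_class"].eq(POLYP_ONLY),
        "age_out_of_range": (df["age"] < 50) | (df["age"] >= 80),
        "crc_or_ibd_history": df["history_crc"].astype(bool)
                              | df["history_ibd"].astype(bool),
        "recent_colonoscopy": recent.fillna(False),
        "inadequate_bowel_prep": ~df["bowel_prep_adequate"].astype(bool),
        "incomplete_colonoscopy": ~df["coecum_reached"].astype(bool),
    }
    if require_genotyped:
        predicates["not_genotyped"] = ~df["genotyped"].astype(bool)

    excluded = np.zeros(len(df), dtype=bool)
    tallies: dict[str, int] = {}
    for rule in EXCLUSION_RULES:
        if rule not in predicates:
            continue
        hit = predicates[rule].to_numpy(dtype=bool) & ~excluded
        tallies[rule] = int(hit.sum())
        excluded |= hit
    return ExclusionResult(kept=df.loc[~excluded].copy(), tallies=tallies,
                           n_input=len(df), rules=tuple(tallies))


def outcome_flags(outcome_class: pd.Series) -> pd.DataFrame:
    """Boolean any-/advanced-neoplasm indicators for a class column."""
    return pd.DataFrame({
        "any_neoplasm": outcome_class.isin(ANY_NEOPLASM),
        "advanced_neoplasm": outcome_class.isin(ADVANCED_NEOPLASM),
    }, index=outcome_class.index)
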