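"""Weighted polygenic risk scores and reference-based percentile/tertile scaling.

A polygenic risk score (PRS) is the weighted sum over risk loci of the
effect-allele dosage times the per-allele log-odds weight,

    PRS_i = sum_j beta_j * g_ij ,

with dosages g_ij in [0, 2] oriented to the effect allele of each variant.
Scores are then placed on the scale actually used for inference and risk
communication: percentiles of a reference distribution (by default the
participants with no finding at colonoscopy) and tertiles of the same
reference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DegenerateReferenceError, StrandAmbiguityWarning

logger = logging.getLogger(__name__)

_DOSAGE_TOL = 1e-6
_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass(frozen=True)
class VariantWeight:
    """One scoring-file row: a variant, its effect allele and log-odds weight."""

    variant_id: str
    effect_allele: str
    other_allele: str
    weight: float

    def __post_init__(self):
        if self.effect_allele == self.other_allele:
            raise ValueError(
                f"{self.variant_id}: effect and other allele are identical "
                f"({self.effect_allele})"
            )
        if not np.isfinite(self.weight):
            raise ValueError(f"{self.variant_id}: non-finite weight {self.weight}")


class GenotypeMatrix:
    """Participants x variants dosage matrix with per-variant allele orientation.

    Parameters
    ----------
    participant_ids, variant_ids : sequences of unique identifiers.
    dosages : (n_participants, n_variants) array of allele dosages in [0, 2];
        NaN marks a missing dosage.
    counted_alleles : optional mapping ``variant_id -> (counted, other)`` giving
        the allele whose copies the stored dosage counts (e.g. the VCF ALT
        allele). When absent, dosages are taken as already oriented to the
        scoring file's effect allele.
    """

    def __init__(self, participant_ids, variant_ids, dosages, counted_alleles=None):
        self.participant_ids = list(participant_ids)
        self.variant_ids = list(variant_ids)
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape != (len(self.participant_ids), len(self.variant_ids)):
            raise ValueError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(self.participant_ids)} participants x "
                f"{len(self.variant_ids)} variants"
            )
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("duplicate variant IDs in genotype matrix")
        with np.errstate(invalid="ignore"):
            bad = (dosages < -_DOSAGE_TOL) | (dosages > 2 + _DOSAGE_TOL)
        if np.any(bad):
            raise ValueError("dosages outside [0, 2]")
        self.dosages = dosages
        self.counted_alleles = dict(counted_alleles) if counted_alleles else None
        self._col = {v: j for j, v in enumerate(self.variant_ids)}

    @property
    def shape(self):
        return self.dosages.shape

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self._col[variant_id]]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._col


def _as_weight_list(weights) -> list[VariantWeight]:
    if isinstance(weights, pd.DataFrame):
        return [
            VariantWeight(
                str(r.variant_id), str(r.effect_allele), str(r.other_allele),
                float(r.effect_weight),
            )
            for r in weights.itertuples(index=False)
        ]
    return list(weights)


class PRSScorer(BaseEstimator, TransformerMixin):
    """Compute weighted PRS values from a genotype matrix and variant weights.

    Dosages are oriented to each weight's effect allele before summing: when
    the matrix stores the dosage of the *other* allele, ``g -> 2 - g``.
    Strand-ambiguous (A/T, C/G) variants are retained with a logged warning
    since allele labels cannot resolve their strand.

    Parameters
    ----------
    weights : DataFrame (variant_id, effect_allele, other_allele, effect_weight)
        or a sequence of :class:`VariantWeight`.
    on_missing_variant : {"error", "drop"}
        What to do when a weighted variant is absent from the matrix.
    missing_dosage : {"allele_freq", "error"}
        Policy for NaN dosage cells. ``"allele_freq"`` fills with twice the
        empirical effect-allele frequency in the cohort (the mean observed
        oriented dosage), the standard practice for score imputation.
    """

    def __init__(self, weights=None, on_missing_variant="error",
                 missing_dosage="allele_freq"):
        self.weights = weights
        self.on_missing_variant = on_missing_variant
        self.missing_dosage = missing_dosage

    def fit(self, X: GenotypeMatrix, y=None):
        self.weights_ = _as_weight_list(self.weights)
        if not self.weights_:
            raise ValueError("no variant weights supplied")
        return self

    def transform(self, X: GenotypeMatrix) -> np.ndarray:
        if not hasattr(self, "weights_"):
            self.fit(X)
        n = len(X.participant_ids)
        prs = np.zeros(n)
        for w in self.weights_:
            if w.variant_id not in X:
                if self.on_missing_variant == "drop":
                    logger.warning("variant %s absent from matrix; dropped",
                                   w.variant_id)
                    continue
                raise KeyError(f"variant {w.variant_id} absent from genotype matrix")
            g = self._oriented_dosage(X, w)
            prs += w.weight * g
        return prs

    def _oriented_dosage(self, X: GenotypeMatrix, w: VariantWeight) -> np.ndarray:
        g = X.column(w.variant_id).copy()
        if X.counted_alleles is not None:
            counted, other = X.counted_alleles[w.variant_id]
            pair = {counted, other}
            if frozenset(pair) in _AMBIGUOUS_PAIRS:
                warnings.warn(
                    f"variant {w.variant_id} is strand-ambiguous "
                    f"({counted}/{other}); retained as stored",
                    StrandAmbiguityWarning, stacklevel=2,
                )
            if counted == w.effect_allele and other == w.other_allele:
                pass
            elif counted == w.other_allele and other == w.effect_allele:
                g = 2.0 - g
            else:
                raise ValueError(
                    f"variant {w.variant_id}: matrix alleles {counted}/{other} "
                    f"do not match weights {w.effect_allele}/{w.other_allele}"
                )
        miss = np.isnan(g)
        if miss.any():
            if self.missing_dosage == "error":
                raise ValueError(f"missing dosages at variant {w.variant_id}")
            if miss.all():
                raise ValueError(
                    f"variant {w.variant_id} has no observed dosages to "
                    "estimate an allele frequency from"
                )
            g[miss] = g[~miss].mean()  # = 2 * empirical effect-allele frequency
        return g


class ReferencePercentiler(BaseEstimator, TransformerMixin):
    """Map PRS values to percentiles of a reference distribution.

    The percentile of a query value x is ``100 * r / (R + 1)`` where R is the
    reference size and r is x's mid-rank among the reference values:
    ``r = #(ref < x) + (#(ref == x) + 1) / 2``. Queries outside the reference
    range land strictly inside the open interval (0, 100).
    """

    def fit(self, X, y=None):
        ref = np.asarray(X, dtype=float).ravel()
        if ref.size == 0:
            raise DegenerateReferenceError("empty reference set")
        self.reference_ = np.sort(ref)
        return self

    def transform(self, X) -> np.ndarray:
        ref = self.reference_
        x = np.asarray(X, dtype=float).ravel()
        nless = np.searchsorted(ref, x, side="left")
        neq = np.searchsorted(ref, x, side="right") - nless
        rank = nless + (neq + 1) / 2.0
        return 100.0 * rank / (ref.size + 1)


class TertileAssigner(BaseEstimator, TransformerMixin):
    """Assign T1/T2/T3 by the empirical tertiles of a reference distribution.

    Cut points are the 1/3 and 2/3 empirical quantiles (inverted-CDF order
    statistics) of the reference; assignment intervals are right-closed:
    (-inf, q33], (q33, q67], (q67, inf). On a reference of 3k distinct values
    this splits the reference itself exactly k/k/k.
    """

    labels = ("T1", "T2", "T3")

    def fit(self, X, y=None):
        ref = np.asarray(X, dtype=float).ravel()
        if ref.size == 0:
            raise DegenerateReferenceError("empty reference set")
        self.q33_, self.q67_ = np.quantile(ref, [1 / 3, 2 / 3], method="inverted_cdf")
        if self.q33_ >= self.q67_:
            raise DegenerateReferenceError(
                "reference distribution is degenerate: tertile cut points "
                f"coincide (q33={self.q33_!r}, q67={self.q67_!r})"
            )
        return self

    def transform(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).ravel()
        codes = np.full(x.shape, 2, dtype=int)
        codes[x <= self.q67_] = 1
        codes[x <= self.q33_] = 0
        return np.asarray(self.labels)[codes]

    def transform_codes(self, X) -> np.ndarray:
        """Ordinal 1/2/3 coding, used by per-tertile trend models."""
        return np.char.lstrip(self.transform(X).astype(str), "T").astype(int)


def compute_prs(genotypes: GenotypeMatrix, weights, **kwargs) -> np.ndarray:
    """Weighted PRS per participant; see :class:`PRSScorer`."""
    return PRSScorer(weights, **kwargs).fit(genotypes).transform(genotypes)


def percentile_transform(values: Sequence[float], reference: Sequence[float]) -> np.ndarray:
    """Percentiles of ``values`` within ``reference``; see :class:`ReferencePercentiler`."""
    return ReferencePercentiler().fit(reference).transform(values)


def tertile_assign(values: Sequence[float], reference: Sequence[float]) -> np.ndarray:
    """T1/T2/T3 labels for ``values`` by reference tertiles; see :class:`TertileAssigner`."""
    return TertileAssigner().fit(reference).transform(values)
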