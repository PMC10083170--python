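"""Scikit-learn-style estimator implementing the LymphPlex assignment rule.

The assignment cascade, per sample:

1. **TP53 priority.** A sample with a qualifying *TP53* mutation is labelled
   ``TP53Mut`` regardless of any co-occurring feature.
2. **Subtype scores.** For each remaining subtype ``s`` with defining
   feature set ``F_s``, the subtype-associated score is the normalized
   overlap ``|F_s ∩ present| / |F_s|`` — the nearest-medoid rule over binary
   feature vectors when the medoid of a subtype is the indicator of its
   defining set (the sets are disjoint, so overlap with one subtype never
   counts toward another).
3. **Selection.** If all scores are zero the sample is ``NOS``; otherwise
   the argmax wins, with ties resolved by the configured policy (default:
   conservative ``nos_on_tie``).
4. **MYC split.** An EZB-like winner is split into ``EZB_like_MYC_pos`` /
   ``EZB_like_MYC_neg`` by *MYC* rearrangement status; MYC status is
   ignored for every other label.
"""

from __future__ import annotations

from typing import AbstractSet, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .panel import (
    EZB,
    EZB_MYC_NEG,
    EZB_MYC_POS,
    FMYC,
    LYMPHPLEX_DEFINITIONS,
    NOS,
    TP53MUT,
    SubtypeDefinition,
)

#: Fixed-precedence tie-break order: single-gene definers first.
PRECEDENCE_ORDER = ("N1_like", "MCD_like", "BN2_like", "EZB_like", "ST2_like")

TIE_BREAK_POLICIES = ("nos_on_tie", "precedence", "weighted")


def subtype_scores_from_features(
    present: AbstractSet[str],
    definitions: Sequence[SubtypeDefinition],
    weights: Optional[Mapping[str, float]] = None,
) -> dict[str, float]:
    """Normalized-overlap score of each subtype for a set of present features.

    With ``weights`` (per-feature, default 1.0 each) the score becomes the
    weighted fraction of the defining set that is present.  Scores are
    always in [0, 1] and equal 1 iff every defining feature is present.
    """
    w = weights or {}
    scores: dict[str, float] = {}
    for d in definitions:
        feats = d.features
        denom = sum(w.get(f, 1.0) for f in feats)
        num = sum(w.get(f, 1.0) for f in feats & present)
        scores[d.name] = num / denom if denom else 0.0
    return scores


def cascade(
    present: AbstractSet[str],
    myc_rearranged: bool,
    definitions: Sequence[SubtypeDefinition],
    tie_break: str = "nos_on_tie",
    weights: Optional[Mapping[str, float]] = None,
    myc_split: bool = True,
) -> tuple[str, dict[str, float], tuple[str, ...]]:
    """Run the assignment cascade on one binary feature set.

    Returns ``(label, scores, evidence)`` where ``scores`` maps every
    subtype name to its normalized overlap (the TP53Mut score included for
    reporting) and ``evidence`` is the sorted tuple of the winning
    subtype's defining features present in the sample.
    """
    if tie_break not in TIE_BREAK_POLICIES:
        raise ValueError(
            f"unknown tie-break policy {tie_break!r}; "
            f"expected one of {TIE_BREAK_POLICIES}"
        )
    by_name = {d.name: d for d in definitions}
    scores = subtype_scores_from_features(present, definitions)

    tp53_def = by_name.get(TP53MUT)
    if tp53_def is not None and tp53_def.features & present:
        evidence = tuple(sorted(tp53_def.features & present))
        return TP53MUT, scores, evidence

    candidates = {n: s for n, s in scores.items() if n != TP53MUT}
    best = max(candidates.values(), default=0.0)
    if best == 0.0:
        return NOS, scores, ()

    tied = sorted(n for n, s in candidates.items() if s == best)
    if len(tied) > 1 and tie_break == "weighted":
        wscores = subtype_scores_from_features(
            present, [by_name[n] for n in tied], weights
        )
        wbest = max(wscores.values())
        tied = sorted(n for n, s in wscores.items() if s == wbest)
    if len(tied) > 1:
        if tie_break == "precedence":
            order = [n for n in PRECEDENCE_ORDER if n in tied]
            tied = [order[0]] if order else [tied[0]]
        else:  # nos_on_tie (and weighted with a residual tie)
            return NOS, scores, ()
    winner = tied[0]

    evidence = tuple(sorted(by_name[winner].features & present))
    if winner == EZB and myc_split:
        winner = EZB_MYC_POS if myc_rearranged else EZB_MYC_NEG
    return winner, scores, evidence


class LymphPlexClassifier(BaseEstimator, ClassifierMixin):
    """Rule-based DLBCL genetic-subtype classifier (38-feature panel).

    Operates on a binary feature matrix: a pandas DataFrame (or ndarray
    with ``feature_names`` given at fit) whose columns are the 35 panel
    gene symbols plus ``FBCL2``, ``FBCL6`` and ``FMYC`` rearrangement
    flags; entries are truthy iff the alteration is present.

    Parameters
    ----------
    definitions
        Subtype definitions to use; defaults to the shipped LymphPlex sets.
        The definitions are data: overriding them (e.g. with the legacy
        20-gene sets) changes the classifier without code changes.
    tie_break
        ``"nos_on_tie"`` (default, conservative), ``"precedence"``
        (N1 > MCD > BN2 > EZB > ST2), or ``"weighted"`` (per-feature
        weights break the tie).
    weights
        Optional per-feature weights used by the ``weighted`` policy.
    myc_split
        Split EZB-like winners by MYC rearrangement status (default True).

    Examples
    --------
    >>> import pandas as pd
    >>> clf = LymphPlexClassifier().fit()
    >>> X = pd.DataFrame(0, index=["s1"], columns=clf.feature_names_in_)
    >>> X.loc["s1", "NOTCH1"] = 1
    >>> clf.predict(X)
    array(['N1_like'], dtype=object)
    """

    def __init__(
        self,
        definitions: Optional[Sequence[SubtypeDefinition]] = None,
        tie_break: str = "nos_on_tie",
        weights: Optional[Mapping[str, float]] = None,
        myc_split: bool = True,
    ) -> None:
        self.definitions = definitions
        self.tie_break = tie_break
        self.weights = weights
        self.myc_split = myc_split

    # The rule set is fixed a priori; fit validates parameters and records
    # the feature universe rather than estimating anything from data.
    def fit(self, X=None, y=None) -> "LymphPlexClassifier":
        defs = tuple(self.definitions) if self.definitions is not None \
            else LYMPHPLEX_DEFINITIONS
        if self.tie_break not in TIE_BREAK_POLICIES:
            raise ValueError(f"unknown tie-break policy {self.tie_break!r}")
        names = [d.name for d in defs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate subtype names in definitions")
        self.definitions_ = defs
        features: set[str] = {FMYC} if self.myc_split else set()
        for d in defs:
            features |= d.features
        self.feature_names_in_ = np.asarray(sorted(features), dtype=object)
        labels = set(names)
        if EZB in labels and self.myc_split:
            labels -= {EZB}
            labels |= {EZB_MYC_POS, EZB_MYC_NEG}
        self.classes_ = np.asarray(sorted(labels | {NOS}), dtype=object)
        return self

    def _frame(self, X) -> pd.DataFrame:
        check_is_fitted(self, "definitions_")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X), columns=self.feature_names_in_)
        missing = [
            f for f in self.feature_names_in_
            if f not in X.columns and f != FMYC
        ]
        if missing:
            raise ValueError(f"feature matrix is missing columns: {missing}")
        return X

    def predict(self, X) -> np.ndarray:
        """Subtype label per row of the binary feature matrix."""
        X = self._frame(X)
        return np.asarray([lbl for lbl, _, _ in self._cascade_rows(X)],
                          dtype=object)

    def decision_function(self, X) -> pd.DataFrame:
        """Per-subtype normalized-overlap scores, one row per sample."""
        X = self._frame(X)
        rows = [scores for _, scores, _ in self._cascade_rows(X)]
        return pd.DataFrame(rows, index=X.index)

    def _cascade_rows(self, X: pd.DataFrame):
        have_myc = FMYC in X.columns
        feature_cols = [c for c in X.columns if c in set(self.feature_names_in_)]
        for _, row in X.iterrows():
            present = frozenset(c for c in feature_cols
                                if c != FMYC and bool(row[c]))
            myc = bool(row[FMYC]) if have_myc else False
            yield cascade(present, myc, self.definitions_,
                          tie_break=self.tie_break, weights=self.weights,
                          myc_split=self.myc_split)
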