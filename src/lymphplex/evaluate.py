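"""Benchmarking a subtype labeling against a reference labeling.

Mirrors the published evaluation protocol: cross-tabulate the two
labelings, optionally drop samples carrying an excluded label in either
scheme (TP53Mut on one side, its copy-number-aware analog A53 on the
other — classes the two algorithms define differently), then compute
one-vs-rest sensitivity, specificity and precision (PPV) per retained
class.  Also provides the genetic-coherence rank-sum comparison of
subtype-associated scores and pooled response-rate arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import subtype_scores
from .panel import LYMPHPLEX_DEFINITIONS, NOS, SubtypeDefinition
from .records import SampleAlterationProfile


@dataclass
class BenchmarkSummary:
    """Confusion matrix plus optional per-class one-vs-rest metrics.

    ``confusion`` is indexed predicted label (rows) x reference label
    (columns).  ``per_class`` maps each retained class to
    ``{"sensitivity", "specificity", "precision"}``; a metric whose
    denominator is zero is reported as ``None`` (NA).
    """

    confusion: pd.DataFrame
    long_table: pd.DataFrame
    per_class: dict[str, dict[str, Optional[float]]] = field(default_factory=dict)
    excluded_classes: frozenset[str] = frozenset()
    n_unique_agreed: int = 0


def cross_tabulate(
    pred: Mapping[str, str],
    ref: Mapping[str, str],
    label_map: Optional[Mapping[str, str]] = None,
) -> BenchmarkSummary:
    """Cross-tabulate predicted vs reference labels over one sample universe.

    ``label_map`` translates predicted labels into the reference vocabulary
    (e.g. ``MCD_like -> MCD``) before counting.  A sample present in only
    one labeling is a hard error.  The ``long_table`` is a Sankey-ready
    (pred, ref, count) long format.
    """
    pred_only = sorted(set(pred) - set(ref))
    ref_only = sorted(set(ref) - set(pred))
    if pred_only or ref_only:
        raise ValueError(
            "labelings cover different samples; "
            f"only in predicted: {pred_only}; only in reference: {ref_only}"
        )
    lm = label_map or {}
    pairs = [(lm.get(pred[s], pred[s]), ref[s]) for s in sorted(pred)]
    df = pd.DataFrame(pairs, columns=["pred", "ref"])
    confusion = pd.crosstab(df["pred"], df["ref"])
    long_table = (
        df.value_counts(["pred", "ref"]).rename("count").reset_index()
        .sort_values(["pred", "ref"]).reset_index(drop=True)
    )
    agreed = int((df["pred"] == df["ref"]).sum())
    return BenchmarkSummary(confusion=confusion, long_table=long_table,
                            n_unique_agreed=agreed)


def per_class_metrics(
    summary: BenchmarkSummary,
    exclude: Iterable[str] = ("TP53Mut", "A53"),
    include_nos: bool = False,
) -> BenchmarkSummary:
    """Complete a benchmark with one-vs-rest metrics per retained class.

    Samples whose predicted OR reference label is in ``exclude`` are
    removed before any metric is computed (so excluded classes leave every
    denominator).  NOS is additionally excluded from the per-class metric
    set by default, though it remains a first-class label in the confusion
    matrix; pass ``include_nos=True`` to score it like any other class.
    """
    excluded = frozenset(exclude)
    metric_excluded = excluded if include_nos else excluded | {NOS}
    lt = summary.long_table
    keep = ~(lt["pred"].isin(excluded) | lt["ref"].isin(excluded))
    sub = lt[keep]
    if sub["count"].sum() == 0:
        raise ValueError("no samples remain after exclusion")

    classes = sorted(
        (set(sub["pred"]) | set(sub["ref"])) - metric_excluded
    )
    if not classes:
        raise ValueError("no classes remain after exclusion")

    total = int(sub["count"].sum())
    per_class: dict[str, dict[str, Optional[float]]] = {}
    for c in classes:
        tp = int(sub[(sub["pred"] == c) & (sub["ref"] == c)]["count"].sum())
        fp = int(sub[(sub["pred"] == c) & (sub["ref"] != c)]["count"].sum())
        fn = int(sub[(sub["pred"] != c) & (sub["ref"] == c)]["count"].sum())
        tn = total - tp - fp - fn
        per_class[c] = {
            "sensitivity": tp / (tp + fn) if tp + fn else None,
            "specificity": tn / (tn + fp) if tn + fp else None,
            "precision": tp / (tp + fp) if tp + fp else None,
        }
    return BenchmarkSummary(
        confusion=summary.confusion,
        long_table=summary.long_table,
        per_class=per_class,
        excluded_classes=excluded,
        n_unique_agreed=summary.n_unique_agreed,
    )


@dataclass(frozen=True)
class CoherenceResult:
    """Rank-sum comparison of a subtype's scores between feature carriers
    and non-carriers."""

    subtype: str
    score_present: tuple[float, ...]
    score_absent: tuple[float, ...]
    statistic: Optional[float]
    p_value: Optional[float]


def coherence_test(
    profiles: Sequence[SampleAlterationProfile],
    subtype: str,
    definitions: Sequence[SubtypeDefinition] = LYMPHPLEX_DEFINITIONS,
    exact_below: int = 50,
) -> CoherenceResult:
    """Compare subtype-associated scores between carriers and non-carriers.

    Carriers hold >= 1 of the subtype's defining features.  The comparison
    is a two-sided Mann-Whitney rank-sum test, exact for groups smaller
    than ``exact_below``, normal-approximated (tie-corrected) otherwise.
    An empty group yields NA statistics with a warning rather than an error.
    """
    by_name = {d.name: d for d in definitions}
    if subtype not in by_name:
        raise ValueError(f"unknown subtype {subtype!r}")
    d = by_name[subtype]

    present: list[float] = []
    absent: list[float] = []
    for p in profiles:
        score = subtype_scores(p, definitions)[subtype]
        (present if score > 0 else absent).append(score)

    if not present or not absent:
        warnings.warn(
            f"coherence_test({subtype}): one group is empty "
            f"(carriers={len(present)}, non-carriers={len(absent)})",
            stacklevel=2,
        )
        return CoherenceResult(subtype, tuple(present), tuple(absent),
                               None, None)
    method = "exact" if min(len(present), len(absent)) < exact_below else "asymptotic"
    try:
        res = stats.mannwhitneyu(present, absent, alternative="two-sided",
                                 method=method)
    except ValueError:  # exact method refuses ties; fall back
        res = stats.mannwhitneyu(present, absent, alternative="two-sided",
                                 method="asymptotic")
    return CoherenceResult(subtype, tuple(present), tuple(absent),
                           float(res.statistic), float(res.pvalue))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (optional across subtypes)."""
    from statsmodels.stats.multitest import multipletests

    return list(multipletests(p_values, method="fdr_bh")[1])


def pooled_response_rates(
    counts: Mapping[str, tuple[int, int, int]],
) -> dict:
    """Pool per-subtype response counts into overall rates.

    ``counts`` maps subtype -> ``(responders, complete_responders,
    evaluable)``.  Pooled ORR = sum(responders)/sum(evaluable), pooled
    CRR likewise; per-subtype rates are computed the same way.  Rates are
    fractions; ``*_pct`` entries are percentages rounded to one decimal.
    """
    for name, (r, cr, n) in counts.items():
        if not 0 <= cr <= r <= n:
            raise ValueError(
                f"{name}: need 0 <= complete_responders <= responders "
                f"<= evaluable, got ({r}, {cr}, {n})"
            )
    total_r = sum(r for r, _, _ in counts.values())
    total_cr = sum(cr for _, cr, _ in counts.values())
    total_n = sum(n for _, _, n in counts.values())
    if total_n == 0:
        raise ValueError("no evaluable patients")
    per_subtype = {
        name: {
            "orr": r / n if n else None,
            "crr": cr / n if n else None,
            "orr_pct": round(100 * r / n, 1) if n else None,
            "crr_pct": round(100 * cr / n, 1) if n else None,
            "evaluable": n,
        }
        for name, (r, cr, n) in counts.items()
    }
    return {
        "orr": total_r / total_n,
        "crr": total_cr / total_n,
        "orr_pct": round(100 * total_r / total_n, 1),
        "crr_pct": round(100 * total_cr / total_n, 1),
        "evaluable": total_n,
        "per_subtype": per_subtype,
    }


def read_response_counts(path) -> dict[str, tuple[int, int, int]]:
    """Read a response-count TSV (subtype, evaluable, responders,
    complete_responders) into the mapping pooled_response_rates expects."""
    df = pd.read_csv(path, sep="\t")
    required = {"subtype", "evaluable", "responders", "complete_responders"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"response-count table missing columns {sorted(missing)}")
    return {
        str(row.subtype): (int(row.responders), int(row.complete_responders),
                           int(row.evaluable))
        for row in df.itertuples()
    }
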