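"""Subtype assignment for alteration profiles and cohorts.

Thin profile-level wrappers over :class:`~lymphplex.estimator.LymphPlexClassifier`;
the cascade itself (TP53 priority, normalized-overlap argmax, EZB MYC split)
lives in :mod:`lymphplex.estimator`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .estimator import LymphPlexClassifier, cascade, subtype_scores_from_features
from .panel import (
    FBCL2,
    FBCL6,
    FMYC,
    LEGACY20_DEFINITIONS,
    LYMPHPLEX_DEFINITIONS,
    NOS,
    SubtypeDefinition,
)
from .records import SampleAlterationProfile


@dataclass(frozen=True)
class Assignment:
    """One sample's subtype call with scores and supporting evidence."""

    sample_id: str
    label: str
    scores: Mapping[str, float]
    evidence: tuple[str, ...]
    policy: str


def profile_features(p: SampleAlterationProfile) -> frozenset[str]:
    """Present features of a profile (mutated genes + positive fusions)."""
    feats = set(p.mutated_genes)
    if p.fbcl2:
        feats.add(FBCL2)
    if p.fbcl6:
        feats.add(FBCL6)
    return frozenset(feats)


def profiles_to_frame(
    profiles: Sequence[SampleAlterationProfile],
    feature_names: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Binary feature matrix (samples x features) from alteration profiles."""
    if feature_names is None:
        feature_names = LymphPlexClassifier().fit().feature_names_in_
    rows = {}
    for p in profiles:
        present = profile_features(p) | ({FMYC} if p.myc_rearranged else set())
        rows[p.sample_id] = {f: int(f in present) for f in feature_names}
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(feature_names)).fillna(0)


def subtype_scores(
    p: SampleAlterationProfile,
    definitions: Sequence[SubtypeDefinition] = LYMPHPLEX_DEFINITIONS,
) -> dict[str, float]:
    """Normalized-overlap score of each subtype for one profile."""
    return subtype_scores_from_features(profile_features(p), definitions)


def classify_sample(
    p: SampleAlterationProfile,
    definitions: Sequence[SubtypeDefinition] = LYMPHPLEX_DEFINITIONS,
    policy: str = "nos_on_tie",
    weights: Optional[Mapping[str, float]] = None,
    myc_split: bool = True,
) -> Assignment:
    """Assign one profile to a genetic subtype (or NOS)."""
    label, scores, evidence = cascade(
        profile_features(p), p.myc_rearranged, definitions,
        tie_break=policy, weights=weights, myc_split=myc_split,
    )
    return Assignment(p.sample_id, label, scores, evidence, policy)


def classify_legacy20(p: SampleAlterationProfile,
                      policy: str = "nos_on_tie") -> Assignment:
    """Assign under the legacy 20-gene scheme (no ST2, no MYC split)."""
    return classify_sample(p, definitions=LEGACY20_DEFINITIONS,
                           policy=policy, myc_split=False)


def classify_cohort(
    profiles: Iterable[SampleAlterationProfile],
    definitions: Sequence[SubtypeDefinition] = LYMPHPLEX_DEFINITIONS,
    policy: str = "nos_on_tie",
    weights: Optional[Mapping[str, float]] = None,
    myc_split: bool = True,
) -> tuple[list[Assignment], dict]:
    """Classify every profile and summarize label counts.

    Returns the assignments (sorted by sample_id, so the result is
    invariant to input order) and a summary dict with per-label counts and
    the classified fraction (non-NOS / total; ``None`` for an empty cohort).
    """
    profiles = sorted(profiles, key=lambda p: p.sample_id)
    seen: set[str] = set()
    for p in profiles:
        if p.sample_id in seen:
            raise ValueError(f"duplicate sample_id {p.sample_id!r} in cohort")
        seen.add(p.sample_id)

    assignments = [
        classify_sample(p, definitions, policy, weights, myc_split)
        for p in profiles
    ]
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.label] = counts.get(a.label, 0) + 1
    n = len(assignments)
    classified = n - counts.get(NOS, 0)
    summary = {
        "n": n,
        "counts": counts,
        "classified": classified,
        "classified_fraction": (classified / n) if n else None,
    }
    return assignments, summary


# ---------------------------------------------------------------------------
# Assignment table IO (TSV round-trips losslessly; JSON mirrors the TSV).

def assignments_to_frame(assignments: Sequence[Assignment]) -> pd.DataFrame:
    subtype_names = sorted({s for a in assignments for s in a.scores})
    rows = []
    for a in assignments:
        row = {"sample_id": a.sample_id, "label": a.label,
               "evidence": ";".join(a.evidence), "policy": a.policy}
        for s in subtype_names:
            row[f"score_{s}"] = a.scores.get(s, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def write_assignments(assignments: Sequence[Assignment],
                      path: str | Path, fmt: str = "tsv") -> None:
    df = assignments_to_frame(assignments)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        records = df.to_dict(orient="records")
        Path(path).write_text(json.dumps(records, indent=1) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_assignments(path: str | Path) -> list[Assignment]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    score_cols = [c for c in df.columns if c.startswith("score_")]
    out = []
    for _, row in df.iterrows():
        ev = row.get("evidence")
        evidence = tuple(str(ev).split(";")) if isinstance(ev, str) and ev else ()
        scores = {c[len("score_"):]: float(row[c]) for c in score_cols}
        out.append(Assignment(str(row["sample_id"]), str(row["label"]),
                              scores, evidence, str(row["policy"])))
    return out
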