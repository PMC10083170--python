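"""Cohort-level pipeline runners and human-readable report tables."""

from __future__ import annotations

import json
import logging
from collections import Counter
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .classify import (
    Assignment,
    assignments_to_frame,
    classify_cohort,
    classify_legacy20,
    write_assignments,
)
from .config import RunConfig, load_definitions
from .evaluate import cross_tabulate, per_class_metrics
from .ingest import build_profiles, read_fish_table, read_variant_table, \
    write_attrition_log
from .panel import LYMPHPLEX_DEFINITIONS

logger = logging.getLogger(__name__)


def run_classify(config: RunConfig, variants_path: str | Path,
                 fish_path: Optional[str | Path] = None,
                 dialect: str = "maf_tsv") -> dict:
    """End-to-end: read tables, filter, build profiles, classify, write.

    Writes ``assignments.tsv``/``assignments.json``, ``summary.tsv`` and
    ``attrition.tsv`` under ``config.out_dir``; returns the artifact paths
    and the cohort summary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    variants = read_variant_table(variants_path, dialect=dialect)
    fish = read_fish_table(fish_path) if fish_path else []
    attrition: Counter = Counter()
    profiles = build_profiles(
        variants, fish, config.thresholds.build(), config.mode,
        myd88_l265p_only=config.myd88_l265p_only, attrition=attrition,
    )

    definitions = (
        load_definitions(config.definitions_path)
        if config.definitions_path else LYMPHPLEX_DEFINITIONS
    )
    assignments, summary = classify_cohort(
        profiles, definitions, policy=config.policy)

    paths = {
        "assignments_tsv": out / "assignments.tsv",
        "assignments_json": out / "assignments.json",
        "summary": out / "summary.tsv",
        "attrition": out / "attrition.tsv",
    }
    if config.legacy20:
        # second assignment column under the 20-gene scheme
        legacy = {p.sample_id: classify_legacy20(p, config.policy).label
                  for p in profiles}
        df = assignments_to_frame(assignments)
        df.insert(2, "label_legacy20", df["sample_id"].map(legacy))
        df.to_csv(paths["assignments_tsv"], sep="\t", index=False)
        paths["assignments_json"].write_text(
            json.dumps(df.to_dict(orient="records"), indent=1) + "\n")
    else:
        write_assignments(assignments, paths["assignments_tsv"], fmt="tsv")
        write_assignments(assignments, paths["assignments_json"], fmt="json")
    write_attrition_log(attrition, paths["attrition"])

    frac = summary["classified_fraction"]
    with open(paths["summary"], "w") as fh:
        fh.write("label\tcount\n")
        for label in sorted(summary["counts"]):
            fh.write(f"{label}\t{summary['counts'][label]}\n")
        fh.write(f"__total__\t{summary['n']}\n")
        fh.write("__classified_fraction__\t"
                 f"{'NA' if frac is None else f'{frac:.4f}'}\n")
    return {"paths": paths, "summary": summary, "assignments": assignments}


def distribution_table(assignments: Sequence[Assignment]) -> pd.DataFrame:
    """Per-label counts and percentages (overall and of classified cases)."""
    if not assignments:
        raise ValueError("no assignments to report")
    counts = Counter(a.label for a in assignments)
    n = len(assignments)
    n_classified = n - counts.get("NOS", 0)
    rows = []
    for label in sorted(counts):
        c = counts[label]
        rows.append({
            "label": label,
            "count": c,
            "pct_of_total": round(100 * c / n, 1),
            "pct_of_classified": (
                round(100 * c / n_classified, 1)
                if label != "NOS" and n_classified else None),
        })
    return pd.DataFrame(rows)


def run_report(assignments: Sequence[Assignment],
               reference: Optional[Mapping[str, str]] = None,
               label_map: Optional[Mapping[str, str]] = None,
               exclude: Sequence[str] = ("TP53Mut", "A53"),
               out_dir: str | Path = ".") -> dict:
    """Write a distribution table and, given a reference labeling, a full
    benchmark (confusion, per-class metrics, Sankey long table, accuracy)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dist = distribution_table(assignments)
    paths = {"distribution": out / "distribution.tsv"}
    dist.to_csv(paths["distribution"], sep="\t", index=False)
    result: dict = {"paths": paths, "distribution": dist}

    if reference is not None:
        pred = {a.sample_id: a.label for a in assignments}
        summary = per_class_metrics(
            cross_tabulate(pred, dict(reference), label_map), exclude=exclude)
        metrics = pd.DataFrame(
            [{"subtype": c, **m} for c, m in summary.per_class.items()])
        n = sum(1 for s in pred)
        accuracy = sum(
            1 for s, l in pred.items()
            if (label_map or {}).get(l, l) == reference[s]) / n
        paths["confusion"] = out / "confusion.tsv"
        paths["metrics"] = out / "metrics.tsv"
        paths["sankey"] = out / "sankey_long.tsv"
        summary.confusion.to_csv(paths["confusion"], sep="\t")
        metrics.to_csv(paths["metrics"], sep="\t", index=False)
        summary.long_table.to_csv(paths["sankey"], sep="\t", index=False)
        (out / "benchmark.json").write_text(json.dumps({
            "accuracy": accuracy,
            "n_unique_agreed": summary.n_unique_agreed,
            "per_class": summary.per_class,
        }, indent=1) + "\n")
        paths["benchmark"] = out / "benchmark.json"
        result.update({"benchmark": summary, "accuracy": accuracy})
    return result


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a sample_id -> label mapping from a TSV with those columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    for need in ("sample_id",):
        if need not in cols:
            raise ValueError(f"label table {path} missing column {need!r}")
    label_col = cols.get("label") or cols.get("true_label")
    if label_col is None:
        raise ValueError(f"label table {path} needs a label/true_label column")
    pairs = list(zip(df[cols["sample_id"]], df[label_col]))
    dupes = [s for s, c in Counter(s for s, _ in pairs).items() if c > 1]
    if dupes:
        raise ValueError(f"duplicated sample_id in {path}: {sorted(dupes)}")
    return {str(s): str(l) for s, l in pairs}
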