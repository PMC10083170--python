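"""Synthetic DLBCL cohorts with known ground-truth genetic subtypes.

The generator emulates what the classifier consumes: per-sample somatic
variant calls (MAF-like TSV) and FISH rearrangement statuses, with each
classified sample carrying a few alterations planted from its subtype's
defining feature set, background passenger mutations, and — optionally —
filter-failing decoy variants that a correct ingest pipeline must remove.

What it does NOT emulate: mutational signatures, trinucleotide context,
clonal structure, copy number, or expression data.  Recovery of the
planted labels therefore demonstrates correctness of the filtering and
assignment logic, not performance on real tumors.

Default prevalences follow the training-cohort subtype distribution
(337 WES/WGS cases: 44 TP53Mut, 37 MCD-like, 39 BN2-like, 12 N1-like,
19 EZB-like of which 3 MYC+, 20 ST2-like, 166 NOS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .panel import (
    EZB,
    EZB_MYC_NEG,
    EZB_MYC_POS,
    FBCL2,
    FBCL6,
    LYMPHPLEX_DEFINITIONS,
    NOS,
    TP53MUT,
    definitions_by_name,
)

#: Training-cohort label counts out of 337 (EZB split by MYC rearrangement).
RUIJIN_COUNTS: Mapping[str, int] = {
    TP53MUT: 44, "MCD_like": 37, "BN2_like": 39, "N1_like": 12,
    EZB_MYC_POS: 3, EZB_MYC_NEG: 16, "ST2_like": 20, NOS: 166,
}

DEFAULT_PREVALENCE: Mapping[str, float] = {
    k: v / 337 for k, v in RUIJIN_COUNTS.items()
}

#: Off-panel genes used for passenger mutations in exclusive-background
#: mode (none belongs to any subtype-defining set).
OFFPANEL_GENES = ("KRAS", "BRAF", "ATM", "KLHL6", "HIST1H1E", "TMSB4X")

#: Per-subtype response counts (responders, complete responders, evaluable)
#: for the 48 patients treated with subtype-guided R-CHOP-X; transcribed
#: study input used by the pooled response-rate arithmetic.
RCHOP_X_RESPONSE_COUNTS: Mapping[str, tuple[int, int, int]] = {
    TP53MUT: (12, 10, 13),
    "MCD_like": (11, 10, 12),
    "BN2_like": (10, 9, 10),
    "N1_like": (1, 1, 1),
    "EZB_like": (1, 1, 1),
    "ST2_like": (1, 1, 1),
    NOS: (8, 8, 10),
}

_VARIANT_COLUMNS = (
    "sample_id", "gene", "variant_class", "protein_change", "vaf", "depth",
    "mapping_quality", "pop_af_max", "in_dbsnp", "in_cosmic", "sift",
    "polyphen2_hvar", "cadd",
)


@dataclass(frozen=True)
class GroundTruth:
    sample_id: str
    true_label: str
    planted_features: tuple[str, ...]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated cohort.

    ``prevalence`` must sum to 1; ``k_planted`` defining features are
    planted per classified sample (capped at the size of the subtype's
    defining set, so single-gene subtypes receive their one feature).
    ``background_rate`` is the per-gene probability of a passenger mutation
    in a panel gene outside the sample's own defining set (off-panel genes
    instead when ``exclusive_background``).  ``noise_fail_rate`` is the
    per-planted-variant probability of additionally emitting a
    filter-failing decoy variant that violates exactly one gate.
    """

    n_samples: int
    prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE))
    k_planted: int = 2
    background_rate: float = 0.02
    noise_fail_rate: float = 0.0
    fish_unknown_rate: float = 0.0
    exclusive_background: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be non-negative")
        if self.k_planted < 1:
            raise ValueError("k_planted must be >= 1")
        total = sum(self.prevalence.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"prevalence sums to {total}, expected 1")
        known = set(RUIJIN_COUNTS)
        unknown = set(self.prevalence) - known
        if unknown:
            raise ValueError(f"unknown labels in prevalence: {sorted(unknown)}")
        if not 0 <= self.background_rate <= 1:
            raise ValueError("background_rate must be in [0, 1]")
        if not 0 <= self.noise_fail_rate <= 1:
            raise ValueError("noise_fail_rate must be in [0, 1]")


def _defining_features(label: str) -> frozenset[str]:
    by_name = definitions_by_name(LYMPHPLEX_DEFINITIONS)
    if label in (EZB_MYC_POS, EZB_MYC_NEG):
        return by_name[EZB].features
    if label == NOS:
        return frozenset()
    return by_name[label].features


def _passing_variant(rng: np.random.Generator, sample_id: str,
                     gene: str) -> dict:
    """A variant row that passes every gate in both filter dialects."""
    classes = ("nonsynonymous_SNV", "stopgain", "frameshift_indel",
               "splicing", "nonframeshift_indel", "stoploss")
    vclass = classes[int(rng.choice(len(classes), p=(0.55, 0.15, 0.12,
                                                     0.08, 0.07, 0.03)))]
    protein_change = "L265P" if gene == "MYD88" else ""
    row = {
        "sample_id": sample_id,
        "gene": gene,
        "variant_class": vclass,
        "protein_change": protein_change,
        "vaf": round(float(rng.uniform(0.10, 0.60)), 4),
        "depth": int(rng.integers(50, 300)),
        "mapping_quality": 60.0,
        "pop_af_max": 0.0,
        "in_dbsnp": "false",
        "in_cosmic": "false",
        "sift": "",
        "polyphen2_hvar": "",
        "cadd": "",
    }
    if vclass == "nonsynonymous_SNV":
        # damaging scores so the targeted-panel missense gate also passes
        row["sift"] = round(float(rng.uniform(0.0, 0.04)), 4)
        row["polyphen2_hvar"] = round(float(rng.uniform(0.6, 1.0)), 4)
        row["cadd"] = round(float(rng.uniform(10.0, 30.0)), 2)
    return row


def _failing_variant(rng: np.random.Generator, sample_id: str,
                     gene: str) -> dict:
    """A decoy variant violating exactly one gate (low VAF or common AF)."""
    row = _passing_variant(rng, sample_id, gene)
    row["protein_change"] = ""
    if rng.random() < 0.5:
        row["vaf"] = round(float(rng.uniform(0.005, 0.045)), 4)
    else:
        row["pop_af_max"] = 0.01
    return row


def generate_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns (variant table, FISH table, truth table).

    The variant table is in the MAF-like TSV layout
    :func:`lymphplex.ingest.read_variant_table` reads; the FISH table uses
    pos/neg/NA tokens.  Reproducible: identical specs (including seed)
    yield identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    # Separate stream for decoy and FISH-unknown injection: turning noise
    # on or off must not perturb the planted structure, so that noisy and
    # clean cohorts with the same seed differ only by filter-failing rows.
    noise_rng = np.random.default_rng((spec.seed, 1))
    labels = sorted(spec.prevalence)
    probs = np.asarray([spec.prevalence[l] for l in labels], dtype=float)
    probs = probs / probs.sum()

    variant_rows: list[dict] = []
    fish_rows: list[dict] = []
    truth_rows: list[dict] = []
    width = max(4, len(str(max(spec.n_samples, 1))))

    for i in range(spec.n_samples):
        sid = f"S{i + 1:0{width}d}"
        label = labels[int(rng.choice(len(labels), p=probs))]
        defining = _defining_features(label)
        own_genes = defining - {FBCL2, FBCL6}

        k = min(spec.k_planted, len(defining))
        planted: list[str] = []
        if defining:
            order = sorted(defining)
            picks = rng.choice(len(order), size=k, replace=False)
            planted = [order[j] for j in sorted(picks)]

        fish = {"bcl2": "neg", "bcl6": "neg", "myc": "neg"}
        for feat in planted:
            if feat == FBCL2:
                fish["bcl2"] = "pos"
            elif feat == FBCL6:
                fish["bcl6"] = "pos"
            else:
                variant_rows.append(_passing_variant(rng, sid, feat))
                if noise_rng.random() < spec.noise_fail_rate:
                    decoys = sorted(
                        set(_all_panel_genes()) - own_genes - {"TP53"})
                    decoy = decoys[int(noise_rng.integers(len(decoys)))]
                    variant_rows.append(_failing_variant(noise_rng, sid, decoy))
        if label == EZB_MYC_POS:
            fish["myc"] = "pos"

        background = (
            OFFPANEL_GENES if spec.exclusive_background
            else sorted(set(_all_panel_genes()) - own_genes)
        )
        for gene in background:
            if rng.random() < spec.background_rate:
                variant_rows.append(_passing_variant(rng, sid, gene))

        if spec.fish_unknown_rate > 0:
            for key in ("bcl2", "bcl6", "myc"):
                if fish[key] == "neg" and noise_rng.random() < spec.fish_unknown_rate:
                    fish[key] = "NA"

        fish_rows.append({"sample_id": sid, **fish})
        truth_rows.append({
            "sample_id": sid,
            "true_label": label,
            "planted_features": ";".join(planted),
        })

    variants = pd.DataFrame(variant_rows, columns=_VARIANT_COLUMNS)
    fish = pd.DataFrame(fish_rows, columns=("sample_id", "bcl2", "bcl6", "myc"))
    truth = pd.DataFrame(
        truth_rows, columns=("sample_id", "true_label", "planted_features"))
    return variants, fish, truth


def _all_panel_genes() -> tuple[str, ...]:
    from .panel import MUTATION_PANEL

    return tuple(sorted(MUTATION_PANEL))


def write_cohort(spec: CohortSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate a cohort and write variants.maf.tsv / fish.tsv / truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    variants, fish, truth = generate_cohort(spec)
    paths = {
        "variants": out / "variants.maf.tsv",
        "fish": out / "fish.tsv",
        "truth": out / "truth.tsv",
    }
    variants.to_csv(paths["variants"], sep="\t", index=False)
    fish.to_csv(paths["fish"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_truth(path: str | Path) -> list[GroundTruth]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        GroundTruth(
            sample_id=row.sample_id,
            true_label=row.true_label,
            planted_features=tuple(
                f for f in row.planted_features.split(";") if f),
        )
        for row in df.itertuples()
    ]


def make_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Write small worked-example fixtures (all synthetic except the
    transcribed response-count table).

    Files: ``tp53_priority.maf.tsv``/``tp53_priority.fish.tsv`` (a TP53 +
    EZH2 + FBCL2 sample the priority rule must call TP53Mut),
    ``corrupt_row.maf.tsv`` (one unparseable VAF among three rows),
    ``fish_only.fish.tsv`` (a FISH-only BCL6+ sample and an empty-profile
    sample), ``confusion_2class.tsv`` (a hand-built 2-class labeling pair),
    and ``response_counts.tsv`` (the 48-patient R-CHOP-X counts).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def maf_row(sid: str, gene: str, vclass: str = "nonsynonymous_SNV",
                vaf: str = "0.35", depth: str = "120", mq: str = "60",
                **extra: str) -> str:
        vals = {"sample_id": sid, "gene": gene, "variant_class": vclass,
                "protein_change": "", "vaf": vaf, "depth": depth,
                "mapping_quality": mq, "pop_af_max": "0", "in_dbsnp": "false",
                "in_cosmic": "false", "sift": "0.01",
                "polyphen2_hvar": "0.9", "cadd": "20"}
        vals.update(extra)
        return "\t".join(vals[c] for c in _VARIANT_COLUMNS)

    header = "\t".join(_VARIANT_COLUMNS)

    paths["tp53_priority_maf"] = out / "tp53_priority.maf.tsv"
    paths["tp53_priority_maf"].write_text("\n".join([
        header,
        maf_row("P1", "TP53"),
        maf_row("P1", "EZH2"),
    ]) + "\n")
    paths["tp53_priority_fish"] = out / "tp53_priority.fish.tsv"
    paths["tp53_priority_fish"].write_text(
        "sample_id\tbcl2\tbcl6\tmyc\nP1\tpos\tneg\tneg\n")

    paths["corrupt_row"] = out / "corrupt_row.maf.tsv"
    paths["corrupt_row"].write_text("\n".join([
        header,
        maf_row("C1", "MYD88", protein_change="L265P"),
        maf_row("C2", "NOTCH1", vaf="NA"),
        maf_row("C3", "SGK1"),
    ]) + "\n")

    paths["fish_only"] = out / "fish_only.fish.tsv"
    paths["fish_only"].write_text(
        "sample_id\tbcl2\tbcl6\tmyc\nF1\tneg\tpos\tneg\nF2\tneg\tneg\tNA\n")

    paths["confusion_2class"] = out / "confusion_2class.tsv"
    lines = ["sample_id\tpred\tref"]
    n = 0
    for pred, ref, count in (("A", "A", 8), ("A", "B", 2),
                             ("B", "A", 1), ("B", "B", 9)):
        for _ in range(count):
            n += 1
            lines.append(f"X{n:02d}\t{pred}\t{ref}")
    paths["confusion_2class"].write_text("\n".join(lines) + "\n")

    paths["response_counts"] = out / "response_counts.tsv"
    lines = ["subtype\tevaluable\tresponders\tcomplete_responders"]
    for name, (r, cr, ev) in RCHOP_X_RESPONSE_COUNTS.items():
        lines.append(f"{name}\t{ev}\t{r}\t{cr}")
    paths["response_counts"].write_text("\n".join(lines) + "\n")
    return paths
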