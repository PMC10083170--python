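"""Read variant and FISH tables and build per-sample alteration profiles.

The filters implemented here are *post-annotation* qualification gates over
a tabular input: read alignment, somatic calling and consequence annotation
happen upstream.  Two filter dialects exist, matching how the two cohort
types were sequenced:

``wes_wgs``
    mapping quality > 30; population AF < 0.001; VAF > 5% AND depth > 10;
    dbSNP sites must also be in COSMIC; functional consequence classes only.

``targeted``
    mapping quality > 30; population AF < 0.001; VAF >= 5%; dbSNP sites must
    also be in COSMIC; functional classes only; missense (nonsynonymous SNV)
    variants must additionally satisfy SIFT <= 0.05 AND PolyPhen2_HVAR >=
    0.447 AND CADD > 4.

The VAF boundary differs on purpose between the two dialects (strict ">" in
WES/WGS, ">=" in targeted).  A missing population AF is treated as a pass
(a novel variant); missing SIFT/PolyPhen/CADD scores in the targeted
missense gate fail closed by default (configurable).
"""

from __future__ import annotations

import csv
import logging
from collections import Counter, defaultdict
from pathlib import Path
from typing import Collection, Iterable, Mapping, Optional, Sequence

from .panel import MUTATION_PANEL
from .records import (
    FUNCTIONAL_CLASSES,
    FilterThresholds,
    FishRecord,
    FishStatus,
    SampleAlterationProfile,
    SequencingMode,
    VariantClass,
    VariantRecord,
)

logger = logging.getLogger(__name__)

REQUIRED_VARIANT_COLUMNS = (
    "sample_id", "gene", "variant_class", "vaf", "depth", "mapping_quality",
)
OPTIONAL_VARIANT_COLUMNS = (
    "protein_change", "pop_af_max", "in_dbsnp", "in_cosmic",
    "sift", "polyphen2_hvar", "cadd",
)

_MISSING_TOKENS = {"", "na", "nan", "none", ".", "null"}

# Accepted spellings of consequence classes (upstream annotators vary).
_CLASS_ALIASES: Mapping[str, VariantClass] = {
    "nonsynonymous_snv": VariantClass.NONSYNONYMOUS_SNV,
    "nonsynonymous snv": VariantClass.NONSYNONYMOUS_SNV,
    "missense": VariantClass.NONSYNONYMOUS_SNV,
    "missense_mutation": VariantClass.NONSYNONYMOUS_SNV,
    "stopgain": VariantClass.STOPGAIN,
    "nonsense_mutation": VariantClass.STOPGAIN,
    "stoploss": VariantClass.STOPLOSS,
    "frameshift_indel": VariantClass.FRAMESHIFT_INDEL,
    "frameshift": VariantClass.FRAMESHIFT_INDEL,
    "frame_shift_ins": VariantClass.FRAMESHIFT_INDEL,
    "frame_shift_del": VariantClass.FRAMESHIFT_INDEL,
    "nonframeshift_indel": VariantClass.NONFRAMESHIFT_INDEL,
    "nonframeshift": VariantClass.NONFRAMESHIFT_INDEL,
    "in_frame_ins": VariantClass.NONFRAMESHIFT_INDEL,
    "in_frame_del": VariantClass.NONFRAMESHIFT_INDEL,
    "splicing": VariantClass.SPLICING,
    "splice_site": VariantClass.SPLICING,
    "synonymous": VariantClass.SYNONYMOUS,
    "silent": VariantClass.SYNONYMOUS,
    "other": VariantClass.OTHER,
}

DEFAULT_FISH_TOKENS: Mapping[str, FishStatus] = {
    "pos": FishStatus.POSITIVE,
    "positive": FishStatus.POSITIVE,
    "+": FishStatus.POSITIVE,
    "1": FishStatus.POSITIVE,
    "neg": FishStatus.NEGATIVE,
    "negative": FishStatus.NEGATIVE,
    "-": FishStatus.NEGATIVE,
    "0": FishStatus.NEGATIVE,
    "na": FishStatus.UNKNOWN,
    "nan": FishStatus.UNKNOWN,
    "unknown": FishStatus.UNKNOWN,
    "": FishStatus.UNKNOWN,
    ".": FishStatus.UNKNOWN,
}


class TableFormatError(ValueError):
    """Raised when a required column or field is missing or malformed."""


def _parse_float(token: str, column: str) -> Optional[float]:
    tok = token.strip()
    if tok.lower() in _MISSING_TOKENS:
        return None
    try:
        return float(tok)
    except ValueError as exc:
        raise ValueError(f"unparseable numeric {token!r} in column {column!r}") from exc


def _parse_bool(token: str, column: str) -> Optional[bool]:
    tok = token.strip().lower()
    if tok in _MISSING_TOKENS:
        return None
    if tok in {"1", "true", "yes", "y", "t"}:
        return True
    if tok in {"0", "false", "no", "n", "f"}:
        return False
    raise ValueError(f"unparseable boolean {token!r} in column {column!r}")


def parse_variant_class(token: str) -> VariantClass:
    key = token.strip().lower()
    if key in _CLASS_ALIASES:
        return _CLASS_ALIASES[key]
    raise ValueError(f"unrecognized variant_class {token!r}")


def _record_from_row(row: Mapping[str, str]) -> VariantRecord:
    vaf = _parse_float(row["vaf"], "vaf")
    depth = _parse_float(row["depth"], "depth")
    mq = _parse_float(row["mapping_quality"], "mapping_quality")
    if vaf is None or depth is None or mq is None:
        missing = [c for c, v in (("vaf", vaf), ("depth", depth),
                                  ("mapping_quality", mq)) if v is None]
        raise ValueError(f"missing required numeric value(s) {missing}")

    def opt(col: str) -> str:
        return row.get(col, "") or ""

    protein_change = opt("protein_change").strip() or None
    return VariantRecord(
        sample_id=row["sample_id"].strip(),
        gene=row["gene"].strip().upper(),
        variant_class=parse_variant_class(row["variant_class"]),
        vaf=vaf,
        depth=int(depth),
        mapping_quality=mq,
        protein_change=protein_change,
        pop_af_max=_parse_float(opt("pop_af_max"), "pop_af_max"),
        in_dbsnp=_parse_bool(opt("in_dbsnp"), "in_dbsnp"),
        in_cosmic=_parse_bool(opt("in_cosmic"), "in_cosmic"),
        sift=_parse_float(opt("sift"), "sift"),
        polyphen2_hvar=_parse_float(opt("polyphen2_hvar"), "polyphen2_hvar"),
        cadd=_parse_float(opt("cadd"), "cadd"),
    )


def read_variant_table(path: str | Path, dialect: str = "maf_tsv",
                       field_map: Optional[Mapping[str, str]] = None,
                       ) -> list[VariantRecord]:
    """Read an annotated somatic-variant table.

    Parameters
    ----------
    path
        Input file. ``maf_tsv`` expects a tab-separated table with one row
        per variant per sample and the columns listed in
        :data:`REQUIRED_VARIANT_COLUMNS`; ``vcf`` expects a VCF whose INFO
        fields are mapped to record fields via ``field_map``.
    dialect
        ``"maf_tsv"`` or ``"vcf"``.
    field_map
        VCF dialect only: maps record field names (``gene``,
        ``variant_class``, ...) to INFO keys.

    Rows with unparseable numerics are skipped with a logged warning;
    a missing required column is a hard :class:`TableFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "maf_tsv":
        return _read_maf_tsv(path)
    if dialect == "vcf":
        return _read_vcf(path, field_map or {})
    raise ValueError(f"unknown dialect {dialect!r}; expected 'maf_tsv' or 'vcf'")


def _read_maf_tsv(path: Path) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = [h.strip().lower() for h in (reader.fieldnames or [])]
        for col in REQUIRED_VARIANT_COLUMNS:
            if col not in header:
                raise TableFormatError(
                    f"variant table {path} is missing required column {col!r}"
                )
        for lineno, raw in enumerate(reader, start=2):
            row = {(k or "").strip().lower(): (v or "") for k, v in raw.items()}
            try:
                records.append(_record_from_row(row))
            except ValueError as exc:
                logger.warning("skipping %s line %d: %s", path.name, lineno, exc)
    return records


# Default mapping of record fields to VCF INFO keys.
DEFAULT_VCF_FIELD_MAP: Mapping[str, str] = {
    "gene": "GENE",
    "variant_class": "VARIANT_CLASS",
    "vaf": "VAF",
    "depth": "DP",
    "mapping_quality": "MQ",
    "protein_change": "AA_CHANGE",
    "pop_af_max": "POP_AF_MAX",
    "in_dbsnp": "IN_DBSNP",
    "in_cosmic": "IN_COSMIC",
    "sift": "SIFT",
    "polyphen2_hvar": "POLYPHEN2_HVAR",
    "cadd": "CADD",
}


def _read_vcf(path: Path, field_map: Mapping[str, str]) -> list[VariantRecord]:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - cyvcf2 is an extra
        raise ImportError("the VCF dialect requires cyvcf2") from exc

    fmap = dict(DEFAULT_VCF_FIELD_MAP)
    fmap.update(field_map)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for idx, variant in enumerate(vcf):
        def info(field: str) -> str:
            val = variant.INFO.get(fmap[field])
            return "" if val is None else str(val)

        carriers = (
            [samples[i] for i, gt in enumerate(variant.gt_types) if gt in (1, 3)]
            if samples else [info("gene") and "SAMPLE" or "SAMPLE"]
        )
        for sid in carriers:
            row = {
                "sample_id": sid,
                "gene": info("gene"),
                "variant_class": info("variant_class"),
                "vaf": info("vaf"),
                "depth": info("depth"),
                "mapping_quality": info("mapping_quality"),
                "protein_change": info("protein_change"),
                "pop_af_max": info("pop_af_max"),
                "in_dbsnp": info("in_dbsnp"),
                "in_cosmic": info("in_cosmic"),
                "sift": info("sift"),
                "polyphen2_hvar": info("polyphen2_hvar"),
                "cadd": info("cadd"),
            }
            try:
                records.append(_record_from_row(row))
            except ValueError as exc:
                logger.warning("skipping VCF record %d (%s): %s", idx, sid, exc)
    return records


def failed_gates(v: VariantRecord, t: FilterThresholds,
                 mode: SequencingMode | str) -> tuple[str, ...]:
    """Names of the qualification gates this variant fails (empty = passes).

    Gate names: ``consequence_class``, ``mapping_quality``, ``pop_af``,
    ``vaf``, ``depth``, ``dbsnp_cosmic``, ``missense_scores``.
    """
    mode = SequencingMode(mode)
    failures: list[str] = []
    if v.variant_class not in FUNCTIONAL_CLASSES:
        failures.append("consequence_class")
    if not v.mapping_quality > t.min_mapping_quality:
        failures.append("mapping_quality")
    if v.pop_af_max is not None and not v.pop_af_max < t.max_pop_af:
        failures.append("pop_af")
    if mode is SequencingMode.WES_WGS:
        if not v.vaf > t.min_vaf:
            failures.append("vaf")
        if not v.depth > t.min_depth:
            failures.append("depth")
    else:
        if not v.vaf >= t.min_vaf:
            failures.append("vaf")
    if t.dbsnp_requires_cosmic and v.in_dbsnp and not v.in_cosmic:
        failures.append("dbsnp_cosmic")
    if (mode is SequencingMode.TARGETED
            and v.variant_class is VariantClass.NONSYNONYMOUS_SNV):
        scores = (v.sift, v.polyphen2_hvar, v.cadd)
        if any(s is None for s in scores):
            if not t.missense_scores_fail_open:
                failures.append("missense_scores")
        elif not (v.sift <= t.max_sift
                  and v.polyphen2_hvar >= t.min_polyphen
                  and v.cadd > t.min_cadd):
            failures.append("missense_scores")
    return tuple(failures)


def qualify_variant(v: VariantRecord, t: FilterThresholds,
                    mode: SequencingMode | str) -> bool:
    """True iff the variant passes every applicable qualification gate."""
    return not failed_gates(v, t, mode)


def read_fish_table(path: str | Path,
                    tokens: Optional[Mapping[str, FishStatus]] = None,
                    ) -> list[FishRecord]:
    """Read a FISH rearrangement table (TSV: sample_id, bcl2, bcl6, myc).

    Status tokens default to pos/neg/NA spellings; a duplicated sample_id or
    an unrecognized token is a hard error.  Unknown never counts as positive.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    token_map = {k.lower(): v for k, v in (tokens or DEFAULT_FISH_TOKENS).items()}

    records: list[FishRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = [h.strip().lower() for h in (reader.fieldnames or [])]
        for col in ("sample_id", "bcl2", "bcl6", "myc"):
            if col not in header:
                raise TableFormatError(
                    f"FISH table {path} is missing required column {col!r}"
                )

        def status(row: Mapping[str, str], col: str) -> FishStatus:
            tok = (row.get(col) or "").strip().lower()
            if tok not in token_map:
                raise TableFormatError(
                    f"unrecognized FISH status token {row.get(col)!r} "
                    f"in column {col!r}"
                )
            return token_map[tok]

        for raw in reader:
            row = {(k or "").strip().lower(): (v or "") for k, v in raw.items()}
            records.append(FishRecord(
                sample_id=row["sample_id"].strip(),
                bcl2_rearranged=status(row, "bcl2"),
                bcl6_rearranged=status(row, "bcl6"),
                myc_rearranged=status(row, "myc"),
            ))

    counts = Counter(r.sample_id for r in records)
    dupes = sorted(s for s, c in counts.items() if c > 1)
    if dupes:
        raise TableFormatError(f"duplicated sample_id in FISH table: {dupes}")
    return records


def build_profiles(
    variants: Iterable[VariantRecord],
    fish: Iterable[FishRecord],
    thresholds: Optional[FilterThresholds] = None,
    mode: SequencingMode | str = SequencingMode.WES_WGS,
    *,
    myd88_l265p_only: bool = False,
    variant_blocklist: Optional[Collection[tuple[str, str, Optional[str]]]] = None,
    gene_blocklist: Optional[Collection[str]] = None,
    attrition: Optional[Counter] = None,
) -> list[SampleAlterationProfile]:
    """Binarize qualifying variants and FISH calls into per-sample profiles.

    One profile is produced per sample appearing in either input.  A gene
    enters ``mutated_genes`` iff at least one of its variants qualifies
    under ``thresholds``/``mode``; qualifying genes outside the 35-gene
    panel are diverted to ``extra_panel_hits`` with a logged warning.
    Rearrangement booleans are true iff the FISH status is positive
    (unknown counts as negative).

    ``variant_blocklist`` holds ``(sample_id, gene, protein_change)``
    triples to drop (``protein_change`` None matches any), and
    ``gene_blocklist`` drops whole genes — hooks for cohort-level exclusion
    of recurrent artifacts or Sanger-confirmed germline calls.  With
    ``myd88_l265p_only``, only MYD88 p.L265P variants count toward MYD88.
    Pass a ``Counter`` as ``attrition`` to collect per-gate failure counts.

    Output order is sorted by sample_id, so profiles are invariant to the
    row order of the inputs.
    """
    t = thresholds or FilterThresholds()
    mode = SequencingMode(mode)
    blocked = set(variant_blocklist or ())
    blocked_genes = {g.upper() for g in (gene_blocklist or ())}

    mutated: dict[str, set[str]] = defaultdict(set)
    extra: dict[str, set[str]] = defaultdict(set)
    sample_ids: set[str] = set()

    for v in variants:
        sample_ids.add(v.sample_id)
        if v.gene in blocked_genes:
            continue
        if ((v.sample_id, v.gene, v.protein_change) in blocked
                or (v.sample_id, v.gene, None) in blocked):
            continue
        gates = failed_gates(v, t, mode)
        if attrition is not None:
            attrition["total"] += 1
            for g in gates:
                attrition[g] += 1
            if not gates:
                attrition["qualified"] += 1
        if gates:
            continue
        if v.gene == "MYD88" and myd88_l265p_only:
            pc = (v.protein_change or "").lstrip("p.").upper()
            if pc != "L265P":
                continue
        if v.gene in MUTATION_PANEL:
            mutated[v.sample_id].add(v.gene)
        else:
            extra[v.sample_id].add(v.gene)
            logger.warning(
                "sample %s: qualifying variant in off-panel gene %s "
                "(recorded in extra_panel_hits only)", v.sample_id, v.gene,
            )

    fish_by_sample: dict[str, FishRecord] = {}
    for f in fish:
        if f.sample_id in fish_by_sample:
            raise TableFormatError(f"duplicated FISH sample {f.sample_id!r}")
        fish_by_sample[f.sample_id] = f
        sample_ids.add(f.sample_id)

    profiles = []
    for sid in sorted(sample_ids):
        f = fish_by_sample.get(sid)
        profiles.append(SampleAlterationProfile(
            sample_id=sid,
            mutated_genes=frozenset(mutated.get(sid, ())),
            fbcl2=bool(f and f.bcl2_rearranged is FishStatus.POSITIVE),
            fbcl6=bool(f and f.bcl6_rearranged is FishStatus.POSITIVE),
            myc_rearranged=bool(f and f.myc_rearranged is FishStatus.POSITIVE),
            extra_panel_hits=frozenset(extra.get(sid, ())),
        ))
    return profiles


def write_attrition_log(attrition: Counter, path: str | Path) -> None:
    """Write per-gate failure counts as a two-column TSV."""
    with open(path, "w") as fh:
        fh.write("gate\tcount\n")
        for gate in sorted(attrition):
            fh.write(f"{gate}\t{attrition[gate]}\n")
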