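"""Variant/FISH readers, qualification gates, and profile construction."""

import dataclasses
import random
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lymphplex.ingest import (
    TableFormatError,
    build_profiles,
    failed_gates,
    qualify_variant,
    read_fish_table,
    read_variant_table,
    write_attrition_log,
)
from lymphplex.panel import MUTATION_PANEL
from lymphplex.records import (
    FilterThresholds,
    FishRecord,
    FishStatus,
    SequencingMode,
    VariantClass,
    VariantRecord,
)

T = FilterThresholds()

VARIANT_HEADER = (
    "sample_id\tgene\tvariant_class\tvaf\tdepth\tmapping_quality\t"
    "pop_af_max\tin_dbsnp\tin_cosmic\tsift\tpolyphen2_hvar\tcadd\t"
    "protein_change"
)


def passing_variant(**overrides) -> VariantRecord:
    base = dict(
        sample_id="s1", gene="MYD88",
        variant_class=VariantClass.NONSYNONYMOUS_SNV,
        vaf=0.30, depth=100, mapping_quality=60.0,
        pop_af_max=0.0, in_dbsnp=False, in_cosmic=False,
        sift=0.01, polyphen2_hvar=0.9, cadd=20.0,
        protein_change="L265P",
    )
    base.update(overrides)
    return VariantRecord(**base)


# ---------------------------------------------------------------- readers

def test_reads_well_formed_table(tmp_path):
    path = tmp_path / "v.tsv"
    rows = [
        "s1\tMYD88\tnonsynonymous_SNV\t0.3\t100\t60\t0\tfalse\tfalse\t0.01\t0.9\t20\tL265P",
        "s1\tCD79B\tstopgain\t0.2\t80\t55\t\t\t\t\t\t\t",
        "s2\tTP53\tframeshift_indel\t0.4\t120\t60\t0\t\t\t\t\t\t",
    ]
    path.write_text(VARIANT_HEADER + "\n" + "\n".join(rows) + "\n")
    recs = read_variant_table(path)
    assert len(recs) == 3
    assert recs[0].gene == "MYD88" and recs[0].protein_change == "L265P"
    assert recs[1].pop_af_max is None and recs[1].in_dbsnp is None


def test_gene_symbols_uppercased_and_trimmed(tmp_path):
    path = tmp_path / "v.tsv"
    path.write_text(
        VARIANT_HEADER + "\n"
        "s1\t myd88 \tmissense\t0.3\t100\t60\t\t\t\t\t\t\t\n")
    recs = read_variant_table(path)
    assert recs[0].gene == "MYD88"
    assert recs[0].variant_class is VariantClass.NONSYNONYMOUS_SNV


def test_missing_required_column_names_it(tmp_path):
    path = tmp_path / "v.tsv"
    path.write_text("sample_id\tgene\tvariant_class\tdepth\tmapping_quality\n")
    with pytest.raises(TableFormatError, match="vaf"):
        read_variant_table(path)


def test_corrupt_row_skipped_with_warning(tmp_path, caplog):
    path = tmp_path / "v.tsv"
    rows = [
        "s1\tMYD88\tmissense\t0.3\t100\t60\t\t\t\t\t\t\t",
        "s2\tNOTCH1\tmissense\tNA\t100\t60\t\t\t\t\t\t\t",
        "s3\tSGK1\tmissense\t0.2\t90\t60\t\t\t\t\t\t\t",
    ]
    path.write_text(VARIANT_HEADER + "\n" + "\n".join(rows) + "\n")
    with caplog.at_level("WARNING", logger="lymphplex.ingest"):
        recs = read_variant_table(path)
    assert len(recs) == 2
    assert any("skipping" in r.message for r in caplog.records)


def test_fish_reader_statuses(tmp_path):
    path = tmp_path / "f.tsv"
    path.write_text(
        "sample_id\tbcl2\tbcl6\tmyc\n"
        "a\tneg\tneg\tpos\n"
        "b\tneg\tNA\tneg\n")
    recs = read_fish_table(path)
    assert len(recs) == 2
    assert sum(r.myc_rearranged is FishStatus.POSITIVE for r in recs) == 1
    assert recs[1].bcl6_rearranged is FishStatus.UNKNOWN


def test_fish_duplicate_sample_is_error(tmp_path):
    path = tmp_path / "f.tsv"
    path.write_text(
        "sample_id\tbcl2\tbcl6\tmyc\na\tneg\tneg\tneg\na\tpos\tneg\tneg\n")
    with pytest.raises(TableFormatError, match="a"):
        read_fish_table(path)


def test_fish_unrecognized_token_is_error(tmp_path):
    path = tmp_path / "f.tsv"
    path.write_text("sample_id\tbcl2\tbcl6\tmyc\na\tmaybe\tneg\tneg\n")
    with pytest.raises(TableFormatError, match="maybe"):
        read_fish_table(path)


# --------------------------------------------------------- qualification

def test_clean_variant_qualifies_in_both_modes():
    v = passing_variant()
    assert qualify_variant(v, T, "wes_wgs")
    assert qualify_variant(v, T, "targeted")


@pytest.mark.parametrize(
    "mode,overrides,gate",
    [
        # mapping quality > 30 (both modes)
        ("wes_wgs", {"mapping_quality": 30.0}, "mapping_quality"),
        ("targeted", {"mapping_quality": 30.0}, "mapping_quality"),
        # population AF < 0.001
        ("wes_wgs", {"pop_af_max": 0.001}, "pop_af"),
        # WES/WGS: VAF strictly > 5% and depth strictly > 10
        ("wes_wgs", {"vaf": 0.05}, "vaf"),
        ("wes_wgs", {"vaf": 0.04}, "vaf"),
        ("wes_wgs", {"depth": 10}, "depth"),
        # targeted: VAF >= 5%
        ("targeted", {"vaf": 0.049}, "vaf"),
        # dbSNP sites must be in COSMIC
        ("wes_wgs", {"in_dbsnp": True, "in_cosmic": False}, "dbsnp_cosmic"),
        # targeted missense gate
        ("targeted", {"sift": 0.20}, "missense_scores"),
        ("targeted", {"sift": 0.051}, "missense_scores"),
        ("targeted", {"polyphen2_hvar": 0.446}, "missense_scores"),
        ("targeted", {"cadd": 4.0}, "missense_scores"),
        # consequence classes
        ("wes_wgs", {"variant_class": VariantClass.SYNONYMOUS},
         "consequence_class"),
        ("targeted", {"variant_class": VariantClass.OTHER},
         "consequence_class"),
    ],
)
def test_single_gate_failures(mode, overrides, gate):
    v = passing_variant(**overrides)
    assert not qualify_variant(v, T, mode)
    assert failed_gates(v, T, mode) == (gate,)


@pytest.mark.parametrize(
    "mode,overrides",
    [
        ("wes_wgs", {"mapping_quality": 30.1}),
        ("wes_wgs", {"pop_af_max": 0.0009}),
        ("wes_wgs", {"vaf": 0.051, "depth": 11}),
        ("targeted", {"vaf": 0.05}),
        ("targeted", {"sift": 0.05, "polyphen2_hvar": 0.447, "cadd": 4.01}),
        ("wes_wgs", {"in_dbsnp": True, "in_cosmic": True}),
        ("wes_wgs", {"pop_af_max": None}),  # absent population AF passes
    ],
)
def test_boundary_passes(mode, overrides):
    assert qualify_variant(passing_variant(**overrides), T, mode)


def test_missing_missense_scores_fail_closed_by_default():
    v = passing_variant(sift=None, polyphen2_hvar=None, cadd=None)
    assert not qualify_variant(v, T, "targeted")
    assert qualify_variant(v, T, "wes_wgs")  # gate is targeted-only
    open_t = dataclasses.replace(T, missense_scores_fail_open=True)
    assert qualify_variant(v, open_t, "targeted")


def test_missense_gate_spares_truncating_variants():
    v = passing_variant(variant_class=VariantClass.STOPGAIN,
                        sift=None, polyphen2_hvar=None, cadd=None)
    assert qualify_variant(v, T, "targeted")


def test_unknown_mode_is_error():
    with pytest.raises(ValueError):
        qualify_variant(passing_variant(), T, "panel")


# ------------------------------------------------------------- profiles

def test_gene_level_binarization():
    variants = [
        passing_variant(gene="MYD88"),
        passing_variant(gene="MYD88", vaf=0.2),
        passing_variant(gene="CD79B", vaf=0.04),  # fails VAF gate
    ]
    (p,) = build_profiles(variants, [], T, "wes_wgs")
    assert p.mutated_genes == {"MYD88"}


def test_fish_only_sample_gets_empty_profile():
    fish = [FishRecord("f1", bcl6_rearranged=FishStatus.POSITIVE)]
    (p,) = build_profiles([], fish, T, "wes_wgs")
    assert p.mutated_genes == frozenset() and p.fbcl6 and not p.fbcl2


def test_off_panel_gene_diverted_to_extra_hits():
    (p,) = build_profiles([passing_variant(gene="KRAS")], [], T, "wes_wgs")
    assert p.mutated_genes == frozenset()
    assert p.extra_panel_hits == {"KRAS"}


def test_unknown_fish_status_never_positive():
    fish = [FishRecord("s", myc_rearranged=FishStatus.UNKNOWN)]
    (p,) = build_profiles([], fish, T, "wes_wgs")
    assert not p.myc_rearranged


def test_myd88_l265p_restriction():
    variants = [passing_variant(gene="MYD88", protein_change="S219C")]
    (p,) = build_profiles(variants, [], T, "wes_wgs", myd88_l265p_only=True)
    assert p.mutated_genes == frozenset()
    variants = [passing_variant(gene="MYD88", protein_change="L265P")]
    (p,) = build_profiles(variants, [], T, "wes_wgs", myd88_l265p_only=True)
    assert p.mutated_genes == {"MYD88"}


def test_variant_and_gene_blocklists():
    variants = [passing_variant(gene="MYD88"), passing_variant(gene="TP53")]
    (p,) = build_profiles(
        variants, [], T, "wes_wgs",
        variant_blocklist={("s1", "TP53", None)})
    assert p.mutated_genes == {"MYD88"}
    (p,) = build_profiles(variants, [], T, "wes_wgs",
                          gene_blocklist={"MYD88"})
    assert p.mutated_genes == {"TP53"}


def test_attrition_log(tmp_path):
    attr = Counter()
    build_profiles(
        [passing_variant(), passing_variant(vaf=0.04)],
        [], T, "wes_wgs", attrition=attr)
    assert attr["total"] == 2 and attr["qualified"] == 1 and attr["vaf"] == 1
    out = tmp_path / "attrition.tsv"
    write_attrition_log(attr, out)
    assert "vaf\t1" in out.read_text()


def test_order_invariance():
    variants = [passing_variant(gene=g, sample_id=s)
                for g in ("MYD88", "TP53", "SGK1") for s in ("a", "b")]
    fwd = build_profiles(variants, [], T, "wes_wgs")
    rev = build_profiles(list(reversed(variants)), [], T, "wes_wgs")
    assert fwd == rev


@settings(derandomize=True, max_examples=50)
@given(
    vaf=st.floats(0.0, 1.0),
    depth=st.integers(0, 200),
    mq=st.floats(0, 100),
    pop_af=st.one_of(st.none(), st.floats(0, 0.01)),
)
def test_threshold_relaxation_is_monotone(vaf, depth, mq, pop_af):
    """Relaxing any gate can only let more variants through, never fewer."""
    v = passing_variant(vaf=vaf, depth=depth, mapping_quality=mq,
                        pop_af_max=pop_af)
    strict = FilterThresholds()
    relaxed = FilterThresholds(min_vaf=0.01, min_depth=5,
                               min_mapping_quality=20, max_pop_af=0.01)
    if qualify_variant(v, strict, "wes_wgs"):
        assert qualify_variant(v, relaxed, "wes_wgs")


def test_filtering_is_idempotent():
    """Re-filtering an already-qualified variant set changes nothing."""
    rng = random.Random(0)
    variants = [
        passing_variant(
            gene=rng.choice(sorted(MUTATION_PANEL)),
            sample_id=f"s{rng.randrange(5)}",
            vaf=rng.uniform(0.0, 0.5),
            depth=rng.randrange(0, 100),
        )
        for _ in range(60)
    ]
    qualified = [v for v in variants if qualify_variant(v, T, "wes_wgs")]
    requalified = [v for v in qualified if qualify_variant(v, T, "wes_wgs")]
    assert requalified == qualified
    assert build_profiles(qualified, [], T, "wes_wgs") == \
        build_profiles(variants, [], T, "wes_wgs")


def test_profiles_match_naive_per_variant_loop():
    """Brute-force oracle: build_profiles equals a literal per-variant loop."""
    rng = random.Random(42)
    genes = sorted(MUTATION_PANEL) + ["KRAS", "BRAF"]
    variants = [
        passing_variant(
            gene=rng.choice(genes),
            sample_id=f"s{rng.randrange(8)}",
            vaf=rng.uniform(0.0, 0.6),
            depth=rng.randrange(0, 150),
            mapping_quality=rng.uniform(10, 70),
        )
        for _ in range(50)
    ]
    expected_mut: dict[str, set] = {}
    expected_extra: dict[str, set] = {}
    for v in variants:
        expected_mut.setdefault(v.sample_id, set())
        if qualify_variant(v, T, "wes_wgs"):
            if v.gene in MUTATION_PANEL:
                expected_mut[v.sample_id].add(v.gene)
            else:
                expected_extra.setdefault(v.sample_id, set()).add(v.gene)
    profiles = build_profiles(variants, [], T, "wes_wgs")
    assert {p.sample_id for p in profiles} == set(expected_mut)
    for p in profiles:
        assert p.mutated_genes == frozenset(expected_mut[p.sample_id])
        assert p.extra_panel_hits == frozenset(
            expected_extra.get(p.sample_id, set()))
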