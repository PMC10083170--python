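"""Record types: annotated variants, FISH results, filter thresholds,
and per-sample binary alteration profiles."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import FrozenSet, Optional

from .panel import MUTATION_PANEL


class VariantClass(str, enum.Enum):
    """Functional consequence classes as annotated upstream.

    Only the six "functional" classes (everything except synonymous/other)
    can qualify a gene as altered.
    """

    NONSYNONYMOUS_SNV = "nonsynonymous_SNV"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    FRAMESHIFT_INDEL = "frameshift_indel"
    NONFRAMESHIFT_INDEL = "nonframeshift_indel"
    SPLICING = "splicing"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Classes retained by the qualification filters.
FUNCTIONAL_CLASSES: FrozenSet[VariantClass] = frozenset(
    {
        VariantClass.NONSYNONYMOUS_SNV,
        VariantClass.STOPGAIN,
        VariantClass.STOPLOSS,
        VariantClass.FRAMESHIFT_INDEL,
        VariantClass.NONFRAMESHIFT_INDEL,
        VariantClass.SPLICING,
    }
)


class SequencingMode(str, enum.Enum):
    """Which filter dialect applies to a cohort's variant calls."""

    WES_WGS = "wes_wgs"
    TARGETED = "targeted"


class FishStatus(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class VariantRecord:
    """One annotated somatic variant for one sample.

    Optional annotation fields are ``None`` when absent from the input.
    VAF and population allele frequencies are fractions in [0, 1].
    """

    sample_id: str
    gene: str
    variant_class: VariantClass
    vaf: float
    depth: int
    mapping_quality: float
    protein_change: Optional[str] = None
    pop_af_max: Optional[float] = None
    in_dbsnp: Optional[bool] = None
    in_cosmic: Optional[bool] = None
    sift: Optional[float] = None
    polyphen2_hvar: Optional[float] = None
    cadd: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf!r} not in [0, 1]")
        if self.depth < 0:
            raise ValueError(f"depth {self.depth!r} negative")
        if self.mapping_quality < 0:
            raise ValueError(f"mapping_quality {self.mapping_quality!r} negative")
        if self.pop_af_max is not None and not 0.0 <= self.pop_af_max <= 1.0:
            raise ValueError(f"pop_af_max {self.pop_af_max!r} not in [0, 1]")


@dataclass(frozen=True)
class FilterThresholds:
    """Post-annotation variant qualification thresholds.

    Defaults reproduce the published filter criteria: mapping quality > 30,
    population allele frequency < 0.001, VAF > 5% with read depth > 10 in
    WES/WGS mode, VAF >= 5% in targeted mode, and the targeted-panel
    missense gate SIFT <= 0.05 AND PolyPhen2_HVAR >= 0.447 AND CADD > 4.
    The comparison sense of each threshold is fixed; only the cut point is
    configurable.
    """

    min_mapping_quality: float = 30.0       # strict ">"
    max_pop_af: float = 0.001               # strict "<"
    min_vaf: float = 0.05                   # ">" in WES/WGS, ">=" in targeted
    min_depth: int = 10                     # strict ">", WES/WGS only
    max_sift: float = 0.05                  # "<=", targeted missense gate
    min_polyphen: float = 0.447             # ">=", targeted missense gate
    min_cadd: float = 4.0                   # ">",  targeted missense gate
    dbsnp_requires_cosmic: bool = True
    missense_scores_fail_open: bool = False  # absent SIFT/PolyPhen/CADD pass?

    def __post_init__(self) -> None:
        for name in ("min_mapping_quality", "max_pop_af", "min_vaf",
                     "max_sift", "min_polyphen", "min_cadd"):
            v = float(getattr(self, name))
            if v != v or v in (float("inf"), float("-inf")):
                raise ValueError(f"{name} must be finite")
        if not 0.0 <= self.max_pop_af <= 1.0:
            raise ValueError("max_pop_af must be a fraction in [0, 1]")
        if not 0.0 <= self.min_vaf <= 1.0:
            raise ValueError("min_vaf must be a fraction in [0, 1]")


@dataclass(frozen=True)
class FishRecord:
    """FISH rearrangement status of BCL2/BCL6/MYC for one sample.

    Unknown never counts as positive anywhere downstream.
    """

    sample_id: str
    bcl2_rearranged: FishStatus = FishStatus.UNKNOWN
    bcl6_rearranged: FishStatus = FishStatus.UNKNOWN
    myc_rearranged: FishStatus = FishStatus.UNKNOWN


@dataclass(frozen=True)
class SampleAlterationProfile:
    """Binary 38-feature view of one sample: which panel genes carry at
    least one qualifying mutation, plus the three rearrangement flags.

    ``extra_panel_hits`` records qualifying mutations in genes outside the
    35-gene panel; they are logged but never enter classification.
    """

    sample_id: str
    mutated_genes: FrozenSet[str] = field(default_factory=frozenset)
    fbcl2: bool = False
    fbcl6: bool = False
    myc_rearranged: bool = False
    extra_panel_hits: FrozenSet[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        off = self.mutated_genes - MUTATION_PANEL
        if off:
            raise ValueError(
                f"mutated_genes outside the 35-gene panel: {sorted(off)}"
            )
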