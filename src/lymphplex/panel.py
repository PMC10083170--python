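"""Gene panel and subtype definitions for LymphPlex genetic subtyping.

LymphPlex assigns newly diagnosed DLBCL tumors to one of seven genetic
subtypes (or NOS) from a 38-feature panel: the mutation status of 35
lymphoma-associated genes plus the FISH rearrangement status of *BCL2*,
*BCL6*, and *MYC*.  Each subtype is defined by a fixed set of features;
the sets are mutually disjoint, so a sample's evidence for one subtype
never counts toward another.

Rearrangement features are named ``FBCL2``/``FBCL6`` (fusion of BCL2/BCL6)
following the field's notation; ``FMYC`` denotes *MYC* rearrangement, which
is not a defining feature of any subtype but splits EZB-like winners into
MYC+ and MYC- halves.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import FrozenSet, Mapping

# Rearrangement feature symbols (FISH).
FBCL2 = "FBCL2"
FBCL6 = "FBCL6"
FMYC = "FMYC"

REARRANGEMENT_FEATURES: FrozenSet[str] = frozenset({FBCL2, FBCL6, FMYC})

#: The 35 mutation genes of the targeted lymphoma panel.
MUTATION_PANEL: FrozenSet[str] = frozenset(
    {
        "ARID1A", "B2M", "BTG1", "BTG2", "CCND3", "CD70", "CD79B", "CIITA",
        "CREBBP", "DDX3X", "DTX1", "DUSP2", "EP300", "EZH2", "FAS", "GNA13",
        "IRF4", "IRF8", "KMT2D", "MPEG1", "MYD88", "NOTCH1", "NOTCH2",
        "PIM1", "PRDM1", "SGK1", "SOCS1", "STAT3", "STAT6", "TBL1XR1",
        "TET2", "TNFAIP3", "TNFRSF14", "TP53", "ZFP36L1",
    }
)

#: Full binary feature space: 35 mutation genes + 3 rearrangements = 38.
FEATURE_SPACE: FrozenSet[str] = MUTATION_PANEL | REARRANGEMENT_FEATURES

# Assignable labels.
TP53MUT = "TP53Mut"
MCD = "MCD_like"
BN2 = "BN2_like"
N1 = "N1_like"
EZB = "EZB_like"
EZB_MYC_POS = "EZB_like_MYC_pos"
EZB_MYC_NEG = "EZB_like_MYC_neg"
ST2 = "ST2_like"
NOS = "NOS"

#: The seven assignable subtype labels (EZB split counted as two) plus NOS.
ASSIGNABLE_LABELS = (TP53MUT, MCD, BN2, N1, EZB_MYC_POS, EZB_MYC_NEG, ST2)
ALL_LABELS = ASSIGNABLE_LABELS + (NOS,)


@dataclass(frozen=True)
class SubtypeDefinition:
    """A subtype's defining feature set.

    ``mutation_genes`` are HGNC symbols from the mutation panel;
    ``rearrangement_features`` is a subset of {FBCL2, FBCL6}.
    """

    name: str
    mutation_genes: FrozenSet[str]
    rearrangement_features: FrozenSet[str] = field(default_factory=frozenset)

    @property
    def features(self) -> FrozenSet[str]:
        """All defining features (mutations plus rearrangements)."""
        return self.mutation_genes | self.rearrangement_features

    def __post_init__(self) -> None:
        extra = self.rearrangement_features - {FBCL2, FBCL6}
        if extra:
            raise ValueError(f"invalid rearrangement features: {sorted(extra)}")


#: Shipped LymphPlex definitions (38-gene algorithm).
LYMPHPLEX_DEFINITIONS: tuple[SubtypeDefinition, ...] = (
    SubtypeDefinition(TP53MUT, frozenset({"TP53"})),
    SubtypeDefinition(
        MCD,
        frozenset({"MYD88", "CD79B", "PIM1", "MPEG1", "BTG1", "TBL1XR1",
                   "PRDM1", "IRF4"}),
    ),
    SubtypeDefinition(
        BN2,
        frozenset({"NOTCH2", "CD70", "DTX1", "BTG2", "TNFAIP3", "CCND3"}),
        frozenset({FBCL6}),
    ),
    SubtypeDefinition(N1, frozenset({"NOTCH1"})),
    SubtypeDefinition(
        EZB,
        frozenset({"EZH2", "TNFRSF14", "KMT2D", "B2M", "FAS", "CREBBP",
                   "ARID1A", "EP300", "CIITA", "STAT6", "GNA13"}),
        frozenset({FBCL2}),
    ),
    SubtypeDefinition(
        ST2,
        frozenset({"SGK1", "TET2", "SOCS1", "DDX3X", "ZFP36L1", "DUSP2",
                   "STAT3", "IRF8"}),
    ),
)

#: Legacy 20-gene (GenClass-style) definitions: 18 mutation genes + 2
#: rearrangements, no ST2 subtype and no MYC split.
LEGACY20_DEFINITIONS: tuple[SubtypeDefinition, ...] = (
    SubtypeDefinition(TP53MUT, frozenset({"TP53"})),
    SubtypeDefinition(
        MCD,
        frozenset({"MYD88", "CD79B", "PIM1", "MPEG1", "BTG1", "TBL1XR1"}),
    ),
    SubtypeDefinition(
        BN2,
        frozenset({"NOTCH2", "TNFAIP3", "CD70", "DTX1"}),
        frozenset({FBCL6}),
    ),
    SubtypeDefinition(N1, frozenset({"NOTCH1"})),
    SubtypeDefinition(
        EZB,
        frozenset({"EZH2", "TNFRSF14", "CREBBP", "EP300", "MTOR", "STAT6"}),
        frozenset({FBCL2}),
    ),
)


def definition_gene_universe(
    defs: tuple[SubtypeDefinition, ...] = LYMPHPLEX_DEFINITIONS,
) -> FrozenSet[str]:
    """Union of all mutation genes across definitions."""
    out: set[str] = set()
    for d in defs:
        out |= d.mutation_genes
    return frozenset(out)


def definitions_checksum(
    defs: tuple[SubtypeDefinition, ...] = LYMPHPLEX_DEFINITIONS,
) -> str:
    """SHA-256 over a canonical JSON encoding of the definitions.

    Printed by ``lymphplex --version`` so that any override of the shipped
    gene sets is visible at a glance.
    """
    payload = [
        {
            "name": d.name,
            "mutation_genes": sorted(d.mutation_genes),
            "rearrangements": sorted(d.rearrangement_features),
        }
        for d in defs
    ]
    blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


def definitions_by_name(
    defs: tuple[SubtypeDefinition, ...],
) -> Mapping[str, SubtypeDefinition]:
    return {d.name: d for d in defs}
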