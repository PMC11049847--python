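"""Reference classifications from the maize drought-tolerance meta-QTL study.

The published maize drought meta-analysis that this package operationalizes
reported, from 83 meta-QTL on the IBM2 2008 Neighbors map, eight breeders'
MQTL (physical CI < 1 Mb, genetic CI < 4 cM, > 2 member QTL) and fourteen
MQTL verified by more than three GWAS marker-trait associations.  Those
identifier lists are reproduced here as a worked example for the core-MQTL
union logic; two loci satisfy both definitions, so the core set has 20
members.
"""
from __future__ import annotations

__all__ = [
    "MAIZE_DROUGHT_BREEDERS_MQTL",
    "MAIZE_DROUGHT_MTA_MQTL",
    "core_mqtl_ids",
]

#: Breeders' MQTL reported by the maize drought meta-QTL study.
MAIZE_DROUGHT_BREEDERS_MQTL: frozenset[str] = frozenset({
    "MQTL4_9", "MQTL5_6", "MQTL7_1", "MQTL8_2",
    "MQTL8_6", "MQTL8_7", "MQTL8_10", "MQTL9_8",
})

#: MQTL verified by more than three GWAS marker-trait associations.
MAIZE_DROUGHT_MTA_MQTL: frozenset[str] = frozenset({
    "MQTL1_3", "MQTL2_3", "MQTL2_5", "MQTL2_7", "MQTL2_10",
    "MQTL3_4", "MQTL4_9", "MQTL6_7", "MQTL7_1", "MQTL7_6",
    "MQTL8_8", "MQTL8_9", "MQTL9_9", "MQTL10_8",
})


def core_mqtl_ids(breeders: frozenset[str] = MAIZE_DROUGHT_BREEDERS_MQTL,
                  mta_mqtl: frozenset[str] = MAIZE_DROUGHT_MTA_MQTL
                  ) -> set[str]:
    """Core MQTL: the union of breeders' and MTA-verified MQTL."""
    return set(breeders) | set(mta_mqtl)
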