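"""Exclusion of variants present in reference site databases.

Mirrors the novelty step of exome prioritization: a candidate is dropped
if its exact (chrom, pos, ref, alt) key appears in any configured
database (dbSNP-like, HapMap-like, 1000 Genomes-like, personal-genome
site lists). Matching is allele-exact — a novel allele at a catalogued
position survives.
"""

from __future__ import annotations

from typing import List, Sequence

from .types import SiteSet, VariantRecord


def exclude_known(records: Sequence[VariantRecord],
                  dbs: Sequence[SiteSet]) -> List[VariantRecord]:
    """Remove records whose key is in any database; order preserved."""
    return [r for r in records if not any(r in db for db in dbs)]
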