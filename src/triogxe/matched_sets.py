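"""Construction of 1-case : 3-pseudo-control matched sets.

Given both parents' genotypes at a biallelic marker, Mendelian transmission
admits exactly four equally likely child genotypes (one allele from each
parent, each parental allele used once).  The observed affected child is the
case; the three genotypes it could have received but did not are its matched
pseudo-controls.  Maternal exposure is a property of the trio, so all four
members of a set share one exposure vector.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .trio_io import MISSING, TrioRecord

#: TRANSMISSIONS[f, m] is the canonical (descending) 4-multiset of child
#: dosages for parental dosages f, m.
TRANSMISSIONS = np.empty((3, 3, 4), dtype=np.int8)
for _f in range(3):
    for _m in range(3):
        _fa = [1] * _f + [0] * (2 - _f)
        _ma = [1] * _m + [0] * (2 - _m)
        _kids = sorted((a + b for a in _fa for b in _ma), reverse=True)
        TRANSMISSIONS[_f, _m] = _kids
del _f, _m, _fa, _ma, _kids


class SkipReason(enum.Enum):
    MISSING_GENOTYPE = "MISSING_GENOTYPE"
    MENDEL_INCONSISTENT = "MENDEL_INCONSISTENT"
    MISSING_EXPOSURE = "MISSING_EXPOSURE"


@dataclass
class MatchedSet:
    """Case plus three pseudo-controls at one SNP for one family.

    ``genotypes[0]`` is the observed case; indices 1..3 are the
    pseudo-controls in canonical (descending) order.  ``informative`` is
    False when all four genotypes coincide (both parents homozygous), in
    which case the set carries no likelihood information.
    """

    family_id: str
    snp_id: str
    genotypes: np.ndarray  # shape (4,), int8
    exposures: dict[str, int] = field(default_factory=dict)

    @property
    def informative(self) -> bool:
        g = self.genotypes
        return bool((g != g[0]).any())


def enumerate_transmissions(father_dosage: int, mother_dosage: int) -> np.ndarray:
    """The 4-multiset of Mendelian child dosages, sorted descending."""
    if father_dosage == MISSING or mother_dosage == MISSING:
        raise ValueError("set not constructible: missing parental genotype")
    return TRANSMISSIONS[father_dosage, mother_dosage].copy()


def build_matched_set(trio: TrioRecord, snp_index: int, snp_id: str,
                      exposure_names: tuple[str, ...] = ()) -> MatchedSet | SkipReason:
    """Build the matched set for one trio at one SNP, or say why not.

    Returns SkipReason.MISSING_GENOTYPE when any member's genotype is
    missing, MENDEL_INCONSISTENT when the child's genotype is impossible
    given the parents, and MISSING_EXPOSURE when any requested maternal
    exposure is unobserved.  Skips are per-SNP: the same trio may be usable
    at other markers or in models with fewer exposures.
    """
    f = int(trio.father[snp_index])
    m = int(trio.mother[snp_index])
    c = int(trio.child[snp_index])
    if MISSING in (f, m, c):
        return SkipReason.MISSING_GENOTYPE
    trans = TRANSMISSIONS[f, m]
    if c not in trans:
        return SkipReason.MENDEL_INCONSISTENT
    expos: dict[str, int] = {}
    for name in exposure_names:
        v = trio.exposures.get(name, MISSING)
        if v == MISSING:
            return SkipReason.MISSING_EXPOSURE
        expos[name] = int(v)
    # pseudo-controls = transmission multiset minus one instance of the case
    pseudo = list(trans)
    pseudo.remove(c)
    genotypes = np.array([c] + sorted(pseudo, reverse=True), dtype=np.int8)
    return MatchedSet(trio.family_id, snp_id, genotypes, expos)


def build_matched_sets(trios: list[TrioRecord], snp_index: int, snp_id: str,
                       exposure_names: tuple[str, ...] = ()
                       ) -> tuple[list[MatchedSet], dict[SkipReason, int]]:
    """Matched sets for every constructible trio plus skip-reason counts."""
    sets: list[MatchedSet] = []
    skipped: dict[SkipReason, int] = {r: 0 for r in SkipReason}
    for tr in trios:
        out = build_matched_set(tr, snp_index, snp_id, exposure_names)
        if isinstance(out, SkipReason):
            skipped[out] += 1
        else:
            sets.append(out)
    return sets, skipped


def sets_to_arrays(sets: list[MatchedSet], exposure_names: tuple[str, ...] = ()
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Stack matched sets into (n, 4) genotype and (n, k) exposure arrays."""
    n = len(sets)
    G = np.empty((n, 4), dtype=np.int8)
    E = np.empty((n, len(exposure_names)), dtype=np.int8)
    for i, s in enumerate(sets):
        G[i] = s.genotypes
        for j, name in enumerate(exposure_names):
            E[i, j] = s.exposures[name]
    return G, E
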