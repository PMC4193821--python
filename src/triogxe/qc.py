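"""Per-SNP quality control computed from parents' genotypes.

Four flags mirror standard trio-panel hygiene: minor allele frequency below
threshold, genotyping call rate below threshold, Mendelian error rate above
threshold, and departure from Hardy-Weinberg equilibrium among parents by an
exact test.  Pairs of markers in complete LD (r^2 = 1 from EM-estimated
haplotype frequencies) are de-duplicated, keeping the first by map order.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .matched_sets import TRANSMISSIONS
from .trio_io import MISSING, Marker, TrioRecord


class QCFlag(enum.Enum):
    LOW_MAF = "LOW_MAF"
    LOW_CALL = "LOW_CALL"
    HIGH_MENDEL = "HIGH_MENDEL"
    HWE_FAIL = "HWE_FAIL"
    LD_DUPLICATE = "LD_DUPLICATE"


class MendelStatus(enum.Enum):
    CONSISTENT = "CONSISTENT"
    INCONSISTENT = "INCONSISTENT"
    UNKNOWN = "UNKNOWN"


@dataclass
class QCThresholds:
    """QC cut-offs; ``hwe_alpha=None`` means 0.05 / number of markers."""

    maf_min: float = 0.01
    call_rate_min: float = 0.95
    mendel_max: float = 0.05
    hwe_alpha: float | None = None
    ld_r2_max: float = 1.0


@dataclass
class MarkerQC:
    snp_id: str
    maf: float
    call_rate: float
    mendel_error_rate: float
    hwe_p: float
    flags: set[QCFlag] = field(default_factory=set)
    ld_partner: str | None = None

    @property
    def passed(self) -> bool:
        return not self.flags


def auto_hwe_alpha(n_markers: int) -> float:
    """Panel-wide HWE threshold: 0.05 Bonferroni-divided by the marker count."""
    return 0.05 / max(1, n_markers)


def compute_maf(parental_dosages, allele_a: str = "a",
                allele_b: str = "b") -> tuple[float, str, bool]:
    """Minor allele frequency from parents' dosages of ``allele_a``.

    Returns ``(maf, minor_allele_label, flipped)``; ``flipped`` is True when
    the counted allele turned out to be the major one (frequency > 0.5), in
    which case callers should recode dosages as ``2 - d``.  A tie at 0.5 is
    broken to the lexicographically smaller allele label.  All-missing input
    yields ``(nan, allele_a, False)``.
    """
    d = np.asarray(parental_dosages)
    d = d[d != MISSING]
    if d.size == 0:
        return float("nan"), allele_a, False
    freq_a = float(d.sum()) / (2 * d.size)
    if freq_a > 0.5:
        return 1.0 - freq_a, allele_b, True
    if freq_a == 0.5:
        labels = sorted([allele_a, allele_b])
        return 0.5, labels[0], labels[0] != allele_a
    return freq_a, allele_a, False


def hwe_exact(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact Hardy-Weinberg test conditional on the allele counts.

    The p-value sums, over all heterozygote counts compatible with the fixed
    allele counts (same parity as the observed count), the probabilities of
    configurations no more probable than the observed one (two-sided
    "at least as extreme = at most as probable" rule, no mid-p correction).
    Monomorphic input gives p = 1.
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        raise ValueError("no genotypes")
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n_hom_major + n_het
    if n_minor > n_major:  # work with the rarer allele
        n_minor, n_major = n_major, n_minor
    if n_minor == 0:
        return 1.0
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_min = (n_minor - hets) // 2
    hom_maj = n - hom_min - hets
    logp = (gammaln(n + 1) - gammaln(hom_maj + 1) - gammaln(hets + 1)
            - gammaln(hom_min + 1) + hets * np.log(2.0)
            + gammaln(n_minor + 1) + gammaln(n_major + 1) - gammaln(2 * n + 1))
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def mendel_check(father: int, mother: int, child: int) -> MendelStatus:
    """Is the child's dosage possible given one transmitted allele per parent?"""
    if MISSING in (father, mother, child):
        return MendelStatus.UNKNOWN
    if child in TRANSMISSIONS[father, mother]:
        return MendelStatus.CONSISTENT
    return MendelStatus.INCONSISTENT


def ld_r2(dosages_snp1, dosages_snp2, max_iter: int = 200,
          tol: float = 1e-10) -> float:
    """Pairwise r^2 between two SNPs from EM haplotype-frequency estimates.

    Input dosages are parents only; individuals missing at either SNP are
    dropped (pairwise complete).  Monomorphic input returns 0.
    """
    g = np.asarray(dosages_snp1)
    h = np.asarray(dosages_snp2)
    keep = (g != MISSING) & (h != MISSING)
    g, h = g[keep], h[keep]
    n = g.size
    if n == 0:
        return 0.0
    counts = np.zeros((3, 3))
    for gi, hi in zip(g, h):
        counts[gi, hi] += 1
    n11 = counts[1, 1]  # double heterozygotes: phase-ambiguous
    base_ab = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]   # A-B
    base_aB = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]   # A-b
    base_ab2 = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]  # a-B
    base_ab3 = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]  # a-b
    p = np.full(4, 0.25)  # [AB, Ab, aB, ab]
    for _ in range(max_iter):
        denom = p[0] * p[3] + p[1] * p[2]
        w = 0.5 if denom == 0 else p[0] * p[3] / denom
        new = np.array([base_ab + w * n11, base_aB + (1 - w) * n11,
                        base_ab2 + (1 - w) * n11, base_ab3 + w * n11]) / (2 * n)
        if np.max(np.abs(new - p)) < tol:
            p = new
            break
        p = new
    pA = p[0] + p[1]
    pB = p[0] + p[2]
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        return 0.0
    d_stat = p[0] - pA * pB
    return float(min(1.0, d_stat * d_stat / denom))


def mendel_scan(trios: list[TrioRecord], snp_index: int) -> tuple[int, int]:
    """(inconsistent, checked) Mendelian counts for one SNP across trios."""
    bad = ok = 0
    for tr in trios:
        st = mendel_check(int(tr.father[snp_index]), int(tr.mother[snp_index]),
                          int(tr.child[snp_index]))
        if st is MendelStatus.INCONSISTENT:
            bad += 1
        elif st is MendelStatus.CONSISTENT:
            ok += 1
    return bad, bad + ok


def apply_qc(markers: list[Marker], trios: list[TrioRecord],
             thresholds: QCThresholds | None = None
             ) -> tuple[list[Marker], list[MarkerQC]]:
    """Flag markers, fix minor alleles, and blank Mendelian-inconsistent calls.

    Side effects on the inputs: dosages are recoded (and marker allele labels
    swapped) where the counted allele is actually the major one, and every
    Mendelian-inconsistent trio-SNP genotype is set to MISSING for all three
    members after the error rate has been counted.

    Returns the passing marker list (map order preserved) and the full
    per-marker QC table.
    """
    thr = thresholds or QCThresholds()
    alpha = thr.hwe_alpha if thr.hwe_alpha is not None else auto_hwe_alpha(len(markers))
    n_trios = len(trios)
    table: list[MarkerQC] = []
    inconsistent: list[list[int]] = []

    for j, mk in enumerate(markers):
        fathers = np.array([tr.father[j] for tr in trios])
        mothers = np.array([tr.mother[j] for tr in trios])
        children = np.array([tr.child[j] for tr in trios])
        everyone = np.concatenate([fathers, mothers, children])
        call_rate = float((everyone != MISSING).mean()) if n_trios else 0.0

        statuses = [mendel_check(int(fathers[i]), int(mothers[i]),
                                 int(children[i])) for i in range(n_trios)]
        bad_rows = [i for i, s in enumerate(statuses)
                    if s is MendelStatus.INCONSISTENT]
        checked = sum(s is not MendelStatus.UNKNOWN for s in statuses)
        mendel_rate = len(bad_rows) / checked if checked else 0.0
        inconsistent.append(bad_rows)

        parents = np.concatenate([fathers, mothers])
        maf, minor_label, flip = compute_maf(parents, mk.allele_minor,
                                             mk.allele_major)
        if flip:
            for tr in trios:
                for vec in (tr.father, tr.mother, tr.child):
                    if vec[j] != MISSING:
                        vec[j] = 2 - vec[j]
            mk.allele_minor, mk.allele_major = mk.allele_major, mk.allele_minor
            parents = np.concatenate([np.array([tr.father[j] for tr in trios]),
                                      np.array([tr.mother[j] for tr in trios])])

        obs = parents[parents != MISSING]
        if obs.size:
            n_het = int((obs == 1).sum())
            n_hom_minor = int((obs == 2).sum())
            n_hom_major = int((obs == 0).sum())
            hwe_p = hwe_exact(n_hom_major, n_het, n_hom_minor)
        else:
            hwe_p = float("nan")

        flags: set[QCFlag] = set()
        if not np.isfinite(maf) or obs.size == 0:
            flags.add(QCFlag.LOW_CALL)
        if np.isfinite(maf) and maf < thr.maf_min:
            flags.add(QCFlag.LOW_MAF)
        if call_rate < thr.call_rate_min:
            flags.add(QCFlag.LOW_CALL)
        if mendel_rate > thr.mendel_max:
            flags.add(QCFlag.HIGH_MENDEL)
        if np.isfinite(hwe_p) and hwe_p < alpha:
            flags.add(QCFlag.HWE_FAIL)
        table.append(MarkerQC(mk.snp_id, maf, call_rate, mendel_rate, hwe_p,
                              flags))

    # blank inconsistent trio-SNP genotypes after all rates are computed
    for j, bad_rows in enumerate(inconsistent):
        for i in bad_rows:
            trios[i].father[j] = MISSING
            trios[i].mother[j] = MISSING
            trios[i].child[j] = MISSING

    # r^2 = 1 de-duplication among otherwise-passing markers, map order first
    kept: list[int] = []
    parent_dos = {}
    for j, rec in enumerate(table):
        if rec.flags:
            continue
        parent_dos[j] = np.concatenate(
            [np.array([tr.father[j] for tr in trios]),
             np.array([tr.mother[j] for tr in trios])])
        partner = None
        for i in kept:
            if ld_r2(parent_dos[i], parent_dos[j]) >= thr.ld_r2_max - 1e-9:
                partner = i
                break
        if partner is None:
            kept.append(j)
        else:
            rec.flags.add(QCFlag.LD_DUPLICATE)
            rec.ld_partner = table[partner].snp_id

    passing = [markers[j] for j, rec in enumerate(table) if rec.passed]
    return passing, table


def qc_frame(table: list[MarkerQC]) -> pd.DataFrame:
    return pd.DataFrame([{
        "snp_id": r.snp_id, "maf": r.maf, "call_rate": r.call_rate,
        "mendel_error_rate": r.mendel_error_rate, "hwe_p": r.hwe_p,
        "flags": ",".join(sorted(f.value for f in r.flags)),
        "ld_partner": r.ld_partner or "", "passed": r.passed,
    } for r in table])
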