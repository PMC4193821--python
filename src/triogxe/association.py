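"""Per-SNP association analyses on case-parent trios.

The genotypic TDT (gTDT) fits the G-only conditional-logistic model on all
constructible matched sets; the joint test adds genotype-by-maternal-exposure
interaction terms and compares the full model to the empty one with a
likelihood-ratio test of 1 + k degrees of freedom.  Stratum odds ratios
contrast carriers against non-carriers within an exposure combination:
exp(c'beta) with c = copies * [1, E_1, ..., E_k].  The allelic TDT (a
McNemar-type count of transmitted vs untransmitted minor alleles from
heterozygous parents) and Bonferroni correction complete the toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm

from .clogit import (InestimableError, NoInformationError,
                     TrioConditionalLogit, TrioConditionalLogitResults, lrt)
from .matched_sets import SkipReason, build_matched_set, build_matched_sets, \
    sets_to_arrays
from .qc import MendelStatus, mendel_check
from .trio_io import MISSING, ResultRow, TrioRecord

Z95 = float(norm.ppf(0.975))


@dataclass
class StratumOR:
    """One-copy (or two-copy) odds ratio within an exposure stratum."""

    exposure_combo: dict[str, int]
    copies: int
    or_value: float
    ci_lo: float
    ci_hi: float
    wald_p: float
    n_trios: int = 0
    stratum_maf: float = float("nan")

    def label(self) -> str:
        if not self.exposure_combo:
            return "all"
        return ";".join(f"{k}={v}" for k, v in self.exposure_combo.items())


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value: min(1, m * p)."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def _fit_sets(sets, exposure_names=()):
    G, E = sets_to_arrays(sets, tuple(exposure_names))
    model = TrioConditionalLogit(G, E, tuple(exposure_names))
    return model.fit()


def gtdt(trios: list[TrioRecord], snp_index: int, snp_id: str,
         bonferroni_m: int = 1
         ) -> tuple[TrioConditionalLogitResults | None, list[ResultRow]]:
    """Genotypic TDT: G-only conditional logit over all constructible sets.

    Reports OR = exp(beta_g) with 95% CI and the 1-df Wald p; a SNP whose
    fit separates or carries no information yields a NaN row.
    """
    sets, _ = build_matched_sets(trios, snp_index, snp_id, ())
    try:
        res = _fit_sets(sets)
    except (InestimableError, NoInformationError):
        return None, [ResultRow(snp_id, "gTDT", term="G")]
    if res.separation or not res.converged:
        return res, [ResultRow(snp_id, "gTDT", term="G",
                               n_sets=res.n_sets_informative)]
    beta, se = float(res.params[0]), float(res.bse[0])
    _, _, p = res.wald_test(0)
    row = ResultRow(snp_id, "gTDT", term="G", beta=beta, se=se, wald_p=p,
                    bonferroni_p=bonferroni(p, bonferroni_m),
                    or_value=float(np.exp(beta)),
                    ci_lo=float(np.exp(beta - Z95 * se)),
                    ci_hi=float(np.exp(beta + Z95 * se)),
                    n_sets=res.n_sets_informative)
    return res, [row]


def joint_test(trios: list[TrioRecord], snp_index: int, snp_id: str,
               exposure_names: tuple[str, ...], bonferroni_m: int = 1
               ) -> tuple[TrioConditionalLogitResults | None, list[ResultRow]]:
    """Joint G + GxE test with an LRT against the empty model (df = 1 + k).

    Trios missing any of the named exposures are excluded before set
    construction (per-model complete case), so denominators differ across
    exposure subsets.  Per-term 1-df Wald tests accompany the LRT.
    """
    names = tuple(exposure_names)
    label = "G+" + "+".join(f"Gx{n}" for n in names) if names else "gTDT"
    sets, _ = build_matched_sets(trios, snp_index, snp_id, names)
    try:
        res = _fit_sets(sets, names)
    except (InestimableError, NoInformationError):
        return None, [ResultRow(snp_id, label, term="LRT")]
    if res.separation or not res.converged:
        return res, [ResultRow(snp_id, label, term="LRT",
                               n_sets=res.n_sets_informative)]
    stat, df, p_lrt = lrt(res)
    rows = [ResultRow(snp_id, label, term="LRT", lrt_stat=stat, lrt_df=df,
                      lrt_p=p_lrt, bonferroni_p=bonferroni(p_lrt, bonferroni_m),
                      n_sets=res.n_sets_informative)]
    for j, term in enumerate(res.exog_names):
        beta, se = float(res.params[j]), float(res.bse[j])
        _, _, p = res.wald_test(j)
        rows.append(ResultRow(
            snp_id, label, term=term, beta=beta, se=se, wald_p=p,
            lrt_stat=stat, lrt_df=df, lrt_p=p_lrt,
            bonferroni_p=bonferroni(p, bonferroni_m),
            or_value=float(np.exp(beta)),
            ci_lo=float(np.exp(beta - Z95 * se)),
            ci_hi=float(np.exp(beta + Z95 * se)),
            n_sets=res.n_sets_informative))
    return res, rows


def stratum_or(res: TrioConditionalLogitResults,
               exposure_combo: dict[str, int], copies: int = 1,
               exposure_names: tuple[str, ...] | None = None) -> StratumOR:
    """OR for carrying ``copies`` minor alleles within an exposure stratum.

    The contrast puts ``copies`` on beta_g and ``copies * E_i`` on each
    interaction, so exp(c'beta) compares carriers to non-carriers with the
    same exposures; the CI uses the delta-method variance c' Cov c.
    """
    if copies not in (1, 2):
        raise ValueError("copies must be 1 or 2")
    if exposure_names is None:
        exposure_names = tuple(n[2:] for n in res.exog_names[1:])
    c = np.array([copies] + [copies * exposure_combo.get(n, 0)
                             for n in exposure_names], dtype=float)
    _, _, p = res.wald_test(c)
    est = float(c @ res.params)
    se = float(np.sqrt(c @ res.cov_params @ c))
    return StratumOR(dict(exposure_combo), copies, float(np.exp(est)),
                     float(np.exp(est - Z95 * se)),
                     float(np.exp(est + Z95 * se)), p)


def allelic_tdt(trios: list[TrioRecord], snp_index: int
                ) -> tuple[int, int, float, float]:
    """Allelic TDT: transmitted (b) vs untransmitted (c) minor alleles.

    Counts come from heterozygous parents of Mendelian-consistent,
    fully-genotyped trios; chi2 = (b - c)^2 / (b + c) on 1 df.  With no
    heterozygous parent the statistic is undefined (NaN).
    """
    b = c = 0
    for tr in trios:
        f, m, ch = (int(tr.father[snp_index]), int(tr.mother[snp_index]),
                    int(tr.child[snp_index]))
        if mendel_check(f, m, ch) is not MendelStatus.CONSISTENT:
            continue
        if f == 1 and m == 1:
            if ch == 2:
                b += 2
            elif ch == 0:
                c += 2
            else:
                b += 1
                c += 1
        elif f == 1 or m == 1:
            hom = m if f == 1 else f
            transmitted_minor = ch - hom // 2
            if transmitted_minor == 1:
                b += 1
            else:
                c += 1
    if b + c == 0:
        return b, c, float("nan"), float("nan")
    stat = (b - c) ** 2 / (b + c)
    return b, c, float(stat), float(chi2.sf(stat, 1))


def stratum_table(trios: list[TrioRecord], snp_index: int, snp_id: str,
                  exposure_names: tuple[str, ...], copies: int = 1,
                  bonferroni_m: int = 1
                  ) -> tuple[TrioConditionalLogitResults, list[StratumOR],
                             list[ResultRow]]:
    """Per-exposure-combination ORs with counts and stratum MAF.

    One row per exposure combination actually observed among the analyzed
    trios; the stratum MAF is computed from the parents of the trios in
    that stratum.  Raises if the joint fit is not estimable.
    """
    names = tuple(exposure_names)
    usable: list[tuple[tuple[int, ...], TrioRecord]] = []
    sets = []
    for tr in trios:
        out = build_matched_set(tr, snp_index, snp_id, names)
        if isinstance(out, SkipReason):
            continue
        sets.append(out)
        usable.append((tuple(out.exposures[n] for n in names), tr))
    res = _fit_sets(sets, names)
    if res.separation or not res.converged:
        raise InestimableError(f"{snp_id}: joint fit did not converge")
    combos = sorted({combo for combo, _ in usable}, reverse=True)
    strata: list[StratumOR] = []
    rows: list[ResultRow] = []
    label = "G+" + "+".join(f"Gx{n}" for n in names)
    for combo in combos:
        members = [tr for cmb, tr in usable if cmb == combo]
        parents = np.concatenate(
            [[tr.father[snp_index], tr.mother[snp_index]] for tr in members])
        parents = parents[parents != MISSING]
        maf = float(parents.sum()) / (2 * parents.size) if parents.size else float("nan")
        s = stratum_or(res, dict(zip(names, combo)), copies, names)
        s.n_trios = len(members)
        s.stratum_maf = maf
        strata.append(s)
        rows.append(ResultRow(
            snp_id, label, term=f"stratum[{copies} copy]",
            wald_p=s.wald_p, bonferroni_p=bonferroni(s.wald_p, bonferroni_m),
            stratum=s.label(), or_value=s.or_value, ci_lo=s.ci_lo,
            ci_hi=s.ci_hi, n_sets=s.n_trios))
    return res, strata, rows
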