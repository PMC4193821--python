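"""Synthetic case-parent trios under the multiplicative risk model.

Parents are drawn independently as Binomial(2, MAF) (Hardy-Weinberg), the
child receives one uniformly chosen allele from each parent, and the
mother's binary exposures come from a joint distribution over exposure
combinations.  Ascertainment of an *affected* child follows the rare-disease
multiplicative model implied by the conditional-logistic analysis: a trio is
accepted as a case trio with probability exp(eta - eta_max) where

    eta = beta_g * G_child + sum_i beta_{g x e_i} * G_child * E_i

and eta_max is the largest eta achievable under the configured coefficients
and exposure support.  This rejection step makes the fitted conditional
odds ratios equal the simulated relative risks without having to specify a
baseline penetrance.

Defaults mirror a candidate-gene panel in Asian trio consortia: MAF 0.20 and
peri-conceptional maternal exposure rates ETS 38.2% and VIT 15.0% (with SMK
2.9% and ALCOHOL 2.2% available), independent across exposures, and no
genetic or interaction effect.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .trio_io import MISSING, Marker, TrioRecord

#: Peri-conceptional maternal exposure rates typical of Asian trio panels.
ASIAN_EXPOSURE_RATES = {"SMK": 0.029, "ETS": 0.382, "ALCOHOL": 0.022,
                        "VIT": 0.150}

DEFAULT_MAF = 0.20


@dataclass
class SimConfig:
    """Generative conditions for one causal SNP with maternal exposures.

    Effects may be given either as coefficients (``beta_g`` plus one
    ``beta_gxe`` per exposure, on the log odds-ratio scale) or as one-copy
    odds ratios per exposure stratum via :meth:`from_stratum_ors`.
    ``exposure_probs`` maps each exposure combination (tuple of 0/1 in
    ``exposure_names`` order) to its probability; when omitted, exposures
    are independent with rates from ``exposure_rates``.
    ``extra_null_mafs`` adds independent effect-free markers to the panel
    (for QC and multi-SNP exercises).
    """

    n_trios: int = 500
    maf: float = DEFAULT_MAF
    exposure_names: tuple[str, ...] = ()
    exposure_rates: dict[str, float] = field(default_factory=dict)
    exposure_probs: dict[tuple[int, ...], float] | None = None
    beta_g: float = 0.0
    beta_gxe: tuple[float, ...] = ()
    missing_rate: float = 0.0
    mendel_error_rate: float = 0.0
    seed: int = 0
    extra_null_mafs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        for rate in (self.missing_rate, self.mendel_error_rate):
            if not 0 <= rate < 1:
                raise ValueError("rates must lie in [0, 1)")
        if self.exposure_names and not self.beta_gxe:
            self.beta_gxe = (0.0,) * len(self.exposure_names)
        if len(self.beta_gxe) != len(self.exposure_names):
            raise ValueError("one beta_gxe per exposure required")
        coefs = np.array((self.beta_g,) + tuple(self.beta_gxe), dtype=float)
        if not np.all(np.isfinite(coefs)):
            raise ValueError("effect coefficients must be finite")
        if self.exposure_probs is not None:
            tot = sum(self.exposure_probs.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError("exposure combination probabilities must sum to 1")

    @classmethod
    def from_stratum_ors(cls, stratum_ors: dict[tuple[int, ...], float],
                         exposure_names: tuple[str, ...], **kw) -> "SimConfig":
        """Build from one-copy odds ratios per single-exposure stratum.

        ``stratum_ors`` keys are exposure indicator tuples; the all-zero
        (reference) stratum is required and single-exposure strata define the
        interactions: beta_g = log OR_ref, beta_gxe_i = log(OR_i / OR_ref).
        """
        k = len(exposure_names)
        ref = (0,) * k
        if ref not in stratum_ors:
            raise ValueError("reference (all-unexposed) stratum OR required")
        beta_g = float(np.log(stratum_ors[ref]))
        betas = []
        for i in range(k):
            combo = tuple(int(j == i) for j in range(k))
            if combo not in stratum_ors:
                raise ValueError(f"stratum OR for exposure {exposure_names[i]}"
                                 " alone required")
            betas.append(float(np.log(stratum_ors[combo])) - beta_g)
        return cls(exposure_names=tuple(exposure_names), beta_g=beta_g,
                   beta_gxe=tuple(betas), **kw)

    def combo_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        """(combo matrix (C, k), probability vector (C,)) over exposure combos."""
        k = len(self.exposure_names)
        if k == 0:
            return np.zeros((1, 0), dtype=np.int8), np.array([1.0])
        combos = np.array(list(itertools.product((0, 1), repeat=k)),
                          dtype=np.int8)
        if self.exposure_probs is not None:
            probs = np.array([self.exposure_probs.get(tuple(int(v) for v in c), 0.0)
                              for c in combos])
        else:
            rates = np.array([
                self.exposure_rates.get(name, ASIAN_EXPOSURE_RATES.get(name))
                for name in self.exposure_names], dtype=float)
            if np.any(np.isnan(rates)):
                raise ValueError("exposure rate missing and no default known")
            probs = np.prod(np.where(combos == 1, rates, 1 - rates), axis=1)
        return combos, probs / probs.sum()


def _eta_max(cfg: SimConfig, combos: np.ndarray, probs: np.ndarray) -> float:
    betas = np.array(cfg.beta_gxe, dtype=float)
    slopes = cfg.beta_g + (combos[probs > 0] @ betas if betas.size
                           else np.zeros(int((probs > 0).sum())))
    return float(max(0.0, 2.0 * slopes.max()))


def simulate_arrays(cfg: SimConfig, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised core: (father, mother, child dosages, exposure matrix).

    Returns the causal SNP only; arrays are int8 of length ``cfg.n_trios``
    (exposures ``(n, k)``).  Ascertainment bias from the configured effects
    is applied by rejection sampling.
    """
    combos, probs = cfg.combo_distribution()
    betas = np.array(cfg.beta_gxe, dtype=float)
    eta_max = _eta_max(cfg, combos, probs)
    need = cfg.n_trios
    F = np.empty(0, np.int8)
    M = np.empty(0, np.int8)
    C = np.empty(0, np.int8)
    E = np.empty((0, combos.shape[1]), np.int8)
    while F.size < need:
        m = max(1024, int(1.5 * (need - F.size)))
        f = rng.binomial(2, cfg.maf, m).astype(np.int8)
        mo = rng.binomial(2, cfg.maf, m).astype(np.int8)
        ch = (rng.binomial(1, f / 2.0) + rng.binomial(1, mo / 2.0)).astype(np.int8)
        ci = rng.choice(combos.shape[0], size=m, p=probs)
        e = combos[ci]
        eta = cfg.beta_g * ch + (ch * (e @ betas) if betas.size else 0.0)
        keep = rng.random(m) < np.exp(eta - eta_max)
        F = np.concatenate([F, f[keep]])
        M = np.concatenate([M, mo[keep]])
        C = np.concatenate([C, ch[keep]])
        E = np.concatenate([E, e[keep]])
    return F[:need], M[:need], C[:need], E[:need]


def simulate_trios(cfg: SimConfig) -> tuple[list[Marker], list[TrioRecord]]:
    """Generate a marker panel and TrioRecords under ``cfg``.

    Marker 0 ("snp1") carries the configured effects; any
    ``extra_null_mafs`` markers are independent and effect-free.  Missing
    genotypes and Mendelian errors are injected afterwards at the configured
    rates.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    F, M, C, E = simulate_arrays(cfg, rng)
    n = cfg.n_trios
    cols_f, cols_m, cols_c = [F], [M], [C]
    mafs = (cfg.maf,) + tuple(cfg.extra_null_mafs)
    for q in cfg.extra_null_mafs:
        f = rng.binomial(2, q, n).astype(np.int8)
        mo = rng.binomial(2, q, n).astype(np.int8)
        ch = (rng.binomial(1, f / 2.0) + rng.binomial(1, mo / 2.0)).astype(np.int8)
        cols_f.append(f)
        cols_m.append(mo)
        cols_c.append(ch)
    Fm = np.column_stack(cols_f).astype(np.int8)
    Mm = np.column_stack(cols_m).astype(np.int8)
    Cm = np.column_stack(cols_c).astype(np.int8)
    markers = [Marker(f"snp{j + 1}", "14", 54_000_000 + 1000 * j, "a", "b")
               for j in range(len(mafs))]
    trios = []
    for i in range(n):
        expos = {name: int(E[i, j])
                 for j, name in enumerate(cfg.exposure_names)}
        trios.append(TrioRecord(f"F{i + 1:05d}", Fm[i].copy(), Mm[i].copy(),
                                Cm[i].copy(), expos))
    if cfg.missing_rate > 0:
        inject_missing(trios, cfg.missing_rate, rng)
    if cfg.mendel_error_rate > 0:
        inject_mendel_errors(trios, cfg.mendel_error_rate, rng)
    return markers, trios


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def inject_missing(trios: list[TrioRecord], rate: float, seed=0) -> list[TrioRecord]:
    """Blank each member-genotype independently with probability ``rate``."""
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    rng = _as_rng(seed)
    for tr in trios:
        for vec in (tr.father, tr.mother, tr.child):
            mask = rng.random(len(vec)) < rate
            vec[mask] = MISSING
    return trios


def inject_mendel_errors(trios: list[TrioRecord], rate: float,
                         seed=0) -> list[TrioRecord]:
    """With probability ``rate`` per trio-SNP, replace the child dosage.

    The replacement is drawn uniformly from the two dosages differing from
    the original, so an injected error always changes the stored genotype
    (though it is not guaranteed to be detectable as Mendelian-inconsistent).
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    rng = _as_rng(seed)
    for tr in trios:
        hit = (rng.random(len(tr.child)) < rate) & (tr.child != MISSING)
        for j in np.flatnonzero(hit):
            options = [d for d in (0, 1, 2) if d != tr.child[j]]
            tr.child[j] = options[rng.integers(2)]
    return trios
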