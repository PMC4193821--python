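"""Simulation-based power and type-I-error estimation.

Each replicate draws a fresh trio panel from a :class:`SimConfig`, runs the
requested test (gTDT Wald, joint LRT against the empty model, or a stratum
Wald contrast) and counts rejections at the chosen significance level.
Replicates whose fit is not estimable (separation, no informative sets, or a
degenerate design) are counted as non-rejections and reported separately.

For a stratum test two modes are provided, because an analytic power tool fed
per-stratum inputs could be interpreted either way: ``mode="full"`` simulates
the whole design (all exposure strata present) and tests the stratum
contrast inside the joint model; ``mode="subgroup"`` simulates only that
stratum's trios and runs a G-only gTDT on them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .clogit import (InestimableError, NoInformationError,
                     TrioConditionalLogit, lrt)
from .matched_sets import TRANSMISSIONS
from .simulate import SimConfig, simulate_arrays


@dataclass
class PowerResult:
    power: float
    mc_se: float
    n_reps: int
    alpha: float
    test_label: str
    n_nonestimable: int = 0


@dataclass
class TestSpec:
    """Which test to reject with: 'gtdt', 'lrt' or 'stratum'."""

    __test__ = False  # not a pytest collection target

    kind: str = "gtdt"
    combo: dict[str, int] | None = None
    copies: int = 1
    mode: str = "full"  # stratum tests only: 'full' or 'subgroup'

    def label(self, cfg: SimConfig) -> str:
        if self.kind == "gtdt":
            return "gTDT Wald (1 df)"
        if self.kind == "lrt":
            return f"LRT G+GxE ({1 + len(cfg.exposure_names)} df)"
        return f"stratum Wald [{self.mode}]"


def matched_set_genotypes(F: np.ndarray, M: np.ndarray, C: np.ndarray
                          ) -> np.ndarray:
    """(n, 4) member dosages, case first, from parental/child dosage arrays.

    All trios must be complete and Mendelian-consistent.
    """
    trans = TRANSMISSIONS[F, M]  # (n, 4) descending
    hit = trans == C[:, None]
    if not hit.any(axis=1).all():
        raise ValueError("Mendelian-inconsistent trio in matched-set build")
    first = hit.argmax(axis=1)
    mask = np.ones_like(trans, dtype=bool)
    mask[np.arange(len(first)), first] = False
    pseudo = trans[mask].reshape(-1, 3)
    return np.column_stack([C, pseudo]).astype(np.int8)


def _replicate_pvalue(cfg: SimConfig, test: TestSpec,
                      rng: np.random.Generator) -> float:
    if test.kind == "stratum" and test.mode == "subgroup":
        combo = test.combo or {}
        key = tuple(int(combo.get(n, 0)) for n in cfg.exposure_names)
        cfg = replace(cfg, exposure_probs={key: 1.0})
    F, M, C, E = simulate_arrays(cfg, rng)
    G = matched_set_genotypes(F, M, C)
    if test.kind == "gtdt" or (test.kind == "stratum" and test.mode == "subgroup"):
        res = TrioConditionalLogit(G).fit()
        if res.separation or not res.converged:
            raise InestimableError("fit not estimable")
        return res.wald_test(0)[2]
    res = TrioConditionalLogit(G, E, cfg.exposure_names).fit()
    if res.separation or not res.converged:
        raise InestimableError("fit not estimable")
    if test.kind == "lrt":
        return lrt(res)[2]
    if test.kind == "stratum":
        combo = test.combo or {}
        c = np.array([test.copies] + [test.copies * combo.get(n, 0)
                                      for n in cfg.exposure_names], dtype=float)
        return res.wald_test(c)[2]
    raise ValueError(f"unknown test kind {test.kind!r}")


def estimate_power(cfg: SimConfig, test: TestSpec, alpha: float,
                   n_reps: int, seed: int = 0) -> PowerResult:
    """Monte-Carlo rejection rate of ``test`` at level ``alpha``.

    Deterministic given ``seed``; ``cfg.seed`` is ignored so that the whole
    stream flows from one generator.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    rng = np.random.default_rng(seed)
    hits = 0
    bad = 0
    for _ in range(n_reps):
        try:
            p = _replicate_pvalue(cfg, test, rng)
        except (InestimableError, NoInformationError):
            bad += 1
            continue
        if p < alpha:
            hits += 1
    power = hits / n_reps
    mc_se = float(np.sqrt(power * (1 - power) / n_reps))
    return PowerResult(power, mc_se, n_reps, alpha, test.label(cfg), bad)
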