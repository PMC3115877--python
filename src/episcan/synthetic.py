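"""Synthetic case/control datasets with known genetic architecture.

Genotypes are independent SNPs in Hardy-Weinberg proportions — each column is
Binomial(2, maf) — and disease status follows a logistic model

    logit P(Y = 1) = beta0 + sum_k beta_k g_k + sum_(k,l) beta_kl g_k g_l

with optional planted main and pairwise-interaction effects. The
retrospective case/control design is reproduced by rejection: a population
is simulated and individuals are kept until the case and control quotas are
met, which is exact and fast at the scale these datasets are used
(hundreds to a few thousand individuals). Missingness, when requested, is
applied completely at random after sampling.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.special import expit

from .genotype_io import MISSING, GenotypeDataset

# rejection-sampler guards: a configuration whose rarer outcome has expected
# yield below ~1 per 1e7 draws is rejected as infeasible
_MIN_YIELD = 1e-7
_PILOT_DRAWS = 20_000
_MAX_DRAWS = 20_000_000


class FeasibilityError(RuntimeError):
    """The requested case/control quotas are unreachable by rejection sampling."""


@dataclasses.dataclass
class SyntheticSpec:
    """Recipe for one synthetic case/control dataset.

    Attributes
    ----------
    n_cases, n_controls : int
        Target counts; sampling continues until both quotas are met.
    n_snps : int
        Number of independent SNPs.
    maf : float or (low, high)
        Minor-allele frequency shared by all SNPs, or a range sampled
        uniformly per SNP. Must lie in (0, 0.5].
    beta0 : float
        Baseline log-odds of disease.
    main_effects : dict[int, float]
        SNP index -> main-effect log-odds ratio per minor allele.
    interaction_effects : dict[tuple[int, int], float]
        SNP index pair -> interaction log-odds ratio per allele product.
    missing_rate : float
        Per-genotype probability of being set missing, in [0, 1).
    seed : int
        Seed making the dataset fully reproducible.
    """

    n_cases: int
    n_controls: int
    n_snps: int
    maf: float | tuple[float, float] = 0.3
    beta0: float = 0.0
    main_effects: dict[int, float] = dataclasses.field(default_factory=dict)
    interaction_effects: dict[tuple[int, int], float] = dataclasses.field(
        default_factory=dict
    )
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be positive")
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")
        lo, hi = self.maf_range()
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"MAFs must lie in (0, 0.5], got {self.maf}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        for k in self.main_effects:
            if not 0 <= k < self.n_snps:
                raise ValueError(f"main effect refers to SNP index {k} out of range")
        for k, l in self.interaction_effects:
            if not (0 <= k < self.n_snps and 0 <= l < self.n_snps and k != l):
                raise ValueError(
                    f"interaction effect refers to invalid SNP pair ({k}, {l})"
                )

    def maf_range(self) -> tuple[float, float]:
        if isinstance(self.maf, (tuple, list)):
            return float(self.maf[0]), float(self.maf[1])
        return float(self.maf), float(self.maf)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["interaction_effects"] = {
            f"{k},{l}": v for (k, l), v in self.interaction_effects.items()
        }
        return json.dumps(d, indent=2)


def sample_genotypes(
    n: int, maf: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """One genotype column: n draws from Binomial(2, maf) (HWE proportions)."""
    if not 0 < maf <= 0.5:
        raise ValueError(f"maf must lie in (0, 0.5], got {maf}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.binomial(2, maf, size=n).astype(np.int8)


def _linear_predictor(spec: SyntheticSpec, G: np.ndarray) -> np.ndarray:
    eta = np.full(G.shape[0], spec.beta0, dtype=np.float64)
    for k, beta in spec.main_effects.items():
        eta += beta * G[:, k]
    for (k, l), beta in spec.interaction_effects.items():
        eta += beta * G[:, k].astype(np.float64) * G[:, l]
    return eta


def simulate_case_control(spec: SyntheticSpec) -> GenotypeDataset:
    """Simulate a retrospective case/control dataset from *spec*.

    Individuals are drawn from the population model and retained until the
    case and control quotas are filled; excess draws are discarded. The
    returned dataset lists cases first, then controls. Fully reproducible
    given ``spec.seed``.

    Raises
    ------
    FeasibilityError
        If the effect configuration makes the rarer outcome class too rare
        for rejection sampling (expected yield below ~1 per 1e7 draws).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.maf_range()
    mafs = rng.uniform(lo, hi, size=spec.n_snps) if lo < hi else np.full(spec.n_snps, lo)

    # pilot estimate of the marginal case probability for the feasibility guard
    pilot = _draw_population(rng, mafs, _PILOT_DRAWS)
    p_case = float(np.mean(expit(_linear_predictor(spec, pilot))))
    if spec.n_cases > 0 and p_case < _MIN_YIELD:
        raise FeasibilityError(
            f"expected case yield {p_case:.2e} per draw is below {_MIN_YIELD:.0e}"
        )
    if spec.n_controls > 0 and 1.0 - p_case < _MIN_YIELD:
        raise FeasibilityError(
            f"expected control yield {1.0 - p_case:.2e} per draw is below "
            f"{_MIN_YIELD:.0e}"
        )

    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    n_case = n_ctrl = 0
    draws = 0
    need = spec.n_cases + spec.n_controls
    while n_case < spec.n_cases or n_ctrl < spec.n_controls:
        batch = min(max(2048, 2 * need), 200_000)
        G = _draw_population(rng, mafs, batch)
        y = rng.random(batch) < expit(_linear_predictor(spec, G))
        draws += batch
        if n_case < spec.n_cases:
            take = G[y][: spec.n_cases - n_case]
            cases.append(take)
            n_case += take.shape[0]
        if n_ctrl < spec.n_controls:
            take = G[~y][: spec.n_controls - n_ctrl]
            controls.append(take)
            n_ctrl += take.shape[0]
        if draws > _MAX_DRAWS:
            raise FeasibilityError(
                f"quotas unmet after {draws} draws "
                f"({n_case}/{spec.n_cases} cases, {n_ctrl}/{spec.n_controls} controls)"
            )

    genotypes = np.vstack([*cases, *controls]).astype(np.int8)
    phenotype = np.concatenate(
        [np.ones(spec.n_cases, dtype=np.int8), np.zeros(spec.n_controls, dtype=np.int8)]
    )
    if spec.missing_rate > 0:
        mask = rng.random(genotypes.shape) < spec.missing_rate
        genotypes[mask] = MISSING
    width = max(4, len(str(spec.n_snps)))
    snp_ids = [f"snp{j:0{width}d}" for j in range(spec.n_snps)]
    return GenotypeDataset(phenotype, genotypes, snp_ids)


def _draw_population(
    rng: np.random.Generator, mafs: np.ndarray, n: int
) -> np.ndarray:
    return rng.binomial(2, mafs, size=(n, mafs.size)).astype(np.int8)


def write_truth(spec: SyntheticSpec, path: str | Path) -> None:
    """Record the planted architecture (effects, MAFs, seed) as JSON."""
    Path(path).write_text(spec.to_json() + "\n")
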