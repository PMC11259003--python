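"""Synthetic cohort generator.

Generates urine-metabolomics-like cohorts with the statistical structure the
downstream analysis assumes: log-normal abundances, block-correlated
metabolite clusters (a "steroid-like" block whose members move together),
a heavily imbalanced binary adrenal outcome derived by thresholding a
continuous cortisol measure, a sex covariate, missing-at-random dropout and
planted group effects (a decreased steroid-like block plus a few increased
metabolites). Every draw is reproducible from the config seed.

The defaults mirror the discovery-cohort shape: 200 samples with a 188/12
sufficient/insufficient split and 571 metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortMatrix

#: peak plasma cortisol cutoff (nmol/L); at or below means insufficient
CORTISOL_CUTOFF = 350.0

_SUPER_PATHWAYS = (
    "Amino Acid",
    "Lipid",
    "Carbohydrate",
    "Nucleotide",
    "Peptide",
    "Cofactors and Vitamins",
    "Energy",
)


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort generator.

    ``effect_size`` is a mean shift on the natural-log abundance scale; the
    latent per-metabolite log-SD is 1, so it is also the shift in SD units.
    ``block_specs`` is a list of ``(size, rho)`` pairs: each block is drawn
    from a compound-symmetric latent Gaussian with within-block correlation
    ``rho``. The first block plays the role of the correlated steroid
    cluster and hosts the planted "down" effects.
    """

    n_samples: int = 200
    n_metabolites: int = 571
    minority_fraction: float = 12 / 200
    n_effect_down: int = 20
    n_effect_up: int = 5
    effect_size: float = 1.5
    block_specs: list[tuple[int, float]] = field(default_factory=lambda: [(20, 0.7)])
    missing_rate: float = 0.10
    sex_balance: float = 114 / 200  # proportion male, as in the discovery cohort
    sex_effect: float = 0.0  # log-scale shift for males; default none
    xenobiotic_fraction: float = 0.0
    partially_characterized_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.minority_fraction < 0.5):
            raise ValueError("minority_fraction must be in (0, 0.5)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if sum(s for s, _ in self.block_specs) > self.n_metabolites:
            raise ValueError("block sizes must sum to at most n_metabolites")
        if any(abs(r) >= 1 for _, r in self.block_specs):
            raise ValueError("within-block correlation must satisfy |rho| < 1")
        if self.n_effect_down + self.n_effect_up > self.n_metabolites:
            raise ValueError("more planted effects than metabolites")
        if not (0 <= self.sex_balance <= 1):
            raise ValueError("sex_balance must be a proportion")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")


@dataclass
class SynthCohort:
    """A generated cohort plus the ground truth used to plant it."""

    matrix: CohortMatrix
    truth: pd.Series  # per metabolite: "null" | "down" | "up"
    truth_blocks: pd.Series  # block index per metabolite, -1 if unblocked

    @property
    def down_ids(self) -> list[str]:
        return list(self.truth.index[self.truth == "down"])

    @property
    def up_ids(self) -> list[str]:
        return list(self.truth.index[self.truth == "up"])

    @property
    def effect_ids(self) -> list[str]:
        return self.down_ids + self.up_ids


def _latent_block(rng: np.random.Generator, n: int, size: int, rho: float) -> np.ndarray:
    """Compound-symmetric Gaussian block: z = sqrt(rho)*shared + sqrt(1-rho)*own."""
    shared = rng.standard_normal((n, 1))
    own = rng.standard_normal((n, size))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own


def _fingerprints(rng: np.random.Generator, blocks: np.ndarray, n_bits: int = 64) -> list[str]:
    """Binary substructure-like fingerprints: block members share a template."""
    n = len(blocks)
    out = [""] * n
    templates: dict[int, np.ndarray] = {}
    for j in range(n):
        b = int(blocks[j])
        if b >= 0:
            if b not in templates:
                templates[b] = rng.random(n_bits) < 0.3
            fp = templates[b].copy()
            flip = rng.random(n_bits) < 0.03  # slight within-block variation
            fp ^= flip
        else:
            fp = rng.random(n_bits) < 0.3
        out[j] = "".join("1" if x else "0" for x in fp)
    return out


def generate_cohort(config: SynthConfig) -> SynthCohort:
    """Draw a synthetic discovery cohort from `config`.

    Abundances are ``exp(mu_j + z_ij + effects)`` with block-correlated
    latent z; planted "down"/"up" metabolites are shifted by -/+
    ``effect_size`` on the log scale in the minority group only. A continuous
    cortisol column is constructed so that thresholding at 350 nmol/L
    reproduces the group labels exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_metabolites

    # outcome: fixed minority count so the design imbalance is exact
    n_minority = int(round(config.minority_fraction * n))
    y = np.zeros(n, dtype=int)
    y[rng.choice(n, size=n_minority, replace=False)] = 1

    # block structure
    blocks = np.full(p, -1, dtype=int)
    z = rng.standard_normal((n, p))
    start = 0
    for b, (size, rho) in enumerate(config.block_specs):
        z[:, start : start + size] = _latent_block(rng, n, size, rho)
        blocks[start : start + size] = b
        start += size

    # planted effects: "down" drawn from the first block when it is large
    # enough (the decreased steroid-like cluster), "up" among unblocked ones
    truth = np.array(["null"] * p, dtype=object)
    block0 = np.flatnonzero(blocks == 0)
    free = np.flatnonzero(blocks == -1)
    down_pool = np.concatenate([block0, free]) if block0.size else free
    down_idx = down_pool[: config.n_effect_down]
    up_pool = np.setdiff1d(free, down_idx)
    up_idx = up_pool[: config.n_effect_up]
    if len(down_idx) < config.n_effect_down or len(up_idx) < config.n_effect_up:
        raise ValueError("not enough metabolites to host the planted effects")
    truth[down_idx] = "down"
    truth[up_idx] = "up"

    minority = y == 1
    z[np.ix_(minority, down_idx)] -= config.effect_size
    z[np.ix_(minority, up_idx)] += config.effect_size

    # covariates
    sex = (rng.random(n) < config.sex_balance).astype(int)  # 1 = male
    if config.sex_effect:
        z[sex == 1, :] += config.sex_effect
    age = rng.uniform(5, 18, size=n)
    osmolality = rng.uniform(0.5, 1.5, size=n)

    mu = rng.uniform(1.0, 3.0, size=p)  # baseline log abundance per metabolite
    abund = np.exp(mu[None, :] + z)

    # continuous cortisol consistent with the dichotomization
    cortisol = np.where(
        minority,
        CORTISOL_CUTOFF - rng.uniform(1.0, 200.0, size=n),
        CORTISOL_CUTOFF + rng.uniform(1.0, 450.0, size=n),
    )

    # missing completely at random
    if config.missing_rate > 0:
        mask = rng.random((n, p)) < config.missing_rate
        abund = np.where(mask, np.nan, abund)

    sample_ids = [f"S{i:04d}" for i in range(n)]
    met_ids = [f"M{j:04d}" for j in range(p)]

    sub_pathway = np.array(
        [f"block_{b}" if b >= 0 else f"pathway_{j % 25}" for j, b in enumerate(blocks)]
    )
    sub_pathway[blocks == 0] = "steroid_block"
    super_pathway = np.array(
        ["Lipid" if b == 0 else _SUPER_PATHWAYS[j % len(_SUPER_PATHWAYS)] for j, b in enumerate(blocks)]
    )
    n_xeno = int(round(config.xenobiotic_fraction * p))
    n_partial = int(round(config.partially_characterized_fraction * p))
    flag_pool = rng.permutation(np.setdiff1d(np.arange(p), np.concatenate([down_idx, up_idx])))
    is_xeno = np.zeros(p, dtype=bool)
    is_partial = np.zeros(p, dtype=bool)
    is_xeno[flag_pool[:n_xeno]] = True
    is_partial[flag_pool[n_xeno : n_xeno + n_partial]] = True

    metabolite_meta = pd.DataFrame(
        {
            "name": [f"metabolite {j}" for j in range(p)],
            "super_pathway": super_pathway,
            "sub_pathway": sub_pathway,
            "fingerprint": _fingerprints(rng, blocks),
            "is_xenobiotic": is_xeno,
            "is_partially_characterized": is_partial,
        },
        index=pd.Index(met_ids, name="metabolite_id"),
    )
    sample_meta = pd.DataFrame(
        {
            "group": np.where(minority, "insufficient", "sufficient"),
            "cortisol": cortisol,
            "sex": sex,
            "age": age,
            "osmolality": osmolality,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    matrix = CohortMatrix(
        abundances=pd.DataFrame(abund, index=sample_meta.index, columns=metabolite_meta.index),
        sample_meta=sample_meta,
        metabolite_meta=metabolite_meta,
    )
    return SynthCohort(
        matrix=matrix,
        truth=pd.Series(truth, index=metabolite_meta.index, name="truth"),
        truth_blocks=pd.Series(blocks, index=metabolite_meta.index, name="block"),
    )


def generate_validation_cohort(
    config: SynthConfig,
    shared_ids: list[str],
    discovery: SynthCohort | None = None,
    n_samples: int = 10,
    n_extra_metabolites: int = 40,
    association_slope: float | None = None,
) -> SynthCohort:
    """Small validation cohort with continuous cortisol outcomes.

    Metabolite ids overlap a discovery cohort in exactly ``shared_ids``;
    the remaining metabolites get validation-only ids. Four cortisol
    outcomes (baseline, 30-min, 60-min serum and 24-h urine analogues) are
    generated so that metabolites planted as effects in the discovery
    cohort (per ``discovery.truth``) carry a linear association of strength
    ``association_slope`` (default ``config.effect_size``) with each outcome.
    """
    if len(shared_ids) == 0:
        raise ValueError("shared_ids must be non-empty")
    if discovery is not None:
        missing = set(shared_ids) - set(discovery.matrix.abundances.columns)
        if missing:
            raise ValueError(f"shared_ids not present in discovery cohort: {sorted(missing)}")
    slope = config.effect_size if association_slope is None else association_slope
    rng = np.random.default_rng(config.seed + 1)

    met_ids = list(shared_ids) + [f"V{j:04d}" for j in range(n_extra_metabolites)]
    p = len(met_ids)
    n = n_samples
    z = rng.standard_normal((n, p))
    mu = rng.uniform(1.0, 3.0, size=p)
    abund = np.exp(mu[None, :] + z)

    truth = np.array(["null"] * p, dtype=object)
    signed = np.zeros(p)
    if discovery is not None:
        for j, mid in enumerate(shared_ids):
            lab = discovery.truth.get(mid, "null")
            truth[j] = lab
            signed[j] = {"down": -1.0, "up": 1.0}.get(lab, 0.0)

    # cortisol co-varies positively with "down" metabolites (both fall in
    # suppression) and negatively with "up" metabolites
    driver = -(z @ signed)
    base = 400 + 80 * slope * (driver / max(1.0, np.abs(signed).sum() ** 0.5))
    sample_meta = pd.DataFrame(
        {
            "cortisol_baseline": base + rng.normal(0, 40, n),
            "cortisol_30min": base * 1.4 + rng.normal(0, 40, n),
            "cortisol_60min": base * 1.6 + rng.normal(0, 40, n),
            "cortisol_24h_urine": base * 0.25 + rng.normal(0, 15, n),
            "sex": (rng.random(n) < config.sex_balance).astype(int),
            "age": rng.uniform(8, 15, n),
            "osmolality": rng.uniform(0.5, 1.5, n),
        },
        index=pd.Index([f"V{i:03d}" for i in range(n)], name="sample_id"),
    )
    metabolite_meta = pd.DataFrame(
        {
            "name": met_ids,
            "super_pathway": "unknown",
            "sub_pathway": "unknown",
            "is_xenobiotic": False,
            "is_partially_characterized": False,
        },
        index=pd.Index(met_ids, name="metabolite_id"),
    )
    matrix = CohortMatrix(
        abundances=pd.DataFrame(abund, index=sample_meta.index, columns=metabolite_meta.index),
        sample_meta=sample_meta,
        metabolite_meta=metabolite_meta,
    )
    blocks = pd.Series(-1, index=metabolite_meta.index, name="block")
    return SynthCohort(
        matrix=matrix,
        truth=pd.Series(truth, index=metabolite_meta.index, name="truth"),
        truth_blocks=blocks,
    )
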