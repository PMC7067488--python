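"""Synthetic data generators for the three simulation studies.

Study 1 simulates a quantitative exposure X and outcome Y with a SNP
instrument G for X and a continuous instrument Z for Y, under three
structural models: no confounding (model 1), non-genetic confounding via
a latent C (model 2), and genetic confounding via a G-driven mediator S
(model 3).  Every structural equation has residual standard deviation 1.

Study 2 simulates four binary variables Q -> W -> H -> Y (a gene, high
alcohol, high alanine transaminase, hepatocellular carcinoma) with
Bernoulli nodes and logistic links, under four published coefficient
scenarios (A-D).

Study 3 simulates an extreme-pleiotropy setting: 10,000 HWE SNPs, 12
metabolites (4 null / 4 causal on the outcome / 4 reverse-caused by the
outcome) and one outcome Y, with a synthetic sparse SNP-metabolite
effect matrix standing in for external GWAS coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .dataset import Dataset

__all__ = [
    "Study1Params",
    "ScenarioParams",
    "Study3Config",
    "EffectTable",
    "SCENARIOS",
    "simulate_study1",
    "simulate_study2",
    "generate_snp_effects",
    "simulate_study3",
]


# ---------------------------------------------------------------------------
# Study 1: quantitative traits with instruments G (SNP) and Z (continuous)
# ---------------------------------------------------------------------------

#: shared instrument strengths; confounding paths depend on the preset
_WEAK = dict(beta_GX=0.1, beta_ZY=0.075, beta_CX=0.25, beta_CY=0.25,
             beta_GS=0.25, beta_SY=0.25)
_STRONG = dict(beta_GX=0.1, beta_ZY=0.075, beta_CX=0.5, beta_CY=0.5,
               beta_GS=0.5, beta_SY=0.5)


@dataclass
class Study1Params:
    """Generating coefficients for one study-1 model.

    Exactly one of ``beta_XY`` / ``beta_YX`` may be nonzero, chosen by
    ``direction``: the forward model draws Y given X, the reverse model
    draws X given Y (with the instruments keeping their targets).
    """

    model: int = 1
    beta_GX: float = 0.1
    beta_ZY: float = 0.075
    beta_XY: float = 0.0
    beta_YX: float = 0.0
    beta_CX: float = 0.0
    beta_CY: float = 0.0
    beta_GS: float = 0.0
    beta_SY: float = 0.0
    direction: str = "x_to_y"
    n: int = 2500
    maf_G: float = 0.3
    residual_sd: float = 1.0

    @classmethod
    def preset(cls, model: int, confounding: str = "weak",
               effect: float = 0.0, direction: str = "x_to_y",
               n: int = 2500, maf_G: float = 0.3) -> "Study1Params":
        """Published parameter preset for a model/confounding combination.

        ``effect`` is assigned to beta_XY or beta_YX according to
        ``direction``.  Models 1 has no confounding paths; model 2 keeps
        only the C paths; model 3 only the G->S->Y paths.
        """
        base = {"weak": _WEAK, "strong": _STRONG}[confounding].copy()
        if model == 1:
            base.update(beta_CX=0.0, beta_CY=0.0, beta_GS=0.0, beta_SY=0.0)
        elif model == 2:
            base.update(beta_GS=0.0, beta_SY=0.0)
        elif model == 3:
            base.update(beta_CX=0.0, beta_CY=0.0)
        else:
            raise ValueError(f"unknown model {model}")
        eff = {"x_to_y": {"beta_XY": effect}, "y_to_x": {"beta_YX": effect}}[direction]
        return cls(model=model, direction=direction, n=n, maf_G=maf_G,
                   **base, **eff)

    def validate(self) -> None:
        if self.model not in (1, 2, 3):
            raise ValueError(f"unknown model {self.model}")
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0.0 < self.maf_G < 1.0:
            raise ValueError("maf_G must lie in (0, 1)")
        if self.direction not in ("x_to_y", "y_to_x"):
            raise ValueError(f"unknown direction {self.direction!r}")
        active, inactive = (("beta_XY", "beta_YX") if self.direction == "x_to_y"
                            else ("beta_YX", "beta_XY"))
        if getattr(self, inactive) != 0.0:
            raise ValueError(
                f"{inactive} must be 0 when direction={self.direction!r} "
                f"(only {active} is active)")


def simulate_study1(params: Study1Params, seed: int) -> Dataset:
    """Draw one study-1 dataset.

    Returns columns G, Z, X, Y, plus C for model 2 and S for model 3.
    All variables carry kind ``continuous`` (matching how they are
    treated during network fitting, regardless of G's discrete support).
    """
    params.validate()
    p = params
    rng = np.random.default_rng(seed)
    n, sd = p.n, p.residual_sd

    G = rng.binomial(2, p.maf_G, size=n).astype(float)
    Z = rng.normal(0.0, 1.0, size=n)

    C = rng.normal(0.0, 1.0, size=n) if p.model == 2 else None
    S = rng.normal(p.beta_GS * G, sd) if p.model == 3 else None

    cx = p.beta_CX * C if C is not None else 0.0
    cy = p.beta_CY * C if C is not None else 0.0
    sy = p.beta_SY * S if S is not None else 0.0

    if p.direction == "x_to_y":
        X = rng.normal(p.beta_GX * G + cx, sd)
        Y = rng.normal(p.beta_XY * X + p.beta_ZY * Z + cy + sy, sd)
    else:
        Y = rng.normal(p.beta_ZY * Z + cy + sy, sd)
        X = rng.normal(p.beta_YX * Y + p.beta_GX * G + cx, sd)

    cols = {"G": G, "Z": Z, "X": X, "Y": Y}
    roles = {"G": "instrument", "Z": "instrument",
             "X": "phenotype", "Y": "outcome"}
    if C is not None:
        cols["C"] = C
        roles["C"] = "confounder"
    if S is not None:
        cols["S"] = S
        roles["S"] = "confounder"
    kinds = {c: "continuous" for c in cols}
    return Dataset(values=pd.DataFrame(cols), kinds=kinds, roles=roles)


# ---------------------------------------------------------------------------
# Study 2: binary traits Q, W, H, Y with logistic links
# ---------------------------------------------------------------------------


@dataclass
class ScenarioParams:
    """Logistic-model coefficients for the binary-trait graph.

    Q ~ Bernoulli(freq_Q); W, H, Y are Bernoulli with success probability
    inverse-logit of a linear predictor:

        logit P(W=1) = delta_0 + delta_q Q
        logit P(H=1) = alpha_0 + alpha_q Q + alpha_W W
        logit P(Y=1) = beta_0 + beta_q Q + beta_W W + beta_H H
    """

    freq_Q: float
    beta_0: float
    beta_q: float
    beta_W: float
    beta_H: float
    alpha_0: float
    alpha_q: float
    alpha_W: float
    delta_0: float
    delta_q: float
    n: int = 5000

    def validate(self) -> None:
        if not 0.0 < self.freq_Q < 1.0:
            raise ValueError("freq_Q must lie in (0, 1)")
        if self.n <= 0:
            raise ValueError("n must be positive")
        coefs = [self.beta_0, self.beta_q, self.beta_W, self.beta_H,
                 self.alpha_0, self.alpha_q, self.alpha_W,
                 self.delta_0, self.delta_q]
        if not np.all(np.isfinite(coefs)):
            raise ValueError("coefficients must be finite")


#: published scenario presets (rows A-D of the binary-study parameter table)
SCENARIOS: dict[str, ScenarioParams] = {
    "A": ScenarioParams(0.49, 0.2, 0.3, 0.25, 0.15, 0.2, 0.4, 0.2, 0.1, 0.3),
    "B": ScenarioParams(0.49, -0.9, -0.3, -0.1, 0.2, 0.0, 0.2, 0.2, 0.2, 0.3),
    "C": ScenarioParams(0.49, -1.0, -1.0, -0.8, 0.2, 0.0, 0.2, 0.2, 0.2, 0.3),
    "D": ScenarioParams(0.49, 0.2, 0.2, 0.2, 0.1, 0.1, 0.2, 0.2, 0.1, 0.2),
}


def scenario(name: str, n: int = 5000) -> ScenarioParams:
    """Return a scenario preset, optionally at a non-default sample size."""
    return replace(SCENARIOS[name.upper()], n=n)


def simulate_study2(params: ScenarioParams, seed: int) -> Dataset:
    """Draw one binary dataset in topological order Q -> W -> H -> Y."""
    params.validate()
    p = params
    rng = np.random.default_rng(seed)
    n = p.n

    Q = rng.binomial(1, p.freq_Q, size=n)
    W = rng.binomial(1, expit(p.delta_0 + p.delta_q * Q))
    H = rng.binomial(1, expit(p.alpha_0 + p.alpha_q * Q + p.alpha_W * W))
    Y = rng.binomial(1, expit(p.beta_0 + p.beta_q * Q + p.beta_W * W + p.beta_H * H))

    values = pd.DataFrame({"Q": Q, "W": W, "H": H, "Y": Y})
    kinds = {c: "categorical" for c in values.columns}
    roles = {"Q": "instrument", "W": "phenotype", "H": "phenotype", "Y": "outcome"}
    levels = {c: (0, 1) for c in values.columns}
    return Dataset(values=values, kinds=kinds, roles=roles, levels=levels)


# ---------------------------------------------------------------------------
# Study 3: pleiotropy with 10,000 SNPs, 12 metabolites, one outcome
# ---------------------------------------------------------------------------


@dataclass
class Study3Config:
    """Design of the pleiotropy simulation.

    150 SNPs drive the metabolites through a sparse effect matrix, 75
    distinct SNPs act directly on the outcome Y, and the remaining SNPs
    are null.  Metabolite roles: 4 null, 4 causal on Y, 4 reverse-caused
    by Y, each with coefficient ``causal_beta``.  All residual SDs are 1.
    """

    n: int = 1000
    n_snps_total: int = 10_000
    n_metabolite_snps: int = 150
    n_outcome_snps: int = 75
    n_metabolites: int = 12
    n_per_role: int = 4
    causal_beta: float = 0.3
    residual_sd: float = 1.0
    maf_low: float = 0.01
    maf_high: float = 0.5
    selection_p_threshold: float = 5e-6
    #: probability an individual SNP-metabolite effect is nonzero
    sparsity: float = 0.1
    #: standardized effect magnitude (per allele-SD of the SNP)
    effect_scale: float = 0.3
    effect_scale_sd: float = 0.05

    @property
    def n_null_snps(self) -> int:
        return self.n_snps_total - self.n_metabolite_snps - self.n_outcome_snps

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.n_null_snps < 0:
            raise ValueError("metabolite + outcome SNPs exceed the SNP total")
        if self.n_metabolites != 3 * self.n_per_role:
            raise ValueError("metabolite count must be 3 roles x n_per_role")
        if not 0.0 < self.sparsity <= 1.0:
            raise ValueError("sparsity must lie in (0, 1]")
        if not 0.0 < self.maf_low < self.maf_high <= 0.5:
            raise ValueError("need 0 < maf_low < maf_high <= 0.5")


@dataclass
class EffectTable:
    """Per-allele SNP effects: a sparse SNP x metabolite matrix plus a
    coefficient vector for the outcome-specific SNPs.

    A synthetic stand-in for externally estimated GWAS coefficients; the
    allele frequencies used to scale the effects are carried along so the
    genotype simulator reuses them.
    """

    snp_ids: list[str]
    metabolite_ids: list[str]
    beta: np.ndarray              # (n_metabolite_snps, n_metabolites)
    maf: np.ndarray               # (n_metabolite_snps,)
    outcome_snp_ids: list[str]
    outcome_beta: np.ndarray      # (n_outcome_snps,)
    outcome_maf: np.ndarray       # (n_outcome_snps,)

    def validate(self) -> None:
        if self.beta.shape != (len(self.snp_ids), len(self.metabolite_ids)):
            raise ValueError("beta shape does not match id lists")
        if np.any((self.beta != 0).sum(axis=0) == 0):
            raise ValueError("every metabolite needs >= 1 nonzero SNP effect")

    def write_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.beta, index=self.snp_ids,
                             columns=self.metabolite_ids)
        frame.insert(0, "maf", self.maf)
        frame.to_csv(path, index_label="snp")

    @classmethod
    def read_csv(cls, path: str | Path, outcome_csv: str | Path) -> "EffectTable":
        frame = pd.read_csv(path, index_col="snp")
        maf = frame.pop("maf").to_numpy()
        out = pd.read_csv(outcome_csv, index_col="snp")
        return cls(snp_ids=list(frame.index), metabolite_ids=list(frame.columns),
                   beta=frame.to_numpy(), maf=maf,
                   outcome_snp_ids=list(out.index),
                   outcome_beta=out["beta"].to_numpy(),
                   outcome_maf=out["maf"].to_numpy())


def _effect_magnitudes(rng: np.random.Generator, size: int,
                       config: Study3Config, allele_sd: np.ndarray) -> np.ndarray:
    """Standardized magnitudes ~ |N(scale, scale_sd^2)| with random sign,
    expressed per allele count (divided by the SNP's allele SD)."""
    mag = np.abs(rng.normal(config.effect_scale, config.effect_scale_sd, size))
    sign = rng.choice([-1.0, 1.0], size=size)
    return sign * mag / allele_sd


def generate_snp_effects(config: Study3Config, seed: int) -> EffectTable:
    """Draw a synthetic sparse effect table, reproducible under ``seed``."""
    config.validate()
    rng = np.random.default_rng(seed)
    m, k = config.n_metabolite_snps, config.n_metabolites

    maf = rng.uniform(config.maf_low, config.maf_high, m)
    out_maf = rng.uniform(config.maf_low, config.maf_high, config.n_outcome_snps)
    allele_sd = np.sqrt(2.0 * maf * (1.0 - maf))
    out_sd = np.sqrt(2.0 * out_maf * (1.0 - out_maf))

    mask = rng.random((m, k)) < config.sparsity
    # force coverage: every SNP affects >= 1 metabolite, every metabolite
    # has >= 1 SNP (drawn uniformly where missing)
    for i in np.flatnonzero(~mask.any(axis=1)):
        mask[i, rng.integers(k)] = True
    for j in np.flatnonzero(~mask.any(axis=0)):
        mask[rng.integers(m), j] = True

    beta = np.zeros((m, k))
    idx = np.nonzero(mask)
    beta[idx] = _effect_magnitudes(rng, len(idx[0]), config,
                                   allele_sd[idx[0]])
    out_beta = _effect_magnitudes(rng, config.n_outcome_snps, config, out_sd)

    table = EffectTable(
        snp_ids=[f"snp{i + 1}" for i in range(m)],
        metabolite_ids=[f"M{j + 1}" for j in range(k)],
        beta=beta, maf=maf,
        outcome_snp_ids=[f"snp{m + i + 1}" for i in range(config.n_outcome_snps)],
        outcome_beta=out_beta, outcome_maf=out_maf,
    )
    table.validate()
    return table


def simulate_study3(config: Study3Config, effects: EffectTable,
                    seed: int) -> tuple[Dataset, dict]:
    """Draw one pleiotropy dataset and its ground-truth role map.

    Genotypes are Binomial(2, maf) draws (HWE).  Metabolites are ordered
    null, causal, reverse; the causal set feeds Y together with the
    outcome SNPs, and the reverse set receives ``causal_beta * Y``.
    """
    config.validate()
    effects.validate()
    if effects.beta.shape != (config.n_metabolite_snps, config.n_metabolites):
        raise ValueError("effect table does not match the configuration")
    if len(effects.outcome_beta) != config.n_outcome_snps:
        raise ValueError("outcome coefficient vector does not match the configuration")

    rng = np.random.default_rng(seed)
    n, sd, b = config.n, config.residual_sd, config.causal_beta
    r = config.n_per_role

    null_maf = rng.uniform(config.maf_low, config.maf_high, config.n_null_snps)
    maf_all = np.concatenate([effects.maf, effects.outcome_maf, null_maf])
    G = rng.binomial(2, maf_all, size=(n, config.n_snps_total)).astype(np.int8)

    Gm = G[:, :config.n_metabolite_snps].astype(float)
    Go = G[:, config.n_metabolite_snps:
           config.n_metabolite_snps + config.n_outcome_snps].astype(float)

    genetic = Gm @ effects.beta  # (n, 12) metabolite genetic components
    M = np.empty_like(genetic)
    null_ix = range(0, r)
    causal_ix = range(r, 2 * r)
    reverse_ix = range(2 * r, 3 * r)

    for j in list(null_ix) + list(causal_ix):
        M[:, j] = genetic[:, j] + rng.normal(0.0, sd, n)
    Y = b * M[:, list(causal_ix)].sum(axis=1) + Go @ effects.outcome_beta \
        + rng.normal(0.0, sd, n)
    for j in reverse_ix:
        M[:, j] = genetic[:, j] + b * Y + rng.normal(0.0, sd, n)

    snp_names = (effects.snp_ids + effects.outcome_snp_ids
                 + [f"snp{config.n_metabolite_snps + config.n_outcome_snps + i + 1}"
                    for i in range(config.n_null_snps)])
    met_names = list(effects.metabolite_ids)

    values = pd.DataFrame(G, columns=snp_names)
    for j, name in enumerate(met_names):
        values[name] = M[:, j]
    values["Y"] = Y

    kinds = {c: "continuous" for c in values.columns}
    roles = {c: "instrument" for c in snp_names}
    roles.update({c: "phenotype" for c in met_names})
    roles["Y"] = "outcome"

    role_map = {
        "metabolites": {met_names[j]: role
                        for ix, role in ((null_ix, "null"), (causal_ix, "causal"),
                                         (reverse_ix, "reverse"))
                        for j in ix},
        "metabolite_snps": effects.snp_ids,
        "outcome_snps": effects.outcome_snp_ids,
        "outcome": "Y",
    }
    return Dataset(values=values, kinds=kinds, roles=roles), role_map
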