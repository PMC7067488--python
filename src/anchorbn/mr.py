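"""Mendelian randomization engines.

Implements two-stage least squares (2SLS) with and without the
first-stage-uncertainty correction, weighted allele-score construction
with p-value-thresholded SNP selection, and the MR Steiger procedure
(direction determination via the test for two dependent correlations
sharing one variable, followed by a gated standard MR test).

The uncorrected mode (MR') computes standard errors from the naive
second-stage residuals; for a single instrument its p-value is
algebraically identical to that of regressing the outcome directly on
the instrument.  The corrected mode uses the instrumental-variable
convention: residuals are formed from the observed (not predicted)
exposure, mirroring what dedicated IV regression software reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataset import Dataset

__all__ = [
    "MRResult",
    "SteigerResult",
    "AlleleScore",
    "fit_2sls",
    "build_allele_score",
    "steiger_direction_test",
    "mr_steiger",
]


@dataclass
class MRResult:
    estimate: float
    se: float
    p_value: float
    df: int
    instruments: tuple[str, ...]
    first_stage_p: dict[str, float]
    mode: str                     # "corrected" | "uncorrected"
    valid: bool = True            # False => gated/flagged non-detection
    steiger: "SteigerResult | None" = None


@dataclass
class SteigerResult:
    r_gx: float
    r_gy: float
    r_xy: float
    z_stat: float
    p_value: float
    preferred_exposure: str
    instrument_valid: bool
    first_stage_p: float


@dataclass
class AlleleScore:
    values: np.ndarray
    snp_ids: tuple[str, ...]
    weights: np.ndarray
    selection_threshold: float
    valid: bool = True            # False <=> no SNP passed selection


def _check_variation(name: str, x: np.ndarray) -> None:
    if np.ptp(x) == 0.0:
        raise ValueError(f"column {name!r} has zero variance")


def _marginal_regression_p(g: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and two-sided p-value of the simple regression y ~ 1 + g."""
    n = len(y)
    gc = g - g.mean()
    yc = y - y.mean()
    sxx = gc @ gc
    slope = (gc @ yc) / sxx
    rss = yc @ yc - slope * (gc @ yc)
    sigma2 = max(rss, 0.0) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    if se == 0.0:
        return slope, 0.0
    t = slope / se
    return slope, 2.0 * stats.t.sf(abs(t), n - 2)


def fit_2sls(data: Dataset, exposure: str, outcome: str,
             instruments: list[str] | tuple[str, ...],
             correct_first_stage: bool = True) -> MRResult:
    """Two-stage least squares causal-effect estimate.

    Stage 1 regresses the exposure on the instruments (with intercept);
    stage 2 regresses the outcome on the predicted exposure.  The point
    estimate is identical in both modes; only the residual variance used
    for the standard error differs:

    * ``correct_first_stage=True`` (IV convention): residuals are
      ``outcome - intercept - estimate * observed exposure``;
    * ``False`` (MR'): naive second-stage residuals from the predicted
      exposure.

    The p-value uses a t distribution with n - 2 degrees of freedom.
    """
    instruments = tuple(instruments)
    if not instruments:
        raise ValueError("at least one instrument is required")
    n = data.n
    if n <= len(instruments) + 2:
        raise ValueError("too few observations for the instrument count")

    x = data.column(exposure)
    y = data.column(outcome)
    _check_variation(exposure, x)
    Z = np.column_stack([np.ones(n)] + [data.column(g) for g in instruments])
    for g in instruments:
        _check_variation(g, data.column(g))
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("instruments are perfectly collinear")

    coef1, *_ = np.linalg.lstsq(Z, x, rcond=None)
    xhat = Z @ coef1

    X2 = np.column_stack([np.ones(n), xhat])
    coef2, *_ = np.linalg.lstsq(X2, y, rcond=None)
    intercept, estimate = coef2

    if correct_first_stage:
        resid = y - intercept - estimate * x
        mode = "corrected"
    else:
        resid = y - intercept - estimate * xhat
        mode = "uncorrected"
    df = n - 2
    sigma2 = (resid @ resid) / df
    xtx_inv = np.linalg.inv(X2.T @ X2)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    t = estimate / se
    p = float(2.0 * stats.t.sf(abs(t), df))

    first_stage = {g: _marginal_regression_p(data.column(g), x)[1]
                   for g in instruments}
    return MRResult(estimate=float(estimate), se=se, p_value=p, df=df,
                    instruments=instruments, first_stage_p=first_stage,
                    mode=mode)


def build_allele_score(data: Dataset, snps: list[str], target: str,
                       weights: np.ndarray | None = None,
                       selection_threshold: float = 5e-6) -> AlleleScore:
    """Weighted allele score over SNPs associated with ``target``.

    With ``weights`` omitted, each SNP is regressed marginally on the
    target; SNPs with p below ``selection_threshold`` are selected and
    weighted by their estimated regression coefficient.  An empty
    selection yields a flagged (``valid=False``) all-zero score rather
    than an exception, so replicate loops stay alive.

    With explicit ``weights`` (one per SNP, external provenance), all
    SNPs are used as given.
    """
    G = np.column_stack([data.column(s) for s in snps])
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(snps):
            raise ValueError("one weight per SNP is required")
        return AlleleScore(values=G @ w, snp_ids=tuple(snps), weights=w,
                           selection_threshold=selection_threshold)

    y = data.column(target)
    n = len(y)
    yc = y - y.mean()
    Gc = G - G.mean(axis=0)
    sxx = (Gc * Gc).sum(axis=0)
    sxy = Gc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
        rss = yc @ yc - slope * sxy
        sigma2 = np.maximum(rss, 0.0) / (n - 2)
        se = np.sqrt(np.where(sxx > 0, sigma2 / np.where(sxx > 0, sxx, 1.0), np.inf))
        tstat = np.where(se > 0, slope / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), n - 2)

    keep = np.flatnonzero(pvals < selection_threshold)
    if keep.size == 0:
        return AlleleScore(values=np.zeros(n), snp_ids=(),
                           weights=np.empty(0),
                           selection_threshold=selection_threshold,
                           valid=False)
    w = slope[keep]
    return AlleleScore(values=G[:, keep] @ w,
                       snp_ids=tuple(snps[i] for i in keep), weights=w,
                       selection_threshold=selection_threshold)


def _steiger_z(r_ja: float, r_jb: float, r_ab: float, n: int) -> tuple[float, float]:
    """Steiger (1980) Z test for two dependent correlations sharing
    variable j, via Fisher z-transforms (the psych::r.test form)."""
    z_ja = np.arctanh(r_ja)
    z_jb = np.arctanh(r_jb)
    rm2 = (r_ja ** 2 + r_jb ** 2) / 2.0
    f = min((1.0 - r_ab) / (2.0 * (1.0 - rm2)), 1.0)
    h = (1.0 - f * rm2) / (1.0 - rm2)
    denom = 2.0 * (1.0 - r_ab) * h
    if denom <= 0.0:
        return 0.0, 1.0
    z = (z_ja - z_jb) * np.sqrt((n - 3) / denom)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def steiger_direction_test(data: Dataset, instrument: str, trait_a: str,
                           trait_b: str, threshold: float = 0.05) -> SteigerResult:
    """Decide which of two traits an instrument is more suitable for.

    Compares |cor(instrument, trait_a)| with |cor(instrument, trait_b)|
    using the dependent-correlations Z test; the preferred exposure is
    the trait with the larger absolute correlation.  The instrument is
    declared valid for ``trait_a`` only if its first-stage association
    with trait_a and the direction test both pass ``threshold`` and
    trait_a is the preferred exposure.
    """
    g = data.column(instrument)
    a = data.column(trait_a)
    b = data.column(trait_b)
    for name, col in ((instrument, g), (trait_a, a), (trait_b, b)):
        _check_variation(name, col)
    n = data.n

    r_ga = float(np.corrcoef(g, a)[0, 1])
    r_gb = float(np.corrcoef(g, b)[0, 1])
    r_ab = float(np.corrcoef(a, b)[0, 1])
    # the test compares correlation magnitudes (suitability), not signs
    z, p = _steiger_z(abs(r_ga), abs(r_gb), r_ab, n)

    preferred = trait_a if abs(r_ga) >= abs(r_gb) else trait_b
    _, first_p = _marginal_regression_p(g, a)
    valid = (first_p < threshold) and (p < threshold) and (preferred == trait_a)
    return SteigerResult(r_gx=r_ga, r_gy=r_gb, r_xy=r_ab, z_stat=z,
                         p_value=p, preferred_exposure=preferred,
                         instrument_valid=valid, first_stage_p=first_p)


def mr_steiger(data: Dataset, instrument: str, exposure: str, outcome: str,
               threshold: float = 0.05,
               correct_first_stage: bool = True) -> MRResult:
    """MR Steiger: direction-gated Mendelian randomization.

    Runs the Steiger direction test for the candidate instrument; if the
    instrument is not valid for the requested exposure, returns a flagged
    non-detection (p-value sentinel 1.0) instead of raising, so that
    replicate loops record the outcome.  Otherwise returns the standard
    2SLS result annotated with the Steiger decision.
    """
    st = steiger_direction_test(data, instrument, exposure, outcome, threshold)
    if not st.instrument_valid:
        return MRResult(estimate=np.nan, se=np.nan, p_value=1.0,
                        df=data.n - 2, instruments=(instrument,),
                        first_stage_p={instrument: st.first_stage_p},
                        mode="corrected" if correct_first_stage else "uncorrected",
                        valid=False, steiger=st)
    res = fit_2sls(data, exposure, outcome, [instrument],
                   correct_first_stage=correct_first_stage)
    res.steiger = st
    return res
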