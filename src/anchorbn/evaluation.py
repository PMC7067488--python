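"""Replicate-level evaluation: power, type-I error, ROC curves.

``run_experiment`` orchestrates the quantitative-trait study: for each
replicate it simulates a dataset, runs the configured analyses --
Mendelian randomization with G instrumenting X (testing X to Y) or Z
instrumenting Y (testing Y to X), in corrected and uncorrected (MR')
modes, MR Steiger with either candidate instrument, and anchored
Bayesian networks over {X, Y} plus any subset of {G, Z} -- and records
the per-replicate evidence (p-values for MR-type methods; bootstrap
probabilities of a directed edge for BN).  Detection proportions at
p-value or probability thresholds, their Monte-Carlo standard errors,
and ROC curves are computed from the recorded values.

The pleiotropy study is exposed through ``analyse_study3_replicate``
plus allele-score constraint builders for the one-metabolite (B1) and
all-metabolite (B12) network layouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .averaging import AveragedNetwork, bootstrap_average
from .bn import ConstraintSet
from .dataset import Dataset
from .mr import build_allele_score, fit_2sls, mr_steiger
from .simulate import Study1Params, simulate_study1

__all__ = [
    "ExperimentConfig",
    "EvaluationResult",
    "run_experiment",
    "estimate_power",
    "roc_curve",
    "direction_probability_summary",
    "study3_b1_constraints",
    "study3_b12_constraints",
    "analyse_study3_replicate",
]

#: study-1 analyses; "p" methods yield p-values, "prob" methods yield
#: directed-edge probabilities for the tested direction
STUDY1_METHODS = ("MR(G)", "MR'(G)", "MR(Z)", "MR'(Z)", "St(G)", "St(Z)",
                  "BN(G,Z)", "BN(G)", "BN(Z)")


@dataclass
class ExperimentConfig:
    """Replicate grid for the quantitative-trait study.

    ``effect`` is the active causal coefficient (beta_XY for
    ``direction='x_to_y'``, beta_YX otherwise); ``test_edge`` names the
    directed relationship whose detection is being evaluated.
    """

    model: int = 1
    confounding: str = "weak"
    effect: float = 0.5
    direction: str = "x_to_y"
    test_edge: tuple[str, str] = ("X", "Y")
    n: int = 2500
    replicates: int = 1000
    seed: int = 0
    methods: tuple[str, ...] = STUDY1_METHODS
    bn_bootstraps: int = 1000
    alpha: float = 0.05
    alpha_grid: tuple[float, ...] = (0.01, 0.05, 0.1)
    prob_grid: tuple[float, ...] = (0.7, 0.8, 0.9)

    def validate(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for v in self.alpha_grid + self.prob_grid:
            if not 0.0 < v < 1.0:
                raise ValueError("grid thresholds must lie in (0, 1)")
        unknown = set(self.methods) - set(STUDY1_METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")


@dataclass
class EvaluationResult:
    """Per-replicate evidence values plus aggregate detection table."""

    config: ExperimentConfig
    values: dict[str, np.ndarray]          # method -> replicate values
    modes: dict[str, str]                  # method -> "pvalue" | "probability"
    failures: dict[str, int] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Detection proportion and MC standard error per method/threshold."""
        rows = []
        cfg = self.config
        for method, vals in self.values.items():
            mode = self.modes[method]
            grid = cfg.alpha_grid if mode == "pvalue" else cfg.prob_grid
            for thr in grid:
                prop, se = estimate_power(vals, thr, mode)
                rows.append({"method": method, "mode": mode, "threshold": thr,
                             "proportion": prop, "mc_se": se})
        return pd.DataFrame(rows)


def _bn_methods_spec(method: str) -> list[str]:
    inner = method[3:-1]  # "BN(G,Z)" -> "G,Z"
    return [s for s in inner.split(",") if s]


def _run_replicate(cfg: ExperimentConfig, rep: int) -> dict[str, float]:
    params = Study1Params.preset(cfg.model, cfg.confounding, cfg.effect,
                                 cfg.direction, n=cfg.n)
    sim_seed = np.random.default_rng([cfg.seed, rep]).integers(2 ** 31)
    data = simulate_study1(params, int(sim_seed))
    a, b = cfg.test_edge
    out: dict[str, float] = {}
    for method in cfg.methods:
        if method in ("MR(G)", "MR'(G)"):
            res = fit_2sls(data, "X", "Y", ["G"],
                           correct_first_stage=(method == "MR(G)"))
            val = res.p_value if cfg.test_edge == ("X", "Y") else 1.0
        elif method in ("MR(Z)", "MR'(Z)"):
            res = fit_2sls(data, "Y", "X", ["Z"],
                           correct_first_stage=(method == "MR(Z)"))
            val = res.p_value if cfg.test_edge == ("Y", "X") else 1.0
        elif method in ("St(G)", "St(Z)"):
            inst = method[3:-1]
            res = mr_steiger(data, inst, a, b, threshold=cfg.alpha)
            val = res.p_value
        elif method.startswith("BN("):
            anchors = _bn_methods_spec(method)
            nodes = anchors + ["X", "Y"]
            cs = ConstraintSet.no_incoming(anchors, nodes)
            net = bootstrap_average(data.subset(nodes), constraints=cs,
                                    B=cfg.bn_bootstraps,
                                    seed=int(sim_seed))
            val = net.directed_prob(a, b)
        else:  # pragma: no cover - guarded by validate()
            raise ValueError(method)
        out[method] = float(val)
    return out


def run_experiment(config: ExperimentConfig) -> EvaluationResult:
    """Run the replicate loop and collect per-method evidence values.

    Fully reproducible: replicate r derives its simulation and bootstrap
    seeds from (config.seed, r).  A method failure in one replicate is
    recorded (value NaN, counted in ``failures``) without aborting the
    experiment.
    """
    config.validate()
    values = {m: np.full(config.replicates, np.nan) for m in config.methods}
    failures = {m: 0 for m in config.methods}
    for rep in range(config.replicates):
        try:
            out = _run_replicate(config, rep)
        except Exception:
            for m in config.methods:
                failures[m] += 1
            continue
        for m, v in out.items():
            values[m][rep] = v
    modes = {m: ("probability" if m.startswith("BN(") else "pvalue")
             for m in config.methods}
    return EvaluationResult(config=config, values=values, modes=modes,
                            failures=failures)


def estimate_power(values: np.ndarray, threshold: float,
                   mode: str = "pvalue") -> tuple[float, float]:
    """Detection proportion and its Monte-Carlo standard error.

    ``pvalue`` mode counts values strictly below the threshold;
    ``probability`` mode counts values strictly above it.  NaNs (failed
    replicates) count as non-detections but stay in the denominator.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    ok = ~np.isnan(values)
    if mode == "pvalue":
        detected = np.count_nonzero(values[ok] < threshold)
    elif mode == "probability":
        detected = np.count_nonzero(values[ok] > threshold)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    r = values.size
    p = detected / r
    return p, float(np.sqrt(p * (1.0 - p) / r))


def roc_curve(h1_values: np.ndarray, h0_values: np.ndarray,
              mode: str = "pvalue") -> pd.DataFrame:
    """ROC points from replicate evidence under effect and null models.

    Sweeps the detection threshold over the pooled values (plus the
    degenerate endpoints): x = detection proportion in the null set
    (false positives), y = in the effect set (true positives).  The null
    set may come from a no-effect model or from a wrong-direction model.
    Points are ordered from the strictest threshold, (0, 0), to the most
    permissive, (1, 1).
    """
    h1 = np.asarray(h1_values, dtype=float)
    h0 = np.asarray(h0_values, dtype=float)
    if h1.size == 0 or h0.size == 0:
        raise ValueError("both value sets must be non-empty")
    pooled = np.unique(np.concatenate([h1, h0]))
    if mode == "pvalue":
        thresholds = np.concatenate([[0.0], pooled, [np.inf]])
    elif mode == "probability":
        thresholds = np.concatenate([[np.inf], pooled[::-1], [-np.inf]])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for t in thresholds:
        fpr, _ = estimate_power(h0, t, mode)
        tpr, _ = estimate_power(h1, t, mode)
        rows.append({"threshold": t, "fpr": fpr, "tpr": tpr})
    return pd.DataFrame(rows)


def direction_probability_summary(nets: list[AveragedNetwork],
                                  pair: tuple[str, str]) -> pd.DataFrame:
    """Five-number summaries of directed-edge probabilities across
    replicates, for both orientations of ``pair`` (box-plot statistics).
    """
    if not nets:
        raise ValueError("at least one replicate network is required")
    a, b = pair
    rows = []
    for frm, to in ((a, b), (b, a)):
        vals = np.array([net.directed_prob(frm, to) for net in nets])
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
        rows.append({"edge": f"{frm}->{to}", "min": vals.min(), "q1": q1,
                     "median": med, "q3": q3, "max": vals.max()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pleiotropy-study (study 3) analysis helpers
# ---------------------------------------------------------------------------


def study3_b1_constraints(metabolite: str, outcome: str = "Y") -> tuple[list[str], ConstraintSet]:
    """Nodes and constraints for the one-metabolite network layout:
    {metabolite, outcome, their two allele scores}, each score pinned to
    a single outgoing edge into its instrumented variable."""
    score_m, score_y = f"score_{metabolite}", f"score_{outcome}"
    nodes = [score_m, score_y, metabolite, outcome]
    cs = ConstraintSet()
    cs.add_single_outgoing(score_m, metabolite, nodes)
    cs.add_single_outgoing(score_y, outcome, nodes)
    return nodes, cs


def study3_b12_constraints(metabolites: list[str], outcome: str = "Y") -> tuple[list[str], ConstraintSet]:
    """Nodes and constraints for the all-metabolite layout: all
    metabolites, the outcome, and one pinned allele score per variable."""
    targets = list(metabolites) + [outcome]
    scores = [f"score_{t}" for t in targets]
    nodes = scores + targets
    cs = ConstraintSet()
    for s, t in zip(scores, targets):
        cs.add_single_outgoing(s, t, nodes)
    return nodes, cs


def analyse_study3_replicate(data: Dataset, role_map: dict,
                             snp_names: list[str] | None = None,
                             selection_threshold: float = 5e-6,
                             B: int = 200, seed: int = 0,
                             layout: str = "B1",
                             metabolites: list[str] | None = None) -> pd.DataFrame:
    """Per-metabolite bidirectional tests on one pleiotropy dataset.

    For each metabolite M (and the outcome Y), a weighted allele score
    is rebuilt within the replicate from SNPs passing the selection
    threshold.  MR tests M -> Y (score(M) instrumenting M) and Y -> M
    (score(Y) instrumenting Y); the BN layout (B1 per metabolite, or a
    single B12 network) yields directed-edge probabilities for both
    orientations.  Returns one row per metabolite with columns
    ``mr_p_my``, ``mr_p_ym``, ``bn_prob_my``, ``bn_prob_ym`` and the
    ground-truth role.
    """
    if metabolites is None:
        metabolites = list(role_map["metabolites"])
    outcome = role_map.get("outcome", "Y")
    if snp_names is None:
        snp_names = [c for c, r in data.roles.items() if r == "instrument"]

    scores = {}
    for target in metabolites + [outcome]:
        sc = build_allele_score(data, snp_names, target,
                                selection_threshold=selection_threshold)
        scores[target] = sc

    # augmented frame holding the score columns
    aug = data.values[metabolites + [outcome]].copy()
    kinds = {c: "continuous" for c in aug.columns}
    roles = {c: data.roles[c] for c in aug.columns}
    for target, sc in scores.items():
        col = f"score_{target}"
        aug[col] = sc.values
        kinds[col] = "continuous"
        roles[col] = "score"

    rows = []
    b12_net = None
    if layout == "B12":
        usable = [m for m in metabolites if scores[m].valid]
        nodes, cs = study3_b12_constraints(usable, outcome)
        aug_ds = Dataset(values=aug[nodes].copy(),
                         kinds={c: kinds[c] for c in nodes},
                         roles={c: roles[c] for c in nodes})
        b12_net = bootstrap_average(aug_ds, constraints=cs, B=B, seed=seed)

    for m in metabolites:
        row = {"metabolite": m, "role": role_map["metabolites"][m],
               "score_valid": scores[m].valid}
        aug_ds = None
        if scores[m].valid and scores[outcome].valid:
            mr_my = _score_mr(aug, kinds, roles, f"score_{m}", m, outcome)
            mr_ym = _score_mr(aug, kinds, roles, f"score_{outcome}", outcome, m)
            row["mr_p_my"] = mr_my.p_value
            row["mr_p_ym"] = mr_ym.p_value
            if layout == "B1":
                nodes, cs = study3_b1_constraints(m, outcome)
                aug_ds = Dataset(values=aug[nodes].copy(),
                                 kinds={c: kinds[c] for c in nodes},
                                 roles={c: roles[c] for c in nodes})
                net = bootstrap_average(aug_ds, constraints=cs, B=B,
                                        seed=seed)
            else:
                net = b12_net
            row["bn_prob_my"] = net.directed_prob(m, outcome)
            row["bn_prob_ym"] = net.directed_prob(outcome, m)
        else:
            row.update(mr_p_my=1.0, mr_p_ym=1.0,
                       bn_prob_my=0.0, bn_prob_ym=0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def _score_mr(aug: pd.DataFrame, kinds: dict, roles: dict,
              score_col: str, exposure: str, outcome: str):
    cols = [score_col, exposure, outcome]
    ds = Dataset(values=aug[cols].copy(),
                 kinds={c: kinds[c] for c in cols},
                 roles={c: roles[c] for c in cols})
    return fit_2sls(ds, exposure, outcome, [score_col],
                    correct_first_stage=False)
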