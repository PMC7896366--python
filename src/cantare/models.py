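"""Neighborhood-seeded logistic models: fitting, backward-AIC reduction,
scoring, effect sizes, and de-duplication.

Each qualifying network neighborhood seeds one logistic regression for the
binary outcome: the full model contains the neighborhood's analytes plus
the clinical covariates, and backward selection with AIC as the criterion
removes one predictor at a time while any single removal lowers the AIC.
The reduced model is scored by in-sample AUC (the concordance
probability), and each coefficient is reported as an odds ratio over the
predictor's interquartile range — or over its overall range when the first
and third quartiles coincide (typical for zero-heavy microbes).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from cantare.dataset_io import OmicsDataset
from cantare.network import Neighborhood

logger = logging.getLogger(__name__)

MAX_IRLS_ITER = 25
SEPARATION_EPS = 1e-10
#: |log-odds per predictor SD| beyond this is treated as coefficient blow-up
SEPARATION_COEF_GUARD = 15.0


@dataclass
class LogisticFit:
    """A maximum-likelihood logistic regression fit.

    ``params`` maps 'intercept' and each predictor name to its coefficient
    (log-odds per unit). ``converged`` is False when IRLS hits the
    iteration cap or the fit shows quasi-complete separation (some fitted
    probability within ``SEPARATION_EPS`` of 0 or 1).
    """

    predictors: list[str]
    params: dict[str, float]
    aic: float
    llf: float
    converged: bool
    probabilities: np.ndarray
    n: int
    dropped_constant: list[str] = field(default_factory=list)


@dataclass
class EffectSize:
    """Odds ratio for one predictor over its IQR (or range when Q1 == Q3)."""

    predictor: str
    kind: str  # "IQR" | "range"
    q1: float
    q3: float
    odds_ratio: float


@dataclass
class NeighborhoodModel:
    """One neighborhood-seeded logistic model, full and reduced."""

    seed: str
    full_predictors: list[str]
    reduced_predictors: list[str]
    coefficients: dict[str, float]
    aic_full: float
    aic_reduced: float
    converged: bool
    auc: float = np.nan
    probabilities: np.ndarray | None = None
    effect_sizes: list[EffectSize] = field(default_factory=list)
    seeds: list[str] = field(default_factory=list)  # filled by dedupe_models
    note: str = ""


def _design(data: pd.DataFrame, predictors: list[str]) -> pd.DataFrame:
    X = data[predictors].astype(float).copy()
    X.insert(0, "intercept", 1.0)
    return X


def _glm_fit(data: pd.DataFrame, y: np.ndarray, predictors: list[str]) -> LogisticFit:
    X = _design(data, predictors)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=MAX_IRLS_ITER)
    probs = np.asarray(res.fittedvalues, dtype=float)
    # quasi-complete separation: a fitted probability numerically at 0/1
    # together with coefficient blow-up (a huge per-SD log-odds)
    extreme = bool(
        np.any(probs <= SEPARATION_EPS) or np.any(probs >= 1.0 - SEPARATION_EPS)
    )
    blowup = False
    for name in predictors:
        sd = float(np.std(X[name].to_numpy(), ddof=1))
        if abs(res.params[name]) * sd > SEPARATION_COEF_GUARD:
            blowup = True
            break
    converged = bool(getattr(res, "converged", True)) and not (extreme and blowup)
    # keep reported probabilities in the open interval even when IRLS
    # rounds a fitted value to exactly 0 or 1
    probs = np.clip(probs, 1e-15, 1.0 - 1e-15)
    return LogisticFit(
        predictors=list(predictors),
        params={k: float(v) for k, v in res.params.items()},
        aic=float(res.aic),
        llf=float(res.llf),
        converged=converged,
        probabilities=probs,
        n=len(y),
    )


def fit_logistic(
    data: pd.DataFrame | OmicsDataset,
    outcome: np.ndarray | None = None,
    predictors: list[str] | None = None,
    covariates: list[str] = (),
) -> LogisticFit:
    """Maximum-likelihood logistic regression of a binary outcome.

    ``data`` may be a plain DataFrame (with ``outcome`` given explicitly)
    or an :class:`OmicsDataset`, in which case ``predictors`` name analytes
    and ``covariates`` name metadata columns and the dataset's group label
    is the outcome. Constant predictors are dropped with a warning before
    fitting. AIC is 2k - 2 logL with k counting the intercept.
    """
    if isinstance(data, OmicsDataset):
        frame = data.predictor_frame(list(predictors or []), list(covariates))
        y = data.group.astype(float)
    else:
        frame = data
        if outcome is None:
            raise ValueError("outcome required when data is a DataFrame")
        y = np.asarray(outcome, dtype=float)
        frame = frame[list(predictors) if predictors is not None else frame.columns]
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    keep, dropped = [], []
    for col in frame.columns:
        if np.ptp(frame[col].to_numpy(dtype=float)) == 0.0:
            dropped.append(col)
        else:
            keep.append(col)
    if dropped:
        logger.warning("dropping constant predictor(s): %s", dropped)
    if not keep:
        raise ValueError("no non-constant predictors left to fit")
    fit = _glm_fit(frame, y, keep)
    fit.dropped_constant = dropped
    return fit


def backward_aic(
    data: pd.DataFrame,
    outcome: np.ndarray,
    predictors: list[str],
    force_keep: tuple[str, ...] = (),
) -> LogisticFit:
    """Backward elimination on AIC: drop single terms while any drop helps.

    Each step refits the model with each removable predictor deleted and
    accepts the removal with the lowest AIC if it is below the current
    AIC. Exact AIC ties are broken by removing the predictor that sorts
    later by name, so runs are reproducible. Candidate refits that fail to
    converge are skipped (logged). The intercept-only model is reachable.
    """
    y = np.asarray(outcome, dtype=float)
    current = _glm_fit(data, y, list(predictors))
    while current.predictors:
        best: LogisticFit | None = None
        best_removed: str | None = None
        # later-sorting names first so equal-AIC candidates resolve to the
        # latest name (ties keep the first strictly-better candidate seen)
        for name in sorted(current.predictors, reverse=True):
            if name in force_keep:
                continue
            trial = _glm_fit(data, y, [p for p in current.predictors if p != name])
            if trial.predictors and not trial.converged:
                logger.info("skipping non-converged candidate (drop %s)", name)
                continue
            if best is None or trial.aic < best.aic:
                best, best_removed = trial, name
        if best is None or best.aic >= current.aic:
            break
        logger.debug("backward AIC: removed %s (AIC %.3f -> %.3f)",
                     best_removed, current.aic, best.aic)
        current = best
    return current


def auc(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Concordance AUC: (concordant + 0.5 * tied) / (case x control pairs).

    Computed via the rank (Mann-Whitney) identity, which handles ties with
    the 0.5 credit exactly.
    """
    probs = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    ranks = rankdata(probs)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def effect_sizes(model: LogisticFit, data: pd.DataFrame) -> list[EffectSize]:
    """Per-predictor odds ratios over the IQR, sorted ascending.

    OR = exp(beta * (Q3 - Q1)) with linear-interpolation (type-7)
    quantiles computed on the analysis samples; when Q1 equals Q3 the
    overall range substitutes and the entry is marked kind="range".
    """
    out = []
    for name in model.predictors:
        beta = model.params[name]
        x = data[name].to_numpy(dtype=float)
        q1, q3 = np.quantile(x, [0.25, 0.75], method="linear")
        if q1 == q3:
            lo, hi = float(x.min()), float(x.max())
            out.append(
                EffectSize(name, "range", lo, hi, float(np.exp(beta * (hi - lo))))
            )
        else:
            out.append(
                EffectSize(
                    name, "IQR", float(q1), float(q3),
                    float(np.exp(beta * (q3 - q1))),
                )
            )
    return sorted(out, key=lambda e: e.odds_ratio)


def run_neighborhood_models(
    dataset: OmicsDataset,
    neighborhoods: list[Neighborhood],
    covariates: tuple[str, ...] = ("age", "calprotectin"),
    force_keep: tuple[str, ...] = (),
) -> list[NeighborhoodModel]:
    """Fit, reduce, and score one logistic model per neighborhood.

    Per neighborhood: full fit on members + covariates, backward-AIC
    reduction, then AUC, per-sample probabilities, and effect sizes.
    Models that fail to converge are reported with ``converged=False`` and
    no downstream statistics; the run continues.
    """
    out: list[NeighborhoodModel] = []
    for hood in sorted(neighborhoods, key=lambda h: h.seed):
        members = sorted(m for m in hood.members if m in dataset.registry)
        try:
            frame = dataset.predictor_frame(members, covariates)
        except KeyError as exc:
            out.append(
                NeighborhoodModel(
                    seed=hood.seed, full_predictors=[], reduced_predictors=[],
                    coefficients={}, aic_full=np.nan, aic_reduced=np.nan,
                    converged=False, note=f"unresolvable predictors: {exc}",
                )
            )
            continue
        y = dataset.group
        try:
            full = fit_logistic(frame, y)
        except ValueError as exc:
            out.append(
                NeighborhoodModel(
                    seed=hood.seed,
                    full_predictors=list(frame.columns),
                    reduced_predictors=[], coefficients={},
                    aic_full=np.nan, aic_reduced=np.nan,
                    converged=False, note=str(exc),
                )
            )
            continue
        if not full.converged:
            out.append(
                NeighborhoodModel(
                    seed=hood.seed, full_predictors=full.predictors,
                    reduced_predictors=[], coefficients={},
                    aic_full=full.aic, aic_reduced=np.nan, converged=False,
                    note="full model failed to converge",
                )
            )
            continue
        reduced = backward_aic(frame, y, full.predictors, force_keep=force_keep)
        out.append(
            NeighborhoodModel(
                seed=hood.seed,
                full_predictors=full.predictors,
                reduced_predictors=reduced.predictors,
                coefficients=reduced.params,
                aic_full=full.aic,
                aic_reduced=reduced.aic,
                converged=reduced.converged,
                auc=auc(reduced.probabilities, y),
                probabilities=reduced.probabilities,
                effect_sizes=effect_sizes(reduced, frame),
            )
        )
    return out


def dedupe_models(models: list[NeighborhoodModel]) -> list[NeighborhoodModel]:
    """Collapse models with identical (unordered) reduced predictor sets.

    The first model (by seed order) represents each unique predictor set;
    its ``seeds`` field lists every contributing seed. Non-converged
    records pass through untouched.
    """
    unique: dict[frozenset[str], NeighborhoodModel] = {}
    passthrough: list[NeighborhoodModel] = []
    for model in sorted(models, key=lambda m: m.seed):
        if not model.converged:
            passthrough.append(model)
            continue
        key = frozenset(model.reduced_predictors)
        if key in unique:
            unique[key].seeds.append(model.seed)
        else:
            model.seeds = [model.seed]
            unique[key] = model
    return list(unique.values()) + passthrough


def model_report(models: list[NeighborhoodModel]) -> pd.DataFrame:
    """Flat per-model summary table (CSV/JSON-exportable)."""
    rows = []
    for m in models:
        rows.append(
            {
                "seed": m.seed,
                "seeds": ";".join(m.seeds or [m.seed]),
                "n_full": len(m.full_predictors),
                "n_reduced": len(m.reduced_predictors),
                "reduced_predictors": ";".join(m.reduced_predictors),
                "aic_full": m.aic_full,
                "aic_reduced": m.aic_reduced,
                "auc": m.auc,
                "converged": m.converged,
                "note": m.note,
            }
        )
    return pd.DataFrame(rows)
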