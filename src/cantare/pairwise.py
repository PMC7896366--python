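"""Pairwise cross-ome regressions, influence filtering, and top-table selection.

For every (response analyte, predictor analyte) pair drawn from two
different omes we fit either

* **interaction mode** — OLS on ``y ~ 1 + group + x + group:x``, where the
  target term is the interaction coefficient (beta3): it measures how much
  the analyte-analyte slope differs between the two outcome groups; or
* **correlation mode** — simple linear regression ``y ~ 1 + x``, whose
  slope p-value equals the Pearson-correlation p-value.

Fits driven by influential observations (max |DFFITS| >= 4) and fits
involving rarely observed analytes (non-zero in fewer than 10% of samples)
are excluded, and the surviving fits with the smallest target-term
p-values (capped per assay pair, below a significance threshold) form the
"top table" from which the analyte network is built.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from cantare.dataset_io import OmicsDataset

logger = logging.getLogger(__name__)

DFFITS_MAX_DEFAULT = 4.0


@dataclass
class PairwiseFit:
    """One cross-ome regression between a response and a predictor analyte.

    In interaction mode the coefficients are (beta0, beta1, beta2, beta3) =
    (intercept, group main effect, predictor slope, group x predictor
    interaction) and ``p_target`` is the two-sided t-test p-value of beta3.
    In correlation mode only beta0 (intercept) and beta2 (slope) exist and
    ``p_target`` is the slope p-value. ``p_target`` is NaN when the residual
    variance is zero (p undefined). Invalid fits (rank-deficient designs)
    carry ``valid=False`` and a reason.
    """

    response: str
    predictor: str
    mode: str  # "interaction" | "correlation"
    beta0: float = np.nan
    beta1: float | None = None
    beta2: float = np.nan
    beta3: float | None = None
    p_target: float = np.nan
    t_target: float = np.nan
    max_abs_dffits: float = np.nan
    n: int = 0
    valid: bool = True
    reason: str = ""
    response_ome: str | None = None
    predictor_ome: str | None = None

    @property
    def assay_pair(self) -> tuple[str, str]:
        return (self.response_ome or "?", self.predictor_ome or "?")


@dataclass
class TopTable:
    """Per-assay-pair selection of the best-ranked pairwise fits."""

    entries: list[PairwiseFit]
    per_pair_cap: int = 35
    alpha: float = 0.05
    #: exclusion bookkeeping: reason -> count
    exclusions: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# least-squares core
# ---------------------------------------------------------------------------


def _ols(X: np.ndarray, y: np.ndarray) -> dict:
    """QR-based OLS with coefficient tests, leverages and DFFITS.

    Returns a dict with keys beta, se, t, p, resid, leverage, dffits, rss,
    df (residual degrees of freedom). Raises LinAlgError-like ValueError on
    rank deficiency.
    """
    n, p = X.shape
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    if diag.min() <= max(n, p) * np.finfo(float).eps * max(diag.max(), 1.0):
        raise np.linalg.LinAlgError("rank-deficient design")
    beta = np.linalg.solve(R, Q.T @ y)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    df = n - p
    leverage = np.einsum("ij,ij->i", Q, Q)
    sigma2 = rss / df if df > 0 else np.nan
    Rinv = np.linalg.solve(R, np.eye(p))
    se = np.sqrt(sigma2 * np.einsum("ij,ij->i", Rinv, Rinv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p_vals = 2.0 * stats.t.sf(np.abs(t), df) if df > 0 else np.full(p, np.nan)
    return {
        "beta": beta,
        "se": se,
        "t": t,
        "p": p_vals,
        "resid": resid,
        "leverage": leverage,
        "rss": rss,
        "df": df,
        "sigma2": sigma2,
    }


def _dffits(resid: np.ndarray, leverage: np.ndarray, rss: float, df: int) -> np.ndarray:
    """DFFITS_i = externally studentized residual_i * sqrt(h_i / (1 - h_i)).

    Equals the standardized change in the i-th fitted value when
    observation i is left out. A leverage of exactly 1 (an exact-fit point)
    yields an infinite DFFITS.
    """
    one_minus_h = 1.0 - leverage
    exact = one_minus_h <= np.finfo(float).eps * 8
    safe = np.where(exact, np.nan, one_minus_h)
    # leave-one-out residual variance: s_(i)^2 = (rss - e_i^2/(1-h_i)) / (df - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2_loo = (rss - resid**2 / safe) / (df - 1)
        s2_loo = np.clip(s2_loo, 0.0, None)
        r_ext = resid / np.sqrt(s2_loo * safe)
        out = r_ext * np.sqrt(leverage / safe)
    out[exact] = np.inf
    return out


def max_abs_dffits(X: np.ndarray, y: np.ndarray) -> float:
    """Maximum absolute DFFITS over observations for a least-squares fit.

    Requires n > p + 1 so that the leave-one-out residual variance is
    defined. Exact-fit points (leverage 1) make the maximum infinite; a fit
    with zero residual everywhere has undefined influence and returns NaN.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 for DFFITS (n={n}, p={p})")
    res = _ols(X, y)
    if res["rss"] <= np.finfo(float).eps * max(1.0, float(y @ y)):
        return np.nan
    d = _dffits(res["resid"], res["leverage"], res["rss"], res["df"])
    return float(np.nanmax(np.abs(d)))


def _finish_fit(fit: PairwiseFit, X: np.ndarray, y: np.ndarray, target: int) -> PairwiseFit:
    try:
        res = _ols(X, y)
    except np.linalg.LinAlgError:
        return replace(fit, valid=False, reason="rank-deficient design")
    zero_resid = res["rss"] <= np.finfo(float).eps * max(1.0, float(y @ y)) * len(y)
    beta = res["beta"]
    if fit.mode == "interaction":
        fit = replace(fit, beta0=beta[0], beta1=beta[1], beta2=beta[2], beta3=beta[3])
    else:
        fit = replace(fit, beta0=beta[0], beta2=beta[1])
    if zero_resid:
        return replace(
            fit, p_target=np.nan, t_target=np.nan, max_abs_dffits=np.nan,
            reason="zero residual variance; p undefined",
        )
    d = _dffits(res["resid"], res["leverage"], res["rss"], res["df"])
    return replace(
        fit,
        p_target=float(res["p"][target]),
        t_target=float(res["t"][target]),
        max_abs_dffits=float(np.nanmax(np.abs(d))),
    )


def fit_pair_interaction(
    y: np.ndarray,
    x: np.ndarray,
    group: np.ndarray,
    response: str = "y",
    predictor: str = "x",
) -> PairwiseFit:
    """OLS of y on [1, group, x, group*x]; target term is the interaction.

    The fitted group-0 line is ``beta0 + beta2 * x`` and the group-1 line is
    ``(beta0 + beta1) + (beta2 + beta3) * x``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    group = np.asarray(group, dtype=float)
    n = len(y)
    fit = PairwiseFit(response=response, predictor=predictor, mode="interaction", n=n)
    if n < 5:
        return replace(fit, valid=False, reason=f"n={n} < 5")
    if len(np.unique(group)) != 2:
        return replace(fit, valid=False, reason="both group levels required")
    X = np.column_stack([np.ones(n), group, x, group * x])
    return _finish_fit(fit, X, y, target=3)


def fit_pair_correlation(
    y: np.ndarray, x: np.ndarray, response: str = "y", predictor: str = "x"
) -> PairwiseFit:
    """Simple linear regression of y on x; slope p equals the Pearson p."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    fit = PairwiseFit(response=response, predictor=predictor, mode="correlation", n=n)
    if n < 3:
        return replace(fit, valid=False, reason=f"n={n} < 3")
    X = np.column_stack([np.ones(n), x])
    return _finish_fit(fit, X, y, target=1)


def prevalence_filter(
    dataset: OmicsDataset, ome: str, min_frac: float = 0.10
) -> list[str]:
    """Analytes of one ome observed (non-zero) in at least min_frac of samples.

    An analyte is removed when its non-zero count is strictly fewer than
    ``min_frac * n``; retained when ``count >= min_frac * n``.
    """
    if not 0.0 <= min_frac <= 1.0:
        raise ValueError("min_frac must be in [0, 1]")
    if ome not in dataset.omes:
        raise KeyError(f"unknown ome {ome!r}")
    mat = dataset.omes[ome]
    threshold = min_frac * dataset.n_samples
    counts = (mat.to_numpy() != 0).sum(axis=0)
    return [c for c, k in zip(mat.columns, counts) if k >= threshold]


#: canonical regression directions for the three-ome microbiome study shape:
#: enzymes respond to metabolites, microbes respond to enzymes, and
#: metabolites respond to microbes (microbes as producers/consumers).
CANONICAL_PLAN = (("e", "met"), ("mb", "e"), ("met", "mb"))


def default_pair_plan(ome_names: Sequence[str]) -> list[tuple[str, str]]:
    """One (response ome, predictor ome) entry per unordered ome pair.

    The canonical mb/met/e trio gets the conventional directions of
    :data:`CANONICAL_PLAN`; any other ome set pairs each ome with every
    later one, the earlier-listed ome as response.
    """
    names = list(ome_names)
    if set(names) == {"mb", "met", "e"}:
        return list(CANONICAL_PLAN)
    return [
        (names[i], names[j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
    ]


def run_all_pairs(
    dataset: OmicsDataset,
    mode: str = "interaction",
    ome_pair_plan: Sequence[tuple[str, str]] | None = None,
) -> list[PairwiseFit]:
    """Fit every cross-ome analyte pair in the plan.

    ``ome_pair_plan`` lists each unordered ome pair once as
    (response ome, predictor ome); the interaction p-value depends on the
    direction, so the plan defaults to :func:`default_pair_plan` and is
    logged. Invalid fits are returned flagged, never silently dropped, so
    the number of returned fits always equals the number attempted.
    """
    if mode not in {"interaction", "correlation"}:
        raise ValueError(f"unknown mode {mode!r}")
    if ome_pair_plan is None:
        ome_pair_plan = default_pair_plan(list(dataset.omes))
    logger.info("pair plan (response ome ~ predictor ome): %s", ome_pair_plan)
    seen: set[frozenset[str]] = set()
    for resp_ome, pred_ome in ome_pair_plan:
        for ome in (resp_ome, pred_ome):
            if ome not in dataset.omes:
                raise KeyError(f"plan references unknown ome {ome!r}")
        key = frozenset((resp_ome, pred_ome))
        if len(key) == 1:
            raise ValueError(f"plan pairs analytes within one ome: {resp_ome!r}")
        if key in seen:
            raise ValueError(f"duplicate ome pair in plan: ({resp_ome}, {pred_ome})")
        seen.add(key)

    group = dataset.group.astype(float)
    fits: list[PairwiseFit] = []
    for resp_ome, pred_ome in ome_pair_plan:
        resp_mat = dataset.omes[resp_ome]
        pred_mat = dataset.omes[pred_ome]
        for rname in resp_mat.columns:
            y = resp_mat[rname].to_numpy(dtype=float)
            for pname in pred_mat.columns:
                x = pred_mat[pname].to_numpy(dtype=float)
                if mode == "interaction":
                    fit = fit_pair_interaction(y, x, group, rname, pname)
                else:
                    fit = fit_pair_correlation(y, x, rname, pname)
                fit.response_ome = resp_ome
                fit.predictor_ome = pred_ome
                fits.append(fit)
    return fits


def build_top_table(
    fits: Iterable[PairwiseFit],
    per_pair_cap: int = 35,
    alpha: float = 0.05,
    dffits_max: float = DFFITS_MAX_DEFAULT,
    excluded_analytes: Sequence[str] = (),
) -> TopTable:
    """Select the per-assay-pair fits with the smallest target-term p-values.

    Exclusions apply first, in order: invalid fits, fits with undefined
    p-values, fits touching an excluded analyte (e.g. failing the
    prevalence filter), fits with max |DFFITS| >= ``dffits_max``. The
    survivors are ranked within each assay pair by
    (p_target, -|t_target|, response, predictor), gated at
    ``p_target < alpha``, and capped at ``per_pair_cap`` entries per pair.
    """
    excluded = set(excluded_analytes)
    counts = {
        "invalid": 0,
        "p_undefined": 0,
        "prevalence": 0,
        "dffits": 0,
        "retained": 0,
    }
    eligible: list[PairwiseFit] = []
    for fit in fits:
        if not fit.valid:
            counts["invalid"] += 1
        elif not np.isfinite(fit.p_target):
            counts["p_undefined"] += 1
        elif fit.response in excluded or fit.predictor in excluded:
            counts["prevalence"] += 1
        elif fit.max_abs_dffits >= dffits_max:
            counts["dffits"] += 1
        else:
            counts["retained"] += 1
            eligible.append(fit)

    by_pair: dict[tuple[str, str], list[PairwiseFit]] = {}
    for fit in eligible:
        by_pair.setdefault(fit.assay_pair, []).append(fit)
    entries: list[PairwiseFit] = []
    for pair in sorted(by_pair):
        ranked = sorted(
            (f for f in by_pair[pair] if f.p_target < alpha),
            key=lambda f: (
                f.p_target,
                -abs(f.t_target) if np.isfinite(f.t_target) else 0.0,
                f.response,
                f.predictor,
            ),
        )
        entries.extend(ranked[:per_pair_cap])
    return TopTable(
        entries=entries, per_pair_cap=per_pair_cap, alpha=alpha, exclusions=counts
    )


def top_table_frame(table: TopTable):
    """Top table as a pandas DataFrame (CSV-exportable)."""
    import pandas as pd

    rows = [
        {
            "response": f.response,
            "predictor": f.predictor,
            "mode": f.mode,
            "beta0": f.beta0,
            "beta1": f.beta1,
            "beta2": f.beta2,
            "beta3": f.beta3,
            "p_target": f.p_target,
            "max_abs_dffits": f.max_abs_dffits,
            "n": f.n,
            "assay_pair": "~".join(f.assay_pair),
        }
        for f in table.entries
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "response", "predictor", "mode", "beta0", "beta1", "beta2", "beta3",
            "p_target", "max_abs_dffits", "n", "assay_pair",
        ],
    )


def read_top_table_csv(path) -> TopTable:
    """Reload a top-table CSV written from :func:`top_table_frame`."""
    import pandas as pd

    frame = pd.read_csv(path)
    entries = []
    for row in frame.itertuples(index=False):
        resp_ome, pred_ome = str(row.assay_pair).split("~", 1)
        entries.append(
            PairwiseFit(
                response=row.response,
                predictor=row.predictor,
                mode=row.mode,
                beta0=row.beta0,
                beta1=None if pd.isna(row.beta1) else row.beta1,
                beta2=row.beta2,
                beta3=None if pd.isna(row.beta3) else row.beta3,
                p_target=row.p_target,
                max_abs_dffits=row.max_abs_dffits,
                n=int(row.n),
                response_ome=resp_ome,
                predictor_ome=pred_ome,
            )
        )
    return TopTable(entries=entries)
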