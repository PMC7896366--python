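"""Synthetic multi-omic cohorts with known planted structure.

The generator emulates the data model of a gut-microbiome case/control
study measured on three omes: zero-inflated, non-negative microbial
relative abundances; heavy-right-tailed (log-normal) metabolite and enzyme
intensities on a ppm scale; numeric clinical covariates (age in years and
a fecal inflammation marker); a binary outcome with configurable group
imbalance; group-specific linear cross-ome relationships planted into
chosen analyte pairs; and outcome-linked analytes acting through a
logistic model. Every random draw is controlled by one seed, and the
ground truth (planted edges and effects) is returned alongside the data so
pipeline recovery can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from cantare.dataset_io import OmicsDataset

_LOCAL_STEM = {"mb": "sp", "met": "m", "e": "ec"}

#: scale on which each covariate drives the outcome; the inflammation
#: marker acts multiplicatively, so its effect is per SD of the log value
_COVARIATE_LINK = {"calprotectin": np.log}


class PlantedPair(BaseModel):
    """A planted group-specific linear relationship between two analytes.

    The response column is regenerated as
    ``y = beta0 + beta1*g + beta2*x + beta3*g*x + Normal(0, noise_sd)``
    (clipped at zero to respect non-negativity), so the pair carries a true
    interaction of size beta3 between the groups.
    """

    response: str
    predictor: str
    beta0: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    beta3: float = 0.0
    noise_sd: float = 1.0


class OutcomeEffect(BaseModel):
    """An analyte tied to the outcome: log-odds per SD of the analyte."""

    analyte: str
    logodds_per_sd: float


class SyntheticSpec(BaseModel):
    """Configuration of one synthetic cohort.

    Defaults mirror a 153-participant three-ome IBD-style cohort: 42
    controls vs 111 cases, 201 microbes (relative-abundance fractions,
    roughly half the entries zero), 386 metabolites and 76 enzymes
    (log-normal ppm intensities), with age and fecal calprotectin as
    covariates.
    """

    n_samples: int = 153
    case_fraction: float = 111 / 153
    ome_sizes: dict[str, int] = Field(
        default_factory=lambda: {"mb": 201, "met": 386, "e": 76}
    )
    #: probability that a microbe measurement is structurally zero
    zero_inflation: float = 0.5
    #: per-ome log-scale (mu, sigma) of the positive intensity component
    log_mu: dict[str, float] = Field(
        default_factory=lambda: {"mb": np.log(0.005), "met": np.log(200.0),
                                 "e": np.log(200.0)}
    )
    log_sigma: dict[str, float] = Field(
        default_factory=lambda: {"mb": 1.5, "met": 1.0, "e": 1.0}
    )
    planted_pairs: list[PlantedPair] = Field(default_factory=list)
    outcome_effects: list[OutcomeEffect] = Field(default_factory=list)
    #: log-odds of case status per SD of each covariate
    covariate_effects: dict[str, float] = Field(
        default_factory=lambda: {"age": 0.0, "calprotectin": 0.0}
    )
    renormalize_microbes: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticSpec":
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must lie strictly inside (0, 1)")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must lie in [0, 1]")
        names = set(self.analyte_names_flat())
        for pair in self.planted_pairs:
            for ref in (pair.response, pair.predictor):
                if ref not in names:
                    raise ValueError(f"planted pair references unknown analyte {ref!r}")
        responses = [p.response for p in self.planted_pairs]
        if len(set(responses)) != len(responses):
            raise ValueError("each analyte may be the response of one planted pair")
        outcome_names = {e.analyte for e in self.outcome_effects}
        for ref in outcome_names:
            if ref not in names:
                raise ValueError(f"outcome effect references unknown analyte {ref!r}")
        if outcome_names & set(responses):
            raise ValueError(
                "outcome-effect analytes may not also be planted-pair responses"
            )
        return self

    def analyte_names(self, ome: str) -> list[str]:
        stem = _LOCAL_STEM.get(ome, "a")
        return [f"{ome}_{stem}{i:03d}" for i in range(1, self.ome_sizes[ome] + 1)]

    def analyte_names_flat(self) -> list[str]:
        return [n for ome in self.ome_sizes for n in self.analyte_names(ome)]


@dataclass
class GroundTruth:
    """Everything planted into one simulated cohort."""

    planted_pairs: list[PlantedPair]
    outcome_effects: list[OutcomeEffect]
    covariate_effects: dict[str, float]
    group: np.ndarray
    seed: int


def _calibrate_intercept(offset: np.ndarray, target: float) -> float:
    """Intercept making the mean logistic probability equal the case fraction."""
    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.mean(1.0 / (1.0 + np.exp(-(mid + offset)))) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate(spec: SyntheticSpec) -> tuple[OmicsDataset, GroundTruth]:
    """Draw one cohort from the spec; same spec + seed gives identical data.

    Order of construction: covariates, then independent analyte matrices,
    then the outcome (from the logistic model over the outcome-linked
    analytes and covariates, with the intercept calibrated so the expected
    case fraction matches the spec; when no effects are specified the
    group counts are exact), and finally the planted pairs, whose response
    columns are regenerated from the group and predictor columns. Planted
    pairs are applied in list order: when a planted response is reused as
    the predictor of a later pair, the later pair sees the regenerated
    values, so chains of relationships should be listed parents-first.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]

    age = np.clip(rng.normal(40.0, 12.0, size=n), 18.0, 80.0)
    calprotectin = np.exp(rng.normal(4.0, 1.2, size=n))
    covs = pd.DataFrame(
        {"age": age, "calprotectin": calprotectin},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    omes: dict[str, pd.DataFrame] = {}
    for ome, size in spec.ome_sizes.items():
        mu, sigma = spec.log_mu.get(ome, 0.0), spec.log_sigma.get(ome, 1.0)
        values = rng.lognormal(mean=mu, sigma=sigma, size=(n, size))
        if ome == "mb":
            mask = rng.random((n, size)) >= spec.zero_inflation
            values = values * mask
            if spec.renormalize_microbes:
                totals = values.sum(axis=1, keepdims=True)
                totals[totals == 0] = 1.0
                values = values / totals
        omes[ome] = pd.DataFrame(
            values,
            index=pd.Index(sample_ids, name="sample_id"),
            columns=spec.analyte_names(ome),
        )

    def column(name: str) -> np.ndarray:
        ome = name.split("_", 1)[0]
        return omes[ome][name].to_numpy(dtype=float)

    has_effects = bool(spec.outcome_effects) or any(
        v != 0.0 for v in spec.covariate_effects.values()
    )
    if has_effects:
        offset = np.zeros(n)
        for eff in spec.outcome_effects:
            offset += eff.logodds_per_sd * _zscore(column(eff.analyte))
        for cov, beta in spec.covariate_effects.items():
            if beta != 0.0:
                link = _COVARIATE_LINK.get(cov, lambda v: v)
                offset += beta * _zscore(link(covs[cov].to_numpy()))
        intercept = _calibrate_intercept(offset, spec.case_fraction)
        prob = 1.0 / (1.0 + np.exp(-(intercept + offset)))
        group = (rng.random(n) < prob).astype(int)
        # a degenerate draw would break downstream binary-outcome contracts
        if group.min() == group.max():
            group[np.argsort(prob)[0 if group[0] == 1 else -1]] ^= 1
    else:
        n_case = int(round(n * spec.case_fraction))
        n_case = min(max(n_case, 1), n - 1)
        group = np.zeros(n, dtype=int)
        group[rng.choice(n, size=n_case, replace=False)] = 1

    for pair in spec.planted_pairs:
        x = column(pair.predictor)
        y = (
            pair.beta0
            + pair.beta1 * group
            + pair.beta2 * x
            + pair.beta3 * group * x
            + rng.normal(0.0, pair.noise_sd, size=n)
        )
        ome = pair.response.split("_", 1)[0]
        omes[ome][pair.response] = np.clip(y, 0.0, None)

    dataset = OmicsDataset(
        sample_ids=sample_ids, group=group, covariates=covs, omes=omes
    )
    truth = GroundTruth(
        planted_pairs=list(spec.planted_pairs),
        outcome_effects=list(spec.outcome_effects),
        covariate_effects=dict(spec.covariate_effects),
        group=group,
        seed=spec.seed,
    )
    return dataset, truth


def demo_spec(seed: int = 0, scale: float = 1.0) -> SyntheticSpec:
    """A study-shaped cohort with planted cross-ome structure.

    153 samples (42 controls / 111 cases) on three omes sized as a fraction
    ``scale`` of the 201/386/76 study shape; six planted group-specific
    relationships (two per assay pair) and three outcome-linked analytes
    (one per ome), plus a strong calprotectin and a mild age effect.
    Coefficients are chosen on each ome's natural scale (fractions for
    microbes, hundreds of ppm for metabolites/enzymes).
    """
    sizes = {
        "mb": max(int(round(201 * scale)), 8),
        "met": max(int(round(386 * scale)), 12),
        "e": max(int(round(76 * scale)), 8),
    }
    spec = SyntheticSpec(seed=seed, ome_sizes=sizes)
    mb, met, e = (spec.analyte_names(o) for o in ("mb", "met", "e"))
    # Planted directions follow the canonical pair plan (met~mb, e~met,
    # mb~e). The pairs form small connected hubs rather than isolated edges
    # (real Vnets are well connected), and the outcome-linked analytes also
    # serve as planted-pair predictors so that, as in real cohorts, they
    # carry cross-ome relationships and can enter the network.
    # pairs are applied in list order, so chained relationships are listed
    # parents-first (a response reused as a predictor downstream must be
    # regenerated before its dependents)
    spec.planted_pairs = [
        # enzyme response driven by the outcome-linked metabolite
        PlantedPair(response=e[1], predictor=met[4], beta0=400.0, beta1=50.0,
                    beta2=0.2, beta3=-0.4, noise_sd=120.0),
        # microbe responses driven by enzymes (response on the fraction scale)
        PlantedPair(response=mb[2], predictor=e[4], beta0=0.005, beta2=3e-5,
                    beta3=6e-5, noise_sd=0.01),
        PlantedPair(response=mb[3], predictor=e[5], beta0=0.04, beta1=0.005,
                    beta2=2e-5, beta3=-5e-5, noise_sd=0.01),
        PlantedPair(response=mb[5], predictor=e[1], beta0=0.01, beta2=2e-5,
                    beta3=5e-5, noise_sd=0.01),
        # metabolite responses driven by microbes (x ~ 0-0.1 fraction)
        PlantedPair(response=met[0], predictor=mb[0], beta0=200.0, beta2=2000.0,
                    beta3=8000.0, noise_sd=120.0),
        PlantedPair(response=met[1], predictor=mb[4], beta0=250.0, beta1=80.0,
                    beta2=1500.0, beta3=-8000.0, noise_sd=120.0),
        PlantedPair(response=met[5], predictor=mb[4], beta0=220.0, beta2=1000.0,
                    beta3=7000.0, noise_sd=120.0),
        PlantedPair(response=met[6], predictor=mb[2], beta0=200.0, beta2=1500.0,
                    beta3=8000.0, noise_sd=120.0),
        PlantedPair(response=met[7], predictor=mb[2], beta0=260.0, beta2=1000.0,
                    beta3=-7000.0, noise_sd=120.0),
        PlantedPair(response=met[8], predictor=mb[5], beta0=240.0, beta2=1500.0,
                    beta3=8000.0, noise_sd=120.0),
        # enzyme responses driven by metabolites (x ~ hundreds of ppm)
        PlantedPair(response=e[0], predictor=met[2], beta0=120.0, beta2=0.3,
                    beta3=0.6, noise_sd=100.0),
        PlantedPair(response=e[6], predictor=met[1], beta0=150.0, beta2=0.3,
                    beta3=0.5, noise_sd=100.0),
    ]
    spec.outcome_effects = [
        OutcomeEffect(analyte=mb[4], logodds_per_sd=-1.0),
        OutcomeEffect(analyte=met[4], logodds_per_sd=1.0),
        OutcomeEffect(analyte=e[4], logodds_per_sd=0.8),
    ]
    spec.covariate_effects = {"age": 0.3, "calprotectin": 1.5}
    return spec.model_validate(spec.model_dump())


def recovery_report(
    fits,
    top_table,
    ground_truth: GroundTruth,
    models=None,
    dataset: OmicsDataset | None = None,
    alpha: float = 0.05,
) -> dict:
    """How much of the planted structure the pipeline recovered.

    Returns top-table sensitivity (planted pairs recovered / planted; NaN
    for a null spec), the false-pair rate (fraction of valid non-planted
    fits with target p below alpha), model-level recovery of the
    outcome-linked analytes, and — when the dataset is supplied — the mean
    bias of their recovered per-SD log-odds coefficients.
    """
    planted = {
        frozenset((p.response, p.predictor)) for p in ground_truth.planted_pairs
    }
    universe = {f.response for f in fits} | {f.predictor for f in fits}
    for pair in planted:
        if not pair <= universe:
            raise ValueError(f"ground truth pair {set(pair)} absent from the fits")

    top_pairs = {frozenset((f.response, f.predictor)) for f in top_table.entries}
    sensitivity = (
        len(planted & top_pairs) / len(planted) if planted else float("nan")
    )
    non_planted = [
        f
        for f in fits
        if f.valid
        and np.isfinite(f.p_target)
        and frozenset((f.response, f.predictor)) not in planted
    ]
    false_rate = (
        float(np.mean([f.p_target < alpha for f in non_planted]))
        if non_planted
        else float("nan")
    )
    report = {
        "n_planted": len(planted),
        "top_table_sensitivity": sensitivity,
        "false_pair_rate": false_rate,
    }
    if models is not None:
        targets = {e.analyte: e.logodds_per_sd for e in ground_truth.outcome_effects}
        recovered = {
            name: model
            for model in models
            if model.converged
            for name in model.reduced_predictors
            if name in targets
        }
        report["outcome_analyte_recovery"] = (
            len(recovered) / len(targets) if targets else float("nan")
        )
        if dataset is not None and recovered:
            biases = []
            for name, model in recovered.items():
                sd = dataset.analyte_vector(name).std(ddof=1)
                biases.append(model.coefficients[name] * sd - targets[name])
            report["coefficient_bias"] = float(np.mean(biases))
    return report
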