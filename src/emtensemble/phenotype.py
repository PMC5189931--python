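"""Virtual flow cytometry: ensemble-level phenotype heterogeneity.

Every ensemble member is a deterministic "cell"; simulating the whole
ensemble under a treatment and reading (E-cadherin, Vimentin) at 48 h
yields a population scatter analogous to a two-color FACS plot.
Phenotype calls partition the plane into quadrants using thresholds
derived from the untreated population (untreated cells are
E-cadherin-high / Vimentin-low):

    epithelial   = E-cad >= cut, Vim <  cut
    mesenchymal  = E-cad <  cut, Vim >= cut
    hybrid       = both high (partial EMT)
    low_low      = both low
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .dynamics import (
    Condition,
    IntegrationError,
    ParameterSet,
    compile_model,
    simulate,
)

CALLS = ("epithelial", "mesenchymal", "hybrid", "low_low")

ECAD_SPECIES = "Ecad"
VIM_SPECIES = "Vim"
PSP1_SPECIES = "Sp1_p_nuc"
NFAT_SPECIES = "NFAT_nuc"


@dataclass
class PopulationResult:
    member_id: int
    ecad: float  # nM at 48 h
    vim: float
    psp1_nuclear: float
    nfatc1_nuclear: float
    condition: str
    call: str | None = None
    failed: bool = False


@dataclass
class PhenotypeThresholds:
    ecad_high: float  # nM
    vim_high: float
    derivation: str = "quantiles of untreated population"

    def __post_init__(self):
        if self.ecad_high <= 0 or self.vim_high <= 0:
            raise ValueError("thresholds must be positive")


def population_simulate(
    ensemble: list[ParameterSet],
    condition: Condition,
    model,
    max_failure_fraction: float = 0.10,
) -> list[PopulationResult]:
    """Simulate every member to 48 h; failed members are flagged, not dropped.

    Raises if more than ``max_failure_fraction`` of the population fails.
    """
    if not ensemble:
        raise ValueError("ensemble is empty")
    cm = compile_model(model) if not hasattr(model, "index") else model
    results = []
    failures = 0
    for i, params in enumerate(ensemble):
        try:
            traj = simulate(cm, params, condition)
            results.append(
                PopulationResult(
                    member_id=i,
                    ecad=traj.endpoint(ECAD_SPECIES),
                    vim=traj.endpoint(VIM_SPECIES),
                    psp1_nuclear=traj.endpoint(PSP1_SPECIES),
                    nfatc1_nuclear=traj.endpoint(NFAT_SPECIES),
                    condition=condition.id,
                )
            )
        except IntegrationError:
            failures += 1
            results.append(
                PopulationResult(i, np.nan, np.nan, np.nan, np.nan,
                                 condition.id, failed=True)
            )
    if failures > max_failure_fraction * len(ensemble):
        raise RuntimeError(
            f"{failures}/{len(ensemble)} members failed under {condition.id!r}"
        )
    return results


def derive_thresholds(
    untreated: list[PopulationResult],
    ecad_quantile: float = 0.5,
    vim_quantile: float = 0.9,
) -> PhenotypeThresholds:
    """Quadrant cutoffs from the untreated population.

    E-cad-high is the untreated median (half the resting population sits
    above it); Vim-high is the untreated 90th percentile (resting cells
    are Vimentin-low, so only outliers exceed it).
    """
    ok = [r for r in untreated if not r.failed]
    if not ok:
        raise ValueError("untreated population is empty")
    ecad = np.array([r.ecad for r in ok])
    vim = np.array([r.vim for r in ok])
    if np.ptp(ecad) == 0 and np.ptp(vim) == 0 and len(ok) > 1:
        raise ValueError("degenerate untreated population (all members equal)")
    return PhenotypeThresholds(
        ecad_high=float(np.quantile(ecad, ecad_quantile)),
        vim_high=float(np.quantile(vim, vim_quantile)),
        derivation=(
            f"untreated quantiles (ecad q={ecad_quantile}, vim q={vim_quantile})"
        ),
    )


def classify(ecad: float, vim: float, thresholds: PhenotypeThresholds) -> str:
    """Quadrant call from marker abundances."""
    hi_e = ecad >= thresholds.ecad_high
    hi_v = vim >= thresholds.vim_high
    if hi_e and hi_v:
        return "hybrid"
    if hi_e:
        return "epithelial"
    if hi_v:
        return "mesenchymal"
    return "low_low"


def classify_population(
    results: list[PopulationResult], thresholds: PhenotypeThresholds
) -> list[PopulationResult]:
    return [
        r if r.failed
        else replace(r, call=classify(r.ecad, r.vim, thresholds))
        for r in results
    ]


def fraction_table(results: list[PopulationResult]) -> dict[str, float]:
    """Normalized quadrant fractions; failed members excluded and counted."""
    ok = [r for r in results if not r.failed and r.call is not None]
    if not ok:
        raise ValueError("no classified members")
    n = len(ok)
    table = {call: sum(r.call == call for r in ok) / n for call in CALLS}
    table["n"] = n
    table["failed"] = sum(r.failed for r in results)
    return table


def responder_fraction(
    treated: list[PopulationResult],
    untreated: list[PopulationResult],
    confidence: float = 0.95,
) -> float:
    """Fraction of members displaced beyond the untreated 95% cloud.

    For each member the (E-cad, Vim) displacement treated - untreated is
    measured in the Mahalanobis metric of the untreated population's
    covariance; a member "responded" if its displacement exceeds the
    chi-squared radius containing ``confidence`` of that cloud.
    """
    t_ok = {r.member_id: r for r in treated if not r.failed}
    u_ok = {r.member_id: r for r in untreated if not r.failed}
    common = sorted(set(t_ok) & set(u_ok))
    if not common:
        raise ValueError("no matched members between treated and untreated")
    if set(t_ok) != set(u_ok):
        raise ValueError("member ids do not match")
    U = np.array([[u_ok[i].ecad, u_ok[i].vim] for i in common])
    T = np.array([[t_ok[i].ecad, t_ok[i].vim] for i in common])
    cov = np.cov(U.T) if len(common) > 2 else np.eye(2)
    cov = cov + 1e-9 * np.eye(2) * max(np.trace(cov), 1.0)
    inv = np.linalg.inv(cov)
    d = T - U
    d2 = np.einsum("ij,jk,ik->i", d, inv, d)
    radius2 = chi2.ppf(confidence, df=2)
    return float(np.mean(d2 > radius2))


PERTURBATION_KINDS = {
    "nfat_inhibition": {"inhibitors": {"VIVIT": 1.0}},
    "yreg1_knockout": {"expression_mods": {"YREG1": 0.0}},
    "yreg1_overexpression": {"expression_mods": {"YREG1": 20.0}},
}


def insilico_perturbation(
    ensemble: list[ParameterSet],
    condition: Condition,
    perturbation: str | dict,
    model,
) -> list[PopulationResult]:
    """Population run with a perturbation folded into the condition.

    ``perturbation`` is a named kind (NFAT inhibition, YREG1 knockout or
    overexpression) or an arbitrary ``{"expression_mods": {gene: mult}}``
    / ``{"inhibitors": {...}}`` mapping.
    """
    if isinstance(perturbation, str):
        if perturbation not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation {perturbation!r}")
        spec = PERTURBATION_KINDS[perturbation]
    else:
        spec = perturbation
    cond = Condition(
        id=f"{condition.id}+{spec}" if isinstance(perturbation, dict)
        else f"{condition.id}+{perturbation}",
        doses=dict(condition.doses),
        inhibitors={**condition.inhibitors, **spec.get("inhibitors", {})},
        expression_mods={
            **condition.expression_mods, **spec.get("expression_mods", {})
        },
        t_end=condition.t_end,
    )
    return population_simulate(ensemble, cond, model)


def tf_activity_readout(trajectory) -> tuple[float, float]:
    """(nuclear phospho-Sp1, nuclear NFATc1) abundances at the endpoint."""
    for sp in (PSP1_SPECIES, NFAT_SPECIES):
        if sp not in trajectory.names:
            raise ValueError(f"species {sp} missing from trajectory")
    return trajectory.endpoint(PSP1_SPECIES), trajectory.endpoint(NFAT_SPECIES)


def population_frame(results: list[PopulationResult]) -> pd.DataFrame:
    """Tidy export (member_id, condition, ecad, vim, psp1, nfat, call)."""
    return pd.DataFrame(
        {
            "member_id": [r.member_id for r in results],
            "condition": [r.condition for r in results],
            "ecad": [r.ecad for r in results],
            "vim": [r.vim for r in results],
            "psp1": [r.psp1_nuclear for r in results],
            "nfat": [r.nfatc1_nuclear for r in results],
            "call": [r.call for r in results],
            "failed": [r.failed for r in results],
        }
    )
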