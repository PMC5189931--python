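"""Synthetic training data with the structure of blot/qPCR intensity series.

The experiment families mirror the published training design: TGF-beta2
time courses with and without MEK inhibition, Snail/Slug/E-cadherin
overexpression, TGF-beta3 with dominant-negative Smad4/LEF-1, a
PI3K->GSK3/beta-catenin family, and VEGF-A dose responses read at 3 h
and 48 h.  Under the default grouping they comprise 41 measurement
series organized into 11 objectives.  Band intensities are emulated by
simulating a ground-truth parameter set and applying multiplicative
lognormal noise (blot densitometry error is multiplicative).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .dynamics import Condition, ParameterSet, compile_model, simulate
from .estimation import perturb
from .objectives import MeasurementSeries, Objective

ENDPOINT_TIMES = (0.0, 12.0, 24.0, 48.0)
TEMPORAL_TIMES = (0.0, 6.0, 12.0, 24.0, 36.0, 48.0)
VEGF_TIMES = (3.0, 48.0)  # qPCR harvests


@dataclass
class Protocol:
    """One experiment family: conditions, readouts and sampling times."""

    name: str
    objective_id: int
    series: list[tuple[str, str]]  # (species readout, condition id)
    times: tuple[float, ...]


@dataclass
class NoiseModel:
    """Multiplicative lognormal noise with an additive detection floor."""

    cv: float = 0.15
    floor: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.cv < 0 or self.floor < 0:
            raise ValueError("cv and floor must be nonnegative")


def default_conditions() -> dict[str, Condition]:
    """The treatment registry used by the default protocols (doses in a.u.)."""
    oe = 20.0  # overexpression multiplier for transfection constructs
    conds = [
        Condition("untreated"),
        Condition("tgfb2", doses={"TGFB12": 10.0}),
        Condition("tgfb2_u0126", doses={"TGFB12": 10.0}, inhibitors={"U0126": 1.0}),
        Condition("snail_oe", expression_mods={"Snail": oe}),
        Condition("slug_oe", expression_mods={"Slug": oe}),
        Condition("ecad_oe", expression_mods={"Ecad": oe}),
        Condition("tgfb3", doses={"TGFB3": 10.0}),
        Condition("tgfb3_dnsmad4", doses={"TGFB3": 10.0},
                  inhibitors={"DN-Smad4": 1.0}),
        Condition("tgfb3_dnlef1", doses={"TGFB3": 10.0},
                  inhibitors={"DN-LEF-1": 1.0}),
        Condition("tgfb3_ly294002", doses={"TGFB3": 10.0},
                  inhibitors={"LY294002": 1.0}),
        Condition("vegf_5", doses={"VEGFA": 5.0}),
        Condition("vegf_50", doses={"VEGFA": 50.0}),
    ]
    return {c.id: c for c in conds}


def default_protocols() -> list[Protocol]:
    """The 11 default experiment families (41 measurement series)."""
    return [
        Protocol("tgfb2_mapk", 1, [
            ("AP1_p", "tgfb2"), ("Sp1_p_nuc", "tgfb2"),
            ("Snail", "tgfb2"), ("Slug", "tgfb2"),
        ], ENDPOINT_TIMES),
        Protocol("tgfb2_mek_inhibition", 2, [
            ("AP1_p", "tgfb2_u0126"), ("Snail", "tgfb2_u0126"),
            ("Slug", "tgfb2_u0126"), ("Snail_mRNA", "tgfb2_u0126"),
        ], ENDPOINT_TIMES),
        Protocol("snail_overexpression", 3, [
            ("TGFB3_mRNA", "snail_oe"), ("Ecad", "snail_oe"),
            ("TGFB3", "snail_oe"),
        ], ENDPOINT_TIMES),
        Protocol("slug_overexpression", 4, [
            ("TGFB3_mRNA", "slug_oe"), ("Ecad", "slug_oe"), ("Vim", "slug_oe"),
        ], ENDPOINT_TIMES),
        Protocol("ecad_overexpression", 5, [
            ("TGFB3_mRNA", "ecad_oe"), ("bcat", "ecad_oe"), ("Ecad", "ecad_oe"),
        ], ENDPOINT_TIMES),
        Protocol("tgfb3_induction", 6, [
            ("Vim", "tgfb3"), ("Ecad", "tgfb3"), ("LEF1", "tgfb3"),
            ("Smad_p_nuc", "tgfb3"), ("FN1", "tgfb3"),
        ], ENDPOINT_TIMES),
        Protocol("tgfb3_dn_smad4", 7, [
            ("Vim", "tgfb3_dnsmad4"), ("Ecad", "tgfb3_dnsmad4"),
            ("LEF1", "tgfb3_dnsmad4"),
        ], ENDPOINT_TIMES),
        Protocol("tgfb3_dn_lef1", 8, [
            ("Vim", "tgfb3_dnlef1"), ("Ecad", "tgfb3_dnlef1"),
            ("FN1", "tgfb3_dnlef1"),
        ], ENDPOINT_TIMES),
        Protocol("tgfb2_temporal", 9, [
            ("Ecad", "tgfb2"), ("Smad_p", "tgfb2"),
            ("LEF1", "tgfb2"), ("Vim", "tgfb2"),
        ], TEMPORAL_TIMES),
        Protocol("gsk3_beta_catenin", 10, [
            ("bcat", "tgfb3_ly294002"), ("GSK3_p", "tgfb3_ly294002"),
            ("bcat_nuc", "tgfb3_ly294002"), ("APC_bcat", "tgfb3_ly294002"),
        ], ENDPOINT_TIMES),
        Protocol("vegf_nfat", 11, [
            ("NFATc1_mRNA", "vegf_5"), ("NFATc1_mRNA", "vegf_50"),
            ("Ecad_mRNA", "vegf_5"), ("Ecad_mRNA", "vegf_50"),
            ("NFAT_nuc", "vegf_50"),
        ], VEGF_TIMES),
    ]


def validate_protocols(protocols: list[Protocol], model) -> list[str]:
    """Check readouts/times against the model; returns violations."""
    cm = compile_model(model) if not hasattr(model, "index") else model
    report = []
    for p in protocols:
        for species, cond in p.series:
            if species not in cm.index:
                report.append(f"protocol {p.name}: unknown readout {species}")
        if any(t < 0 or t > 48.0 for t in p.times):
            report.append(f"protocol {p.name}: times outside [0, 48] h")
    return report


def generate_dataset(
    truth: ParameterSet,
    protocols: list[Protocol],
    noise: NoiseModel,
    model,
    conditions: dict[str, Condition] | None = None,
) -> list[Objective]:
    """Simulate the truth under every protocol and emit noisy objectives.

    values = sim * Lognormal(mean 1, cv) + floor * U(0,1); recorded sd is
    cv * value (the default 10%-of-max fallback applies when cv = 0).
    Deterministic for a fixed ``noise.seed``.
    """
    cm = compile_model(model) if not hasattr(model, "index") else model
    conditions = conditions or default_conditions()
    rng = np.random.default_rng(noise.seed)
    sigma = float(np.sqrt(np.log1p(noise.cv**2)))
    trajs: dict[str, object] = {}
    objectives = []
    for p in protocols:
        series = []
        for species, cond_id in p.series:
            if cond_id not in trajs:
                try:
                    trajs[cond_id] = simulate(cm, truth, conditions[cond_id])
                except Exception as exc:
                    raise RuntimeError(
                        f"protocol {p.name}, condition {cond_id}: {exc}"
                    ) from exc
            traj = trajs[cond_id]
            sim = np.interp(p.times, traj.times, traj.series(species))
            fac = (
                np.exp(rng.normal(-0.5 * sigma**2, sigma, size=len(sim)))
                if noise.cv > 0
                else np.ones(len(sim))
            )
            values = sim * fac
            if noise.floor > 0:
                values = values + noise.floor * rng.uniform(size=len(sim))
            sd = noise.cv * np.maximum(values, 1e-12) if noise.cv > 0 else None
            series.append(
                MeasurementSeries(
                    series_id=f"{p.name}:{species}@{cond_id}",
                    species=species,
                    condition_id=cond_id,
                    times=np.asarray(p.times),
                    values=values,
                    sd=sd,
                )
            )
        objectives.append(Objective(id=p.objective_id, series=series))
    return objectives


def generate_population(
    truth: ParameterSet, n: int, spread: float, seed: int
) -> list[ParameterSet]:
    """n ground-truth "cells" by independent multiplicative parameter jitter.

    Extrinsic (parametric) heterogeneity only: each member's parameters
    lie within [1-spread, 1+spread] times the truth.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    if not 0.0 <= spread < 1.0:
        raise ValueError("spread must be in [0, 1)")
    rng = np.random.default_rng(seed)
    return [perturb(truth, spread, rng) for _ in range(n)]


def dataset_manifest(
    protocols: list[Protocol], noise: NoiseModel, truth: ParameterSet
) -> dict:
    """Manifest describing a generated dataset (protocols, noise, truth hash)."""
    blob = json.dumps(
        {
            "k": truth.k, "ksat": truth.ksat, "control_half": truth.control_half,
            "alpha": truth.alpha, "beta": truth.beta,
            "delta": truth.delta, "gamma": truth.gamma,
            "lambda": truth.lambda_const,
        },
        sort_keys=True,
    ).encode()
    return {
        "protocols": [p.name for p in protocols],
        "n_series": sum(len(p.series) for p in protocols),
        "n_objectives": len({p.objective_id for p in protocols}),
        "noise": {"cv": noise.cv, "floor": noise.floor, "seed": noise.seed},
        "truth_sha1": hashlib.sha1(blob).hexdigest(),
    }
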