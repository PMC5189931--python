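"""Kinetics and integration of the coupled signaling / gene-expression ODEs.

Signaling species follow mass balances

    (1/tau_i) dx_i/dt = sum_j sigma_ij r_j - mu x_i

where each rate r_j is a kinetic term (saturation or mass-action) times a
control coefficient v_j in [0, 1] assembled from Hill-type transfer
functions through a min/max integration rule.  Each of the G genes adds a
transcript/protein pair

    dm_j/dt = u_j alpha_j V_T^max G_j/(K_T+G_j) - (mu + delta_j k_dm) m_j + lambda_j
    dp_j/dt = beta_j V_X^max m_j/(K_X+m_j) - (mu + gamma_j k_dp) p_j

with per-gene correction factors alpha, beta, delta, gamma on
characteristic transcription/translation/degradation constants.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .network import ModelDefinition, gene_species_names

__all__ = [
    "ParameterSet",
    "Condition",
    "Trajectory",
    "hill_transfer",
    "integrate_control",
    "saturation_rate",
    "mass_action_rate",
    "transcription_rate",
    "translation_rate",
    "nominal_parameters",
    "compile_model",
    "rhs",
    "apply_condition",
    "simulate",
    "steady_state",
]

# correction-factor bounds reported for the ensemble
CORRECTION_FACTOR_BOUNDS = (0.1, 10.0)

KNOWN_INHIBITORS = ("U0126", "VIVIT", "LY294002", "DN-Smad4", "DN-LEF-1")

# inhibitors acting on one named catalytic step (scaled by 1 - potency)
_INHIBITOR_REACTION = {
    "U0126": "c06",  # MEK kinase activity on ERK
    "VIVIT": "c18",  # calcineurin-mediated NFAT dephosphorylation
    "LY294002": "c13",  # PI3K(-AKT) inactivation of GSK3
}
# dominant negatives scale the transfer-function output of every factor
# that contains the targeted transcription factor
_DN_SPECIES = {
    "DN-Smad4": ("Smad_p_nuc",),
    "DN-LEF-1": ("LEF1_nuc", "bcat_LEF1"),
}

_LIGAND_DOSES = {
    "TGFB12": "TGFB12",
    "TGFB3": "TGFB3_ex",
    "VEGFA": "VEGFA",
}


# ---------------------------------------------------------------------------
# elementary rate laws (reference scalar forms)
# ---------------------------------------------------------------------------

def hill_transfer(x: float, half: float, order: float = 1.0) -> float:
    """Hill transfer function f = x^n / (kappa^n + x^n), bounded in [0, 1]."""
    if x < 0:
        raise ValueError("factor abundance must be nonnegative")
    if half <= 0 or order <= 0:
        raise ValueError("half-saturation and order must be positive")
    if x == 0.0:
        return 0.0
    xn = x**order
    return xn / (half**order + xn)


def integrate_control(values, rule: str) -> float:
    """Combine transfer-function outputs with a min/max integration rule.

    A process with no modifying factors has coefficient exactly 1.
    """
    vals = list(values)
    for v in vals:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"control factor {v} outside [0, 1]")
    if not vals:
        return 1.0
    if rule == "min":
        return min(vals)
    if rule == "max":
        return max(vals)
    raise ValueError(f"unknown integration rule {rule!r}")


def saturation_rate(kcat: float, enzyme: float, substrate: float, ksat: float) -> float:
    """Enzyme-catalyzed saturation kinetics kcat * e * x / (K + x)."""
    if enzyme < 0 or substrate < 0:
        raise ValueError("abundances must be nonnegative")
    if ksat <= 0:
        raise ValueError("saturation constant must be positive")
    return kcat * enzyme * substrate / (ksat + substrate)


def mass_action_rate(kmax: float, reactant_levels, stoich) -> float:
    """Mass-action kinetics kmax * prod x_s^(-sigma_s) over the reactants."""
    rate = kmax
    for x, s in zip(reactant_levels, stoich):
        if x < 0:
            raise ValueError("abundances must be nonnegative")
        if s >= 0:
            raise ValueError("reactant stoichiometric coefficients must be < 0")
        rate *= x ** (-s)
    return rate


def transcription_rate(gene_copies, alpha, vmax_t, kt, u) -> float:
    """Regulated transcription u * alpha * V_T^max * G/(K_T + G)."""
    if gene_copies < 0:
        raise ValueError("gene copies must be nonnegative")
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must be in [0, 1]")
    return u * alpha * vmax_t * gene_copies / (kt + gene_copies)


def translation_rate(mrna, beta, vmax_x, kx) -> float:
    """Translation beta * V_X^max * m/(K_X + m)."""
    if mrna < 0:
        raise ValueError("mRNA abundance must be nonnegative")
    return beta * vmax_x * mrna / (kx + mrna)


# ---------------------------------------------------------------------------
# parameter container
# ---------------------------------------------------------------------------

@dataclass
class ParameterSet:
    """All kinetic, control and gene-expression parameters of a model.

    Per-reaction and per-factor entries are keyed by reaction id and by a
    ``"target|species*...|direction"`` factor key; per-gene entries by
    gene name.  Characteristic expression constants (kT, kX, kdm, kdp,
    RNAP, RIBO, KT, KX) are global; V_T^max = kT*RNAP, V_X^max = kX*RIBO.
    """

    k: dict[str, float] = field(default_factory=dict)  # rate constant per reaction
    ksat: dict[str, float] = field(default_factory=dict)  # per catalytic reaction, nM
    control_half: dict[str, float] = field(default_factory=dict)  # kappa per factor
    control_order: dict[str, float] = field(default_factory=dict)  # Hill order n
    alpha: dict[str, float] = field(default_factory=dict)
    beta: dict[str, float] = field(default_factory=dict)
    delta: dict[str, float] = field(default_factory=dict)
    gamma: dict[str, float] = field(default_factory=dict)
    lambda_const: dict[str, float] = field(default_factory=dict)  # nM/h
    kT: float = 0.003  # 1/h, characteristic transcription rate constant
    kX: float = 0.13  # 1/h, characteristic translation rate constant
    kdm: float = 0.099  # 1/h, mRNA degradation (~7 h half-life)
    kdp: float = 0.0231  # 1/h, protein degradation (~30 h half-life)
    RNAP: float = 150.0  # nM
    RIBO: float = 300.0  # nM
    KT: float = 10.0  # copies/cell
    KX: float = 2.0  # nM
    mu: float = 0.0105  # 1/h specific growth rate (~66 h doubling)

    @property
    def vmax_t(self) -> float:
        return self.kT * self.RNAP

    @property
    def vmax_x(self) -> float:
        return self.kX * self.RIBO

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


def factor_key(target: str, species: tuple[str, ...], direction: str) -> str:
    return f"{target}|{'*'.join(species)}|{direction}"


# class defaults for the nominal parameterization (see docs/methods.md)
_NOMINAL_RATE_DEFAULTS = {
    "binding": 0.001,  # 1/nM/h
    "unbinding": 0.1,  # 1/h
    "translocation": 0.1,
    "basal": 0.01,
    "clearance": 0.05,
    "kcat": 5.0,  # 1/h
    "ksat": 200.0,  # nM
}

# per-reaction overrides of the class defaults, set once so the untreated
# cell rests at an epithelial steady state on the nM concentration scale
_NOMINAL_K_OVERRIDES = {
    # receptor binding: high affinity so 10 a.u. doses engage signaling
    "m01": 0.01, "m03": 0.01, "m05": 0.01,
    # ligand clearance slow enough for sustained 48 h stimulation;
    # secreted TGFB3 turns over faster (autocrine, locally consumed)
    "m24": 0.02, "m25": 0.02, "m26": 0.2,
    # receptor internalization/recycling
    "m27": 0.1, "m28": 0.1, "m29": 0.1,
    # TGFB3 secretion
    "m23": 0.05,
    # beta-catenin sequestration
    "m07": 0.001, "m09": 0.0003,
    # nuclear complex assembly
    "m11": 0.002, "m13": 0.002, "m15": 0.05,
    # translocation of beta-catenin is slow against junctional capture
    "m17": 0.05, "m18": 0.05,
    # phospho-Smad shuttling favors the nucleus
    "m19": 0.5, "m20": 0.05, "m46": 0.02, "m50": 0.05, "m21": 0.3,
    "m04": 0.3, "m47": 0.1, "m48": 0.1,
    # basal activation leak is small against the phosphatase pool
    "m30": 0.005, "m31": 0.005, "m32": 0.005, "m33": 0.005, "m34": 0.002,
    "m35": 0.002, "m36": 0.005, "m37": 0.002, "m38": 0.005, "m39": 0.005,
    # non-canonical receptor -> MAPK/PI3K couplings are weak
    "c02": 1.0, "c03": 0.01, "c10": 1.0, "c11": 0.01, "c12": 1.0, "c14": 0.5,
    "c15": 10.0,
    # GSK3-dependent destruction steps (kcat, 1/h)
    "c21": 0.1, "c22": 0.2, "c23": 0.2, "c24": 0.05, "c26": 0.05, "c27": 0.05,
    "c42": 0.1, "c43": 0.1,
    # PI3K-AKT strongly inactivates GSK3; reactivation by PPASE is slow
    "c13": 20.0, "c40": 0.5,
    # junction disassembly by ERK
    "c25": 0.05,
    # receptor desensitization and RAS feedback are mild
    "c30": 0.5, "c44": 0.5, "c29": 0.5,
    # Smad dephosphorylation is slow in the nucleus, crosstalk mild
    "c37": 2.5, "c38": 2.0, "c28": 0.5,
    # basal NFAT import keeps a moderate nuclear pool untreated
    "m40": 0.02,
}

_NOMINAL_KSAT_OVERRIDES = {
    "c21": 150.0, "c22": 100.0, "c23": 100.0, "c24": 300.0,
    "c26": 100.0, "c27": 100.0,
}

# factor half-saturations (kappa, nM; nM^2 for product factors)
_NOMINAL_KAPPA = {
    factor_key("Snail", ("AP1Sp1",), "activation"): 25.0,
    factor_key("Snail", ("Smad_p_nuc",), "activation"): 50.0,
    factor_key("Slug", ("AP1Sp1",), "activation"): 25.0,
    factor_key("Slug", ("Smad_p_nuc",), "activation"): 50.0,
    factor_key("Ecad", ("Snail", "Slug"), "inhibition"): 600.0,
    factor_key("Ecad", ("Smad_p_nuc", "LEF1_nuc"), "inhibition"): 400.0,
    factor_key("Ecad", ("NFAT_nuc",), "activation"): 12.0,
    factor_key("YREG1", ("Snail",), "inhibition"): 40.0,
    factor_key("YREG1", ("Slug",), "inhibition"): 40.0,
    factor_key("LEF1", ("YREG1",), "inhibition"): 25.0,
    factor_key("LEF1", ("Smad_p_nuc",), "activation"): 30.0,
    factor_key("LEF1", ("bcat_TCF4",), "activation"): 40.0,
    factor_key("TGFB3", ("bcat_TCF4",), "activation"): 60.0,
    factor_key("TGFB3", ("YREG1",), "inhibition"): 25.0,
    factor_key("Vim", ("bcat_LEF1",), "activation"): 10.0,
    factor_key("Vim", ("AP1Sp1",), "activation"): 10.0,
    factor_key("Vim", ("Smad_p_nuc", "LEF1_nuc"), "activation"): 2000.0,
    factor_key("Vim", ("Sp1_p_nuc",), "activation"): 80.0,
    factor_key("FN1", ("bcat_LEF1",), "activation"): 10.0,
    factor_key("FN1", ("AP1Sp1",), "activation"): 10.0,
    factor_key("NFATc1", ("NFAT_nuc",), "activation"): 25.0,
    factor_key("NFATc1", ("Sp1_p_nuc",), "activation"): 40.0,
    factor_key("Sp1", ("Sp1_p_nuc",), "activation"): 40.0,
    factor_key("AP1", ("AP1Sp1",), "activation"): 5.0,
    factor_key("TGFBR", ("Sp1_p_nuc",), "activation"): 40.0,
    factor_key("TGFBR", ("AP1Sp1",), "activation"): 10.0,
    factor_key("Smad", ("Smad_p_nuc",), "inhibition"): 60.0,
    factor_key("CN", ("NFAT_nuc",), "inhibition"): 60.0,
    factor_key("m13", ("YREG1",), "inhibition"): 25.0,
    factor_key("m08", ("GSK3_p",), "activation"): 30.0,
    factor_key("m07", ("GSK3",), "activation"): 30.0,
    factor_key("c05", ("ERK_act",), "inhibition"): 150.0,
    factor_key("c01", ("ERK_act",), "inhibition"): 150.0,
    factor_key("m17", ("GSK3_p",), "activation"): 30.0,
    factor_key("m17", ("Ecad",), "inhibition"): 100.0,
    factor_key("c15", ("Smad_p_nuc",), "inhibition"): 150.0,
    factor_key("m15", ("ERK_act",), "activation"): 30.0,
    factor_key("m40", ("GSK3",), "inhibition"): 150.0,
}


# cooperative (Hill order 2) regulatory edges: the Snail/Slug <-> YREG1
# repression switch needs ultrasensitivity to toggle within 48 h
_NOMINAL_ORDER = {
    factor_key("YREG1", ("Snail",), "inhibition"): 2.0,
    factor_key("YREG1", ("Slug",), "inhibition"): 2.0,
    factor_key("LEF1", ("YREG1",), "inhibition"): 2.0,
    factor_key("TGFB3", ("YREG1",), "inhibition"): 2.0,
    factor_key("m13", ("YREG1",), "inhibition"): 2.0,
}

# transcription factors turn over faster than structural proteins
_NOMINAL_GAMMA = {"Snail": 1.5, "Slug": 1.5, "YREG1": 4.0,
                  "Ecad": 2.0, "Vim": 2.0, "FN1": 2.0}
_NOMINAL_BETA = {"Ecad": 2.0, "Vim": 2.0, "FN1": 2.0}
_NOMINAL_DELTA = {"Snail": 1.5, "Slug": 1.5, "YREG1": 2.0}
_NOMINAL_LAMBDA = {"AP1": 0.01, "Sp1": 0.01, "Snail": 0.008, "Slug": 0.008,
                   "TGFB3": 0.005}
_NOMINAL_ALPHA = {"YREG1": 2.0}


def nominal_parameters(model: ModelDefinition) -> ParameterSet:
    """The nominal parameterization: class defaults plus targeted overrides.

    This is the hand-set starting point the ensemble search perturbs
    within a +/-30% neighborhood.  Rate constants fall into documented
    classes (binding, unbinding, translocation, basal leak, clearance,
    catalysis); factor half-saturations are set relative to the untreated
    abundance of each regulator.
    """
    p = ParameterSet()
    d = _NOMINAL_RATE_DEFAULTS
    for r in model.reactions:
        if r.rate_law == "catalytic":
            p.k[r.id] = _NOMINAL_K_OVERRIDES.get(r.id, d["kcat"])
            p.ksat[r.id] = _NOMINAL_KSAT_OVERRIDES.get(r.id, d["ksat"])
        else:
            if r.id in _NOMINAL_K_OVERRIDES:
                p.k[r.id] = _NOMINAL_K_OVERRIDES[r.id]
            elif len(r.reactants) > 1 or any(-c > 1 for _, c in r.reactants):
                p.k[r.id] = d["binding"]
            elif r.id in ("m02", "m04", "m06", "m08", "m10", "m12", "m14", "m16"):
                p.k[r.id] = d["unbinding"]
            elif r.id in ("m19", "m20", "m21", "m22"):
                p.k[r.id] = d["translocation"]
            elif r.id in ("m30", "m31", "m32", "m33", "m34", "m35", "m36",
                          "m37", "m38", "m39"):
                p.k[r.id] = d["basal"]
            else:
                p.k[r.id] = d["clearance"]
    for c in model.controls:
        for f in c.factors:
            key = factor_key(c.target, f.species, f.direction)
            p.control_half[key] = _NOMINAL_KAPPA.get(key, 50.0)
            p.control_order[key] = _NOMINAL_ORDER.get(key, 1.0)
    for g in model.genes:
        p.alpha[g] = _NOMINAL_ALPHA.get(g, 1.0)
        p.beta[g] = _NOMINAL_BETA.get(g, 1.0)
        p.delta[g] = _NOMINAL_DELTA.get(g, 1.0)
        p.gamma[g] = _NOMINAL_GAMMA.get(g, 1.0)
        p.lambda_const[g] = _NOMINAL_LAMBDA.get(g, 0.003)
    return p


# ---------------------------------------------------------------------------
# conditions
# ---------------------------------------------------------------------------

@dataclass
class Condition:
    """A treatment protocol: ligand doses (a.u., 1 a.u. = 1 nM), inhibitor
    potencies in [0, 1], per-gene expression multipliers, and duration."""

    id: str = "untreated"
    doses: dict[str, float] = field(default_factory=dict)
    inhibitors: dict[str, float] = field(default_factory=dict)
    expression_mods: dict[str, float] = field(default_factory=dict)
    t_end: float = 48.0

    def __post_init__(self):
        for lig, dose in self.doses.items():
            if lig not in _LIGAND_DOSES:
                raise ValueError(f"unknown ligand {lig!r}")
            if dose < 0:
                raise ValueError("doses must be nonnegative")
        for inh, pot in self.inhibitors.items():
            if inh not in KNOWN_INHIBITORS:
                raise ValueError(f"unknown inhibitor {inh!r}")
            if not 0.0 <= pot <= 1.0:
                raise ValueError("inhibitor potency must be in [0, 1]")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")

    def cache_key(self) -> tuple:
        return (
            tuple(sorted(self.doses.items())),
            tuple(sorted(self.inhibitors.items())),
            tuple(sorted(self.expression_mods.items())),
            self.t_end,
        )


@dataclass
class Trajectory:
    times: np.ndarray  # h, strictly increasing
    states: np.ndarray  # (len(times), n_state)
    names: list[str]
    condition: Condition

    def series(self, species: str) -> np.ndarray:
        return self.states[:, self.names.index(species)]

    def endpoint(self, species: str) -> float:
        return float(self.states[-1, self.names.index(species)])


# ---------------------------------------------------------------------------
# model compilation: ModelDefinition -> index arrays for the ODE kernel
# ---------------------------------------------------------------------------

class CompiledModel:
    """Index arrays derived once from a :class:`ModelDefinition`.

    The state vector is [molecular species..., gene loci...]; gene copy
    numbers are constant.  Parameter values are packed separately per
    simulation so one compiled structure serves every parameter set.
    """

    def __init__(self, model: ModelDefinition):
        self.model = model
        mol = model.molecular_species
        self.names = [s.name for s in mol] + [
            gene_species_names(g)[0] for g in model.genes
        ]
        self.index = {n: i for i, n in enumerate(self.names)}
        self.n_mol = len(mol)
        self.n_state = len(self.names)
        self.genes = list(model.genes)

        self.x0 = np.zeros(self.n_state)
        self.fixed = np.zeros(self.n_state, dtype=np.bool_)
        for s in model.species:
            self.x0[self.index[s.name]] = s.initial_value
            self.fixed[self.index[s.name]] = s.fixed or s.kind == "gene"
        self.tau = np.array(
            [s.tau for s in mol] + [1.0] * len(model.genes)
        )

        rxns = model.reactions
        self.reaction_ids = [r.id for r in rxns]
        self.n_rxn = len(rxns)
        from .network import build_stoichiometry

        S = build_stoichiometry(model)
        self.S = np.zeros((self.n_state, self.n_rxn))
        self.S[: self.n_mol, :] = S

        self.is_cat = np.array(
            [r.rate_law == "catalytic" for r in rxns], dtype=np.bool_
        )
        self.enz_idx = np.array(
            [self.index[r.enzyme] if r.enzyme else -1 for r in rxns], dtype=np.int64
        )
        self.sub_idx = np.array(
            [self.index[r.reactants[0][0]] if r.rate_law == "catalytic" else -1
             for r in rxns],
            dtype=np.int64,
        )
        # flattened mass-action reactant lists
        ptr = [0]
        sp, ex = [], []
        for r in rxns:
            if r.rate_law == "mass_action":
                for n, c in r.reactants:
                    sp.append(self.index[n])
                    ex.append(-c)
            ptr.append(len(sp))
        self.ma_ptr = np.array(ptr, dtype=np.int64)
        self.ma_sp = np.array(sp, dtype=np.int64)
        self.ma_exp = np.array(ex, dtype=np.float64)

        # controls: flatten declarations and factors
        self.control_keys = []  # factor keys aligned with factor arrays
        tgt_kind, tgt_idx, rule, fptr = [], [], [], [0]
        fsp1, fsp2, fdir = [], [], []
        gene_pos = {g: i for i, g in enumerate(self.genes)}
        rxn_pos = {rid: j for j, rid in enumerate(self.reaction_ids)}
        for c in model.controls:
            if c.target in rxn_pos:
                tgt_kind.append(0)
                tgt_idx.append(rxn_pos[c.target])
            else:
                tgt_kind.append(1)
                tgt_idx.append(gene_pos[c.target])
            rule.append(0 if c.rule == "min" else 1)
            for f in c.factors:
                self.control_keys.append(factor_key(c.target, f.species, f.direction))
                fsp1.append(self.index[f.species[0]])
                fsp2.append(self.index[f.species[1]] if len(f.species) > 1 else -1)
                fdir.append(1 if f.direction == "activation" else -1)
            fptr.append(len(fsp1))
        self.ctrl_tgt_kind = np.array(tgt_kind, dtype=np.int64)
        self.ctrl_tgt_idx = np.array(tgt_idx, dtype=np.int64)
        self.ctrl_rule = np.array(rule, dtype=np.int64)
        self.ctrl_fptr = np.array(fptr, dtype=np.int64)
        self.fac_sp1 = np.array(fsp1, dtype=np.int64)
        self.fac_sp2 = np.array(fsp2, dtype=np.int64)
        self.fac_dir = np.array(fdir, dtype=np.int64)
        self.n_factor = len(fsp1)

        self.gene_locus = np.array(
            [self.index[gene_species_names(g)[0]] for g in self.genes], dtype=np.int64
        )
        self.gene_mrna = np.array(
            [self.index[gene_species_names(g)[1]] for g in self.genes], dtype=np.int64
        )
        self.gene_prot = np.array(
            [self.index[gene_species_names(g)[2]] for g in self.genes], dtype=np.int64
        )

    # -- parameter packing -------------------------------------------------

    def pack(self, params: ParameterSet) -> tuple[np.ndarray, ...]:
        k = np.array([params.k[rid] for rid in self.reaction_ids])
        ksat = np.array(
            [params.ksat.get(rid, 1.0) for rid in self.reaction_ids]
        )
        kappa = np.array([params.control_half[key] for key in self.control_keys])
        order = np.array([params.control_order[key] for key in self.control_keys])
        alpha = np.array([params.alpha[g] for g in self.genes])
        beta = np.array([params.beta[g] for g in self.genes])
        delta = np.array([params.delta[g] for g in self.genes])
        gamma = np.array([params.gamma[g] for g in self.genes])
        lam = np.array([params.lambda_const[g] for g in self.genes])
        scalars = np.array(
            [params.vmax_t, params.KT, params.vmax_x, params.KX,
             params.kdm, params.kdp, params.mu]
        )
        fac_scale = np.ones(self.n_factor)
        return k, ksat, kappa, order, fac_scale, alpha, beta, delta, gamma, lam, scalars


_COMPILED_CACHE: dict[int, CompiledModel] = {}


def compile_model(model: ModelDefinition) -> CompiledModel:
    key = id(model)
    if key not in _COMPILED_CACHE:
        _COMPILED_CACHE[key] = CompiledModel(model)
    return _COMPILED_CACHE[key]


# ---------------------------------------------------------------------------
# ODE kernel (numba-compiled, numpy fallback)
# ---------------------------------------------------------------------------

def _rhs_impl(
    t, y, S, tau, fixed,
    is_cat, enz_idx, sub_idx, ma_ptr, ma_sp, ma_exp,
    ctrl_tgt_kind, ctrl_tgt_idx, ctrl_rule, ctrl_fptr,
    fac_sp1, fac_sp2, fac_dir,
    k, ksat, kappa, order, fac_scale,
    alpha, beta, delta, gamma, lam,
    gene_locus, gene_mrna, gene_prot, scalars,
):
    n_state = y.shape[0]
    n_rxn = k.shape[0]
    n_gene = gene_locus.shape[0]
    vmax_t, KT, vmax_x, KX, kdm, kdp, mu = (
        scalars[0], scalars[1], scalars[2], scalars[3],
        scalars[4], scalars[5], scalars[6],
    )
    x = np.empty(n_state)
    for i in range(n_state):
        x[i] = y[i] if y[i] > 0.0 else 0.0

    # control coefficients: v per reaction, u per gene (default 1)
    v = np.ones(n_rxn)
    u = np.ones(n_gene)
    for c in range(ctrl_tgt_kind.shape[0]):
        rule = ctrl_rule[c]
        agg = 1.0e30 if rule == 0 else -1.0e30
        for f in range(ctrl_fptr[c], ctrl_fptr[c + 1]):
            val = x[fac_sp1[f]]
            if fac_sp2[f] >= 0:
                val *= x[fac_sp2[f]]
            n = order[f]
            if val > 0.0:
                vn = val**n
                h = vn / (kappa[f] ** n + vn)
            else:
                h = 0.0
            h *= fac_scale[f]
            if fac_dir[f] < 0:
                h = 1.0 - h
            if rule == 0:
                if h < agg:
                    agg = h
            else:
                if h > agg:
                    agg = h
        if ctrl_tgt_kind[c] == 0:
            v[ctrl_tgt_idx[c]] = agg
        else:
            u[ctrl_tgt_idx[c]] = agg

    # reaction rates
    r = np.empty(n_rxn)
    for j in range(n_rxn):
        if is_cat[j]:
            s = x[sub_idx[j]]
            r[j] = k[j] * x[enz_idx[j]] * s / (ksat[j] + s) * v[j]
        else:
            rate = k[j]
            for q in range(ma_ptr[j], ma_ptr[j + 1]):
                e = ma_exp[q]
                xv = x[ma_sp[q]]
                if e == 1.0:
                    rate *= xv
                else:
                    rate *= xv**e
            r[j] = rate * v[j]

    dx = np.zeros(n_state)
    for i in range(n_state):
        if fixed[i]:
            continue
        acc = 0.0
        for j in range(n_rxn):
            sij = S[i, j]
            if sij != 0.0:
                acc += sij * r[j]
        dx[i] = (acc - mu * x[i]) / tau[i]

    # gene expression: transcription / translation balances
    for g in range(n_gene):
        G = x[gene_locus[g]]
        m = x[gene_mrna[g]]
        dx[gene_mrna[g]] += (
            u[g] * alpha[g] * vmax_t * G / (KT + G) - delta[g] * kdm * m + lam[g]
        )
        dx[gene_prot[g]] += (
            beta[g] * vmax_x * m / (KX + m) - gamma[g] * kdp * x[gene_prot[g]]
        )
    return dx


try:  # pragma: no cover - exercised implicitly everywhere
    import numba

    _rhs_kernel = numba.njit(_rhs_impl, cache=True, fastmath=False)
except Exception:  # pragma: no cover
    _rhs_kernel = _rhs_impl


def _kernel_args(cm: CompiledModel, packed, fixed=None):
    (k, ksat, kappa, order, fac_scale, alpha, beta, delta, gamma, lam,
     scalars) = packed
    if fixed is None:
        fixed = cm.fixed
    return (
        cm.S, cm.tau, fixed,
        cm.is_cat, cm.enz_idx, cm.sub_idx, cm.ma_ptr, cm.ma_sp, cm.ma_exp,
        cm.ctrl_tgt_kind, cm.ctrl_tgt_idx, cm.ctrl_rule, cm.ctrl_fptr,
        cm.fac_sp1, cm.fac_sp2, cm.fac_dir,
        k, ksat, kappa, order, fac_scale,
        alpha, beta, delta, gamma, lam,
        cm.gene_locus, cm.gene_mrna, cm.gene_prot, scalars,
    )


def rhs(t, state, model, params: ParameterSet, condition: Condition | None = None):
    """Derivative vector at (t, state) — reference entry point.

    ``state`` is ordered [molecular species..., gene loci...] as in
    ``compile_model(model).names``.
    """
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    state = np.asarray(state, dtype=float)
    if state.shape[0] != cm.n_state:
        raise ValueError(
            f"state length {state.shape[0]} != {cm.n_state} "
            "(molecular species + genes)"
        )
    if condition is not None:
        params, _ = apply_condition(cm, params, condition)
    packed = cm.pack(params)
    fixed = None
    if condition is not None:
        _apply_condition_packed(cm, condition, packed)
        fixed = _condition_fixed(cm, condition)
    return _rhs_kernel(float(t), state, *_kernel_args(cm, packed, fixed))


# ---------------------------------------------------------------------------
# conditions -> modified parameters / initial state
# ---------------------------------------------------------------------------

def apply_condition(
    model, params: ParameterSet, condition: Condition
) -> tuple[ParameterSet, np.ndarray]:
    """Fold a treatment protocol into (parameters, initial state).

    Ligand doses set ligand initial values (1 a.u. = 1 nM); inhibitors
    scale their target catalytic constant or transcription-factor
    transfer-function output by (1 - potency); expression multipliers act
    on the constitutive rate lambda_j (and on alpha_j for
    overexpression).
    """
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    p = params.copy()
    x0 = cm.x0.copy()
    for lig, dose in condition.doses.items():
        x0[cm.index[_LIGAND_DOSES[lig]]] = dose  # 1 a.u. == 1 nM
    for inh, pot in condition.inhibitors.items():
        rid = _INHIBITOR_REACTION.get(inh)
        if rid is not None:
            p.k[rid] = p.k[rid] * (1.0 - pot)
    for gene, m in condition.expression_mods.items():
        if gene not in p.lambda_const:
            raise ValueError(f"unknown gene {gene!r} in expression_mods")
        p.lambda_const[gene] *= m
        if m > 1.0:
            p.alpha[gene] *= m
        elif m == 0.0:
            p.alpha[gene] = 0.0
    return p, x0


def _condition_fixed(cm: CompiledModel, condition: Condition) -> np.ndarray:
    """Dosed ligands are held at their dose for the whole treatment
    (constant-concentration bath); secreted autocrine ligands stay dynamic."""
    fixed = cm.fixed.copy()
    for lig in condition.doses:
        fixed[cm.index[_LIGAND_DOSES[lig]]] = True
    return fixed


def _apply_condition_packed(cm: CompiledModel, condition: Condition, packed):
    """Apply dominant-negative constructs to the packed factor scales."""
    fac_scale = packed[4]
    for inh, pot in condition.inhibitors.items():
        targets = _DN_SPECIES.get(inh)
        if not targets:
            continue
        names = set(targets)
        for f, key in enumerate(cm.control_keys):
            sp = key.split("|")[1].split("*")
            if names & set(sp):
                fac_scale[f] *= 1.0 - pot


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

NEGATIVE_TOLERANCE = -1e-8


class IntegrationError(RuntimeError):
    pass


def simulate(
    model,
    params: ParameterSet,
    condition: Condition | None = None,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> Trajectory:
    """Integrate the model under a treatment condition with a stiff solver.

    Small negative excursions (above -1e-8) are clamped to zero; larger
    ones or integrator failures raise :class:`IntegrationError`.
    """
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    condition = condition or Condition()
    p, x0 = apply_condition(cm, params, condition)
    packed = cm.pack(p)
    _apply_condition_packed(cm, condition, packed)
    args = _kernel_args(cm, packed, _condition_fixed(cm, condition))
    if t_eval is None:
        t_eval = np.linspace(0.0, condition.t_end, 49)
    t_eval = np.asarray(t_eval, dtype=float)

    sol = solve_ivp(
        lambda t, y: _rhs_kernel(t, y, *args),
        (0.0, float(condition.t_end)),
        x0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed for condition {condition.id!r} at "
            f"t={sol.t[-1] if len(sol.t) else 0.0:.3f} h: {sol.message}"
        )
    states = sol.y.T.copy()
    if not np.all(np.isfinite(states)):
        raise IntegrationError(f"non-finite state in condition {condition.id!r}")
    worst = states.min()
    if worst < NEGATIVE_TOLERANCE * max(1.0, np.abs(states).max()):
        raise IntegrationError(
            f"negative excursion {worst:.3e} in condition {condition.id!r}"
        )
    np.clip(states, 0.0, None, out=states)
    return Trajectory(sol.t.copy(), states, list(cm.names), condition)


def steady_state(
    model,
    params: ParameterSet,
    condition: Condition | None = None,
    t_max: float = 3000.0,
    rhs_tol: float = 1e-4,
) -> tuple[np.ndarray, float]:
    """Relax to the (quasi-)steady state; returns (state, residual).

    residual = ||dx/dt|| / ||x|| at the final time.  A residual above
    ``rhs_tol`` raises :class:`IntegrationError`.
    """
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    condition = condition or Condition(t_end=t_max)
    condition = Condition(
        id=condition.id, doses=dict(condition.doses),
        inhibitors=dict(condition.inhibitors),
        expression_mods=dict(condition.expression_mods), t_end=t_max,
    )
    traj = simulate(cm, params, condition, t_eval=np.array([0.0, t_max]))
    x = traj.states[-1]
    dx = rhs(t_max, x, cm, params, condition)
    res = float(np.linalg.norm(dx) / max(np.linalg.norm(x), 1e-12))
    if res > rhs_tol:
        raise IntegrationError(f"no steady state reached: residual {res:.3e}")
    return x, res
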