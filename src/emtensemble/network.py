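"""Plain-text network grammar for the EMT signaling / gene-expression model.

The model is declared in a line-oriented text format (one declaration per
line, ``#`` comments).  Four statement kinds exist:

``species NAME kind=K compartment=C init=X [tau=T] [fixed]``
    A molecular species.  ``kind`` is one of ``gene, mRNA, protein,
    complex, ligand, drug``.  ``fixed`` marks a boundary species whose
    abundance is held constant (receptor pools, the phosphatase pool).

``gene NAME [mrna_init=X] [protein_init=Y] [compartment=C]``
    Shorthand declaring a gene locus together with its paired transcript
    and protein: species ``NAME_gene`` (2 copies/cell, nucleus),
    ``NAME_mRNA`` and ``NAME`` (the free protein).

``reaction ID catalytic ENZYME : SUBSTRATE -> PRODUCTS``
``reaction ID mass_action : [n] A + [m] B -> PRODUCTS``
    An irreversible signaling reaction.  Reversible binding is written as
    two irreversible entries.  Catalytic reactions carry exactly one
    enzyme and one saturating substrate.

``control TARGET rule=min|max : activation F ; inhibition G*H ; ...``
    A regulatory declaration.  ``TARGET`` is a reaction id (activity
    control, v_j) or a gene name (expression control, u_j).  Each factor
    is a species or a ``*``-product of species; inhibitory factors enter
    the integration rule as ``1 - f``.

A formal EBNF of the grammar is in ``docs/model-grammar.md``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

SPECIES_KINDS = ("gene", "mRNA", "protein", "complex", "ligand", "drug")
COMPARTMENTS = ("extracellular", "cytosol", "nucleus", "membrane")

GENE_SUFFIX = "_gene"
MRNA_SUFFIX = "_mRNA"

GENE_COPIES = 2.0  # diploid locus, copies per cell


class ModelSyntaxError(ValueError):
    """Raised for malformed model text; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class SpeciesDecl:
    name: str
    kind: str
    compartment: str
    initial_value: float
    tau: float = 1.0
    fixed: bool = False


@dataclass
class ReactionDecl:
    id: str
    rate_law: str  # "catalytic" | "mass_action"
    reactants: list[tuple[str, float]]  # (species, stoichiometric coefficient < 0)
    products: list[tuple[str, float]]  # (species, coefficient > 0)
    enzyme: str | None = None


@dataclass
class ControlFactor:
    species: tuple[str, ...]  # one name, or several for a product factor
    direction: str  # "activation" | "inhibition"


@dataclass
class ControlDecl:
    target: str  # reaction id or gene name
    rule: str  # "min" | "max"
    factors: list[ControlFactor]


@dataclass
class ModelDefinition:
    species: list[SpeciesDecl] = field(default_factory=list)
    reactions: list[ReactionDecl] = field(default_factory=list)
    controls: list[ControlDecl] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)

    def species_by_name(self) -> dict[str, SpeciesDecl]:
        return {s.name: s for s in self.species}

    @property
    def molecular_species(self) -> list[SpeciesDecl]:
        """Species that enter the ODE state (everything except gene loci)."""
        return [s for s in self.species if s.kind != "gene"]


@dataclass
class StructuralCounts:
    nodes: int
    interactions: int
    molecular_species: int
    genes: int
    kinetic_params: int
    control_params: int
    saturation_params: int

    @property
    def total_params(self) -> int:
        return self.kinetic_params + self.control_params + self.saturation_params

    def as_dict(self) -> dict[str, int]:
        d = {
            "nodes": self.nodes,
            "interactions": self.interactions,
            "molecular_species": self.molecular_species,
            "genes": self.genes,
            "kinetic_params": self.kinetic_params,
            "control_params": self.control_params,
            "saturation_params": self.saturation_params,
        }
        d["total_params"] = self.total_params
        return d


def gene_species_names(gene: str) -> tuple[str, str, str]:
    """(locus, mRNA, protein) species names for a gene."""
    return gene + GENE_SUFFIX, gene + MRNA_SUFFIX, gene


def _parse_kv(tokens: list[str], lineno: int) -> dict[str, str]:
    out = {}
    for tok in tokens:
        if tok == "fixed":
            out["fixed"] = "true"
            continue
        if "=" not in tok:
            raise ModelSyntaxError(f"expected key=value, got {tok!r}", lineno)
        k, v = tok.split("=", 1)
        out[k] = v
    return out


def _parse_side(text: str, lineno: int) -> list[tuple[str, float]]:
    """Parse 'A + 2 B' into [(A, 1.0), (B, 2.0)]. Empty text -> []."""
    text = text.strip()
    if not text:
        return []
    entries = []
    for term in text.split("+"):
        parts = term.split()
        if len(parts) == 1:
            entries.append((parts[0], 1.0))
        elif len(parts) == 2:
            try:
                coeff = float(parts[0])
            except ValueError:
                raise ModelSyntaxError(
                    f"bad stoichiometric coefficient {parts[0]!r}", lineno
                ) from None
            entries.append((parts[1], coeff))
        else:
            raise ModelSyntaxError(f"malformed reaction term {term.strip()!r}", lineno)
    return entries


def parse_model_definition(text: str) -> ModelDefinition:
    """Parse a model-grammar document into a validated :class:`ModelDefinition`.

    Raises :class:`ModelSyntaxError` (with line number) on malformed input
    and ``ValueError`` on semantic problems (dangling references,
    duplicate names).
    """
    model = ModelDefinition()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        kw = tokens[0]
        if kw == "species":
            if len(tokens) < 3:
                raise ModelSyntaxError("species needs a name and attributes", lineno)
            name = tokens[1]
            kv = _parse_kv(tokens[2:], lineno)
            missing = {"kind", "compartment", "init"} - set(kv)
            if missing:
                raise ModelSyntaxError(
                    f"species {name}: missing {sorted(missing)}", lineno
                )
            if kv["kind"] not in SPECIES_KINDS:
                raise ModelSyntaxError(f"unknown species kind {kv['kind']!r}", lineno)
            if kv["compartment"] not in COMPARTMENTS:
                raise ModelSyntaxError(
                    f"unknown compartment {kv['compartment']!r}", lineno
                )
            model.species.append(
                SpeciesDecl(
                    name=name,
                    kind=kv["kind"],
                    compartment=kv["compartment"],
                    initial_value=float(kv["init"]),
                    tau=float(kv.get("tau", 1.0)),
                    fixed=kv.get("fixed") == "true",
                )
            )
        elif kw == "gene":
            if len(tokens) < 2:
                raise ModelSyntaxError("gene needs a name", lineno)
            name = tokens[1]
            kv = _parse_kv(tokens[2:], lineno)
            locus, mrna, prot = gene_species_names(name)
            comp = kv.get("compartment", "cytosol")
            if comp not in COMPARTMENTS:
                raise ModelSyntaxError(f"unknown compartment {comp!r}", lineno)
            model.genes.append(name)
            model.species.append(
                SpeciesDecl(locus, "gene", "nucleus", GENE_COPIES, fixed=True)
            )
            model.species.append(
                SpeciesDecl(mrna, "mRNA", "cytosol", float(kv.get("mrna_init", 0.0)))
            )
            model.species.append(
                SpeciesDecl(prot, "protein", comp, float(kv.get("protein_init", 0.0)))
            )
        elif kw == "reaction":
            if len(tokens) < 3 or ":" not in line:
                raise ModelSyntaxError("malformed reaction declaration", lineno)
            rid = tokens[1]
            law = tokens[2]
            if law not in ("catalytic", "mass_action"):
                raise ModelSyntaxError(f"unknown rate law {law!r}", lineno)
            head, body = line.split(":", 1)
            enzyme = None
            if law == "catalytic":
                head_tokens = head.split()
                if len(head_tokens) != 4:
                    raise ModelSyntaxError(
                        "catalytic reaction needs exactly one enzyme", lineno
                    )
                enzyme = head_tokens[3]
            if "->" not in body:
                raise ModelSyntaxError("reaction body needs '->'", lineno)
            lhs, rhs = body.split("->", 1)
            reactants = [(s, -c) for s, c in _parse_side(lhs, lineno)]
            products = _parse_side(rhs, lineno)
            if law == "catalytic" and len(reactants) != 1:
                raise ModelSyntaxError(
                    "catalytic reaction needs exactly one saturating substrate", lineno
                )
            if law == "mass_action" and not reactants:
                raise ModelSyntaxError("mass-action reaction needs >= 1 reactant", lineno)
            model.reactions.append(ReactionDecl(rid, law, reactants, products, enzyme))
        elif kw == "control":
            if ":" not in line or len(tokens) < 3:
                raise ModelSyntaxError("malformed control declaration", lineno)
            head, body = line.split(":", 1)
            head_tokens = head.split()
            if len(head_tokens) != 3 or not head_tokens[2].startswith("rule="):
                raise ModelSyntaxError("control needs 'control TARGET rule=...'", lineno)
            target = head_tokens[1]
            rule = head_tokens[2].split("=", 1)[1]
            if rule not in ("min", "max"):
                raise ModelSyntaxError(f"integration rule must be min or max", lineno)
            factors = []
            for clause in body.split(";"):
                parts = clause.split()
                if len(parts) != 2 or parts[0] not in ("activation", "inhibition"):
                    raise ModelSyntaxError(
                        f"malformed control factor {clause.strip()!r}", lineno
                    )
                factors.append(
                    ControlFactor(tuple(parts[1].split("*")), direction=parts[0])
                )
            if not factors:
                raise ModelSyntaxError("control declaration without factors", lineno)
            model.controls.append(ControlDecl(target, rule, factors))
        else:
            raise ModelSyntaxError(f"unknown declaration {kw!r}", lineno)

    report = validate_model(model)
    fatal = [v for v in report if v.startswith(("duplicate", "undeclared"))]
    if fatal:
        raise ValueError("invalid model: " + "; ".join(fatal))
    return model


def write_model_definition(model: ModelDefinition) -> str:
    """Serialize a model back to grammar text (parse/write round-trips)."""
    lines = []
    gene_aux = set()
    for g in model.genes:
        gene_aux.update(gene_species_names(g))
    by_name = model.species_by_name()
    for g in model.genes:
        _, mrna, prot = gene_species_names(g)
        attrs = [f"mrna_init={by_name[mrna].initial_value:g}",
                 f"protein_init={by_name[prot].initial_value:g}"]
        if by_name[prot].compartment != "cytosol":
            attrs.append(f"compartment={by_name[prot].compartment}")
        lines.append(f"gene {g} " + " ".join(attrs))
    for s in model.species:
        if s.name in gene_aux:
            continue
        attrs = [f"kind={s.kind}", f"compartment={s.compartment}",
                 f"init={s.initial_value:g}"]
        if s.tau != 1.0:
            attrs.append(f"tau={s.tau:g}")
        if s.fixed:
            attrs.append("fixed")
        lines.append(f"species {s.name} " + " ".join(attrs))

    def side(entries, sign):
        return " + ".join(
            (f"{sign * c:g} {n}" if sign * c != 1.0 else n) for n, c in entries
        )

    for r in model.reactions:
        lhs = side(r.reactants, -1)
        rhs = side(r.products, 1)
        if r.rate_law == "catalytic":
            lines.append(f"reaction {r.id} catalytic {r.enzyme} : {lhs} -> {rhs}")
        else:
            lines.append(f"reaction {r.id} mass_action : {lhs} -> {rhs}")
    for c in model.controls:
        clauses = " ; ".join(
            f"{f.direction} {'*'.join(f.species)}" for f in c.factors
        )
        lines.append(f"control {c.target} rule={c.rule} : {clauses}")
    return "\n".join(lines) + "\n"


def validate_model(model: ModelDefinition) -> list[str]:
    """Check model invariants; returns an itemized list of violations.

    An empty report means the model is internally consistent: unique
    names, no dangling references, gene mRNA/protein pairing, catalytic
    arity, positive time-scale factors and nonnegative initial values.
    """
    report = []
    names = [s.name for s in model.species]
    seen = set()
    for n in names:
        if n in seen:
            report.append(f"duplicate species name {n}")
        seen.add(n)
    declared = set(names)
    for s in model.species:
        if s.initial_value < 0:
            report.append(f"species {s.name}: negative initial value")
        if s.tau <= 0:
            report.append(f"species {s.name}: tau must be > 0")
    for g in model.genes:
        for part, label in zip(gene_species_names(g), ("locus", "mRNA", "protein")):
            if part not in declared:
                report.append(f"gene {g}: missing paired {label} species {part}")
    rids = set()
    for r in model.reactions:
        if r.id in rids:
            report.append(f"duplicate reaction id {r.id}")
        rids.add(r.id)
        for n, c in r.reactants + r.products:
            if n not in declared:
                report.append(f"undeclared species {n} in reaction {r.id}")
        if r.rate_law == "catalytic":
            if r.enzyme is None:
                report.append(f"reaction {r.id}: catalytic without enzyme")
            elif r.enzyme not in declared:
                report.append(f"undeclared species {r.enzyme} enzyme of {r.id}")
            if len(r.reactants) != 1:
                report.append(f"reaction {r.id}: catalytic needs one substrate")
        else:
            if not r.reactants:
                report.append(f"reaction {r.id}: mass-action needs >= 1 reactant")
        for n, c in r.reactants:
            if c >= 0:
                report.append(f"reaction {r.id}: reactant coefficient must be < 0")
        for n, c in r.products:
            if c <= 0:
                report.append(f"reaction {r.id}: product coefficient must be > 0")
    gene_set = set(model.genes)
    seen_targets = set()
    for c in model.controls:
        if c.target not in rids and c.target not in gene_set:
            report.append(f"control target {c.target} is neither reaction nor gene")
        if c.target in seen_targets:
            report.append(f"control target {c.target} declared twice")
        seen_targets.add(c.target)
        for f in c.factors:
            for n in f.species:
                if n not in declared:
                    report.append(f"undeclared species {n} in control of {c.target}")
    return report


def count_components(model: ModelDefinition) -> StructuralCounts:
    """Structural bookkeeping under the documented counting convention.

    * nodes = molecular species + gene loci
    * interactions = signaling reactions + control declarations
      + one expression edge and one translation edge per gene
    * kinetic parameters = one rate constant per signaling reaction
      + per-gene transcription, translation and constitutive-rate slots
    * control parameters = one half-saturation per transfer-function factor
    * saturation parameters = one per catalytic reaction
    """
    n_mol = len(model.molecular_species)
    n_gene = len(model.genes)
    n_rxn = len(model.reactions)
    n_ctrl_decl = len(model.controls)
    n_factors = sum(len(c.factors) for c in model.controls)
    n_cat = sum(1 for r in model.reactions if r.rate_law == "catalytic")
    return StructuralCounts(
        nodes=n_mol + n_gene,
        interactions=n_rxn + n_ctrl_decl + 2 * n_gene,
        molecular_species=n_mol,
        genes=n_gene,
        kinetic_params=n_rxn + 3 * n_gene,
        control_params=n_factors,
        saturation_params=n_cat,
    )


def build_stoichiometry(model: ModelDefinition) -> np.ndarray:
    """Signed stoichiometric matrix over (molecular species x reactions).

    Entry (i, j) is the net coefficient of species i in reaction j; rows
    of species untouched by a reaction are zero.  Catalytic enzymes are
    not consumed and do not appear unless they are also products.
    """
    mol = model.molecular_species
    index = {s.name: i for i, s in enumerate(mol)}
    S = np.zeros((len(mol), len(model.reactions)))
    for j, r in enumerate(model.reactions):
        for n, c in r.reactants + r.products:
            S[index[n], j] += c
    return S


def load_packaged_model() -> ModelDefinition:
    """Load the EMT network shipped with the package."""
    text = (
        importlib.resources.files("emtensemble")
        .joinpath("data/emt_network.txt")
        .read_text()
    )
    return parse_model_definition(text)
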