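# Model grammar

The network is declared in a line-oriented UTF-8 text file: one
declaration per line, `#` starts a comment, blank lines are ignored.
The packaged EMT network (`src/emtensemble/data/emt_network.txt`) is
written in this grammar.

## EBNF

```
document     = { line } ;
line         = [ declaration ] [ "#" comment ] newline ;
declaration  = species | gene | reaction | control ;

species      = "species" name "kind=" kind "compartment=" compartment
               "init=" number [ "tau=" number ] [ "fixed" ] ;
kind         = "gene" | "mRNA" | "protein" | "complex" | "ligand" | "drug" ;
compartment  = "extracellular" | "cytosol" | "nucleus" | "membrane" ;

gene         = "gene" name [ "mrna_init=" number ] [ "protein_init=" number ]
               [ "compartment=" compartment ] ;

reaction     = "reaction" id ( "catalytic" name | "mass_action" )
               ":" side "->" side ;
side         = [ term { "+" term } ] ;
term         = [ number ] name ;

control      = "control" target "rule=" ( "min" | "max" )
               ":" factor { ";" factor } ;
target       = id | name ;               (* reaction id or gene name *)
factor       = ( "activation" | "inhibition" ) name { "*" name } ;
```

## Semantics

* `species` declares one molecular species with an initial abundance
  (nM; copies/cell for gene loci).  `tau` is the per-species time-scale
  multiplier (1 everywhere in this study).  `fixed` marks a boundary
  species whose abundance is held constant (receptor pools, the lumped
  phosphatase).
* `gene NAME` is shorthand for three species — the locus `NAME_gene`
  (kind `gene`, nucleus, 2 copies/cell, constant), the transcript
  `NAME_mRNA` (cytosol) and the free protein `NAME` — and registers the
  gene for the transcription/translation balances.  This makes the
  "every gene has exactly one mRNA and one protein partner" invariant
  true by construction for files; hand-assembled models are checked by
  `validate_model`.
* `reaction ... catalytic E : S -> P` is an enzyme-catalyzed step with
  saturation kinetics `kcat * E * S/(Ksat + S)`; exactly one enzyme and
  one saturating substrate.  `mass_action` steps use
  `kmax * prod x^(-sigma)`; reversible binding is always written as two
  irreversible lines.  An empty right-hand side denotes degradation.
* `control` attaches transfer-function factors to a reaction (activity
  coefficient `v_j`) or a gene (expression coefficient `u_j`).  Each
  factor is a Hill function of one species, or of a product of species
  for co-dependent regulation; inhibitory factors enter as `1 - f`.
  The declaration's `rule` combines all factor outputs by `min` or
  `max`; a target declared nowhere has coefficient exactly 1.

## Counting convention

`count_components` reports, for a parsed model:

| quantity            | definition                                                      |
|---------------------|-----------------------------------------------------------------|
| nodes               | molecular species + gene loci                                   |
| interactions        | reactions + control declarations + 2 per gene (expr./transl.)   |
| kinetic parameters  | 1 rate constant per reaction + 3 slots per gene (transcription, translation, constitutive rate) |
| control parameters  | 1 half-saturation per transfer-function factor                  |
| saturation params   | 1 per catalytic reaction                                        |

For the packaged network: 97 nodes = 74 + 23, 169 interactions =
100 + 23 + 46, and 251 = 169 + 38 + 44 searched parameters.  The four
per-gene correction factors (α, β, δ, γ) adjust characteristic
expression constants and are accounted separately from the 251.
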