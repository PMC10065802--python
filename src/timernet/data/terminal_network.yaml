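# Canonical Drosophila posterior-terminal patterning network, v1.
#
# Regions 1-4 = trunk, tail, hindgut, posterior midgut.
# Timepoints t0-t3 = nuclear cycle 13, early stage 5, mid stage 5, stage 6.
# Levels: 0 = off, 1 = weak/on, 2 = strong.
# Rules are referenced by identifier and resolved in code
# (timernet.terminal.RULE_REGISTRY).
name: drosophila_terminal
n_regions: 4
n_timepoints: 4
rules: drosophila_terminal_v1

factors:
  - {name: Tll, max_level: 2, role: input}
  - {name: Hkb, max_level: 2, role: input}
  - {name: Fkh, max_level: 1, role: output}
  - {name: Wg,  max_level: 1, role: output}
  - {name: Cad, max_level: 1, role: output}
  - {name: D,   max_level: 2, role: output}
  - {name: Opa, max_level: 2, role: output}

# Output levels at t0; Cad is maternally deposited, hence on everywhere.
initial:
  Cad: 1

# Hard-coded input grids: one row per region (1-4), one column per timepoint.
# The trunk sees neither input; the tail sees weak, transient Tll; the
# hindgut sees strong Tll plus weak, transient Hkb; the posterior midgut sees
# strong Tll plus strong Hkb, with Hkb persisting weakly after gastrulation.
schedule:
  Tll:
    - [0, 0, 0, 0]
    - [1, 1, 0, 0]
    - [2, 2, 2, 0]
    - [2, 2, 2, 0]
  Hkb:
    - [0, 0, 0, 0]
    - [0, 0, 0, 0]
    - [1, 1, 0, 0]
    - [2, 2, 2, 1]

# Null mutants are clamps: the listed factors are held at 0 everywhere.
# tor- removes Torso signalling and with it all posterior Tll and Hkb.
genotypes:
  - {name: wild_type, label: wild-type, clamped: []}
  - {name: fkh, label: fkh-, clamped: [Fkh]}
  - {name: cad_mz, label: cad(m-z-), clamped: [Cad]}
  - {name: D, label: D-, clamped: [D]}
  - {name: opa, label: opa-, clamped: [Opa]}
  - {name: tor, label: tor-, clamped: [Tll, Hkb]}
  - {name: hkb, label: hkb-, clamped: [Hkb]}
  - {name: tll, label: tll-, clamped: [Tll]}
  - {name: tll_opa, label: tll- opa-, clamped: [Tll, Opa]}

# 18 regulatory edges; provenance this_study marks the 11 newly inferred
# interactions, literature the 7 previously proposed ones.  threshold is the
# minimum source level at which the effect applies.  functional: false marks
# net/indirect edges that the rule table does not encode as separate terms.
interactions:
  - {source: Opa, target: Cad, sign: repression, directness: direct, provenance: this_study, threshold: 2}
  - {source: D,   target: Cad, sign: repression, directness: direct, provenance: this_study, threshold: 1}
  - {source: Cad, target: D,   sign: activation, directness: direct, provenance: this_study, threshold: 1}
  - {source: Opa, target: D,   sign: repression, directness: direct, provenance: this_study, threshold: 2}
  - {source: Tll, target: Cad, sign: repression, directness: direct, provenance: this_study, threshold: 2}
  - {source: Tll, target: D,   sign: repression, directness: direct, provenance: this_study, threshold: 1}
  - {source: Tll, target: Opa, sign: repression, directness: direct, provenance: this_study, threshold: 1}
  - {source: Hkb, target: Cad, sign: repression, directness: direct, provenance: this_study, threshold: 2}
  - {source: Hkb, target: D,   sign: repression, directness: direct, provenance: this_study, threshold: 1}
  - {source: Hkb, target: Opa, sign: repression, directness: direct, provenance: this_study, threshold: 2}
  - {source: Hkb, target: Wg,  sign: repression, directness: direct, provenance: this_study, threshold: 2}
  - {source: Fkh, target: Wg,  sign: activation, directness: direct, provenance: literature, threshold: 1}
  - {source: Cad, target: Fkh, sign: activation, directness: direct, provenance: literature, threshold: 1}
  - {source: Tll, target: Fkh, sign: activation, directness: indirect, provenance: literature, threshold: 2}
  - {source: Hkb, target: Fkh, sign: activation, directness: indirect, provenance: literature, threshold: 2}
  - {source: Fkh, target: Fkh, sign: activation, directness: direct, provenance: literature, threshold: 1}
  - {source: Cad, target: Wg,  sign: activation, directness: indirect, provenance: literature, threshold: 1, functional: false}
  - {source: Fkh, target: Cad, sign: repression, directness: indirect, provenance: literature, threshold: 1, functional: false}
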