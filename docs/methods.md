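# Methods

## Model framework

The core model is a synchronous multi-valued logical network. Each factor
is an ordinal variable with levels `0..max_level`; the state at timepoint
t+1 is computed from the complete state at t by one pure rule per output
factor, identical at every timepoint. There is no within-step ordering, no
asynchrony, and no stochasticity: two runs with equal arguments are
bit-identical, and no part of the network engine takes a seed. The
anteroposterior axis is discretised into regions that are simulated
independently — the biological assumption being that over the ~40 minutes
of blastoderm patterning modelled here, diffusion and cell movement are
negligible relative to the transcriptional dynamics, so each region's fate
is set by its own input history.

Mutants are modelled as clamps: the null factor is forced to level 0 at
every region and timepoint, *after* rule evaluation and schedule lookup.
Clamping after evaluation (including at t0) means a clamped maternal factor
never shows its initial condition, which is the intended reading of a
protein-null genotype.

### The terminal network

The canonical instantiation has seven factors. Tll and Hkb are inputs —
their expression is driven by terminal Torso signalling, which the model
does not mechanistically represent, so their levels are hard-coded grids
over 4 regions × 4 timepoints. The grids encode the imaging observations
that the two repressors form nested posterior domains (Tll reaching further
from the pole than Hkb), that the tail sees only weak, transient Tll, that
*tll* fades by stage 6 while *hkb* persists weakly after gastrulation, and
that the trunk is free of both. Cross-regulation of *tll* by Hkb is
deliberately omitted (the network treats the inputs as independent), which
is why the model cannot produce the concerted fate-map shifts seen in
*hkb⁻* and *D⁻* embryos — there is no representation of region size or of
input-domain geometry to shift.

The five output rules encode net regulatory logic with explicit
strong/weak thresholds:

* weak Tll suffices to repress *D* and *opa* but not *cad* — this single
  asymmetry is what delays the timer sequence in the tail without
  truncating it;
* weak Hkb represses *D* but not *opa*, *cad* or *wg*;
* Cad boosts *D* activation from weak to strong (the *D* rule's weak
  default-activation represents activation by ubiquitous maternal factors
  that the model does not name);
* Opa accumulates as a ratchet (`min(Opa+1, 2)`) with no timer-gene input —
  *opa* is an input-only component of the blastoderm module — and resets to
  0 if repression reappears (a case the shipped monotone-decay schedules
  never produce);
* Fkh requires Cad plus a *strong* terminal input, and is then
  self-maintaining, so hindgut/posterior-midgut identity persists after the
  terminal inputs decay; Wg requires Fkh and is vetoed by strong Hkb.

Cad is default-on (no activator is modelled): maternal deposition justifies
presence absent repression, and the t0 condition "Cad on everywhere"
follows from the rule itself rather than being a special case.

The 18-edge interaction table is metadata over these rules: source, target,
sign, directness, provenance (11 edges newly inferred from the mutant
analysis, 7 previously proposed) and acting threshold. Two edges are
metadata-only by construction: Cad→Wg is a net indirect effect realised
through Fkh, and Fkh⊣Cad is recorded as tentative but not encoded (the
evidence for it is inconclusive). These two are the documented exceptions
to the edge-necessity property; deleting any of the other 16 edges breaks
at least one expectation in the shipped suite, which the test suite
verifies edge by edge.

## The expectation suite

Each qualitative claim about a genotype is one `Expectation`: a decidable
predicate over trajectories plus the verbatim observation it
operationalizes. Three informal notions are made precise:

* **delayed repression** — strictly later first-off time than the reference
  genotype, where first-off is the earliest timepoint at which a previously
  expressed factor reads 0. A factor that never switches off is ordered
  after every finite time (this is how *opa⁻*, where D decays to weak but
  never off, counts as delayed). Because "delayed" alone would also be
  satisfied by outright loss of repression, delay claims ship together with
  an eventual-repression check (e.g. *D⁻* trunk Cad must still be off by
  t3).
* **reduced activation** — strictly lower maximum level over the
  simulation (*cad*^m−z−^ D: weak vs strong).
* **transformed into** — exact equality of level time-series over a stated
  factor subset; for *tll⁻ opa⁻* region 3 vs wild-type region 2 the subset
  is {Cad, D}, since Opa is clamped and whole-state equality is impossible
  by construction.

For *hkb⁻*, Fkh/Wg expectations assert eventual presence (on by t3) rather
than onset timing: the discrete implementation of time and Fkh regulation
makes onset in this genotype sensitive to representation choices that the
model does not resolve, so timing there is treated as non-normative.

The shipped suite has 43 expectations covering all nine genotypes; 100%
must pass on the canonical network, and the evaluation is a pure function
of (trajectories, suite).

## The sequential variant

The variant asks whether the blastoderm timer module, minimally rewired,
yields segment-addition-zone dynamics on a growing 1-D cell row. Three
modifications are made, each a documented reconstruction choice and each
individually toggleable on `VariantConfig`:

1. **Wnt-dependent Cad.** Cad is on iff the cell saw Wnt (a binary
   positional input held by the posterior-most `wnt_range` cells) at the
   previous step. A cell born into the Wnt zone activates Cad at birth;
   without this, the Opa ratchet would fire in newborn cells one step
   before Cad could repress it, short-circuiting the phase sequence.
2. **Timer-gene repression of opa.** Opa is additionally repressed by
   Cad≥1 or D=2, subdividing the zone into a posterior Cad/D compartment
   and an anterior Opa compartment.
3. **Cad-gated D activation.** D activates (to strong) only from Cad, with
   weak D as a decay state of prior expression rather than a default. The
   blastoderm rule's weak default-activation would put newborn cells
   directly into the cad+D phase, destroying the cad-first ordering; in the
   sequentially segmenting context the D domain sits inside the cad domain,
   which this gating expresses. The blastoderm behaviour is recovered with
   `d_requires_cad=False`.

Phases are labelled from the Cad/D/Opa levels (naive, cad, cad+D, D, D+opa,
opa, in developmental order; Opa-bearing states rank last, and a cell
co-expressing Cad and Opa — not produced by the shipped rules — counts as
Opa-bearing). Under the default config (2 initial cells, Wnt range 2, one
cell appended per step, 20 steps) every cell's phase rank is non-decreasing
in time, phase rank is spatially non-increasing from anterior to posterior
at every step, and every cell that left the Wnt zone long enough ago
traverses cad → cad+D → D → D+opa → opa in order.

Disabling all three modifications plus growth and Wnt
(`variant.reduction_config()`) makes every cell reproduce the blastoderm
network's trunk dynamics exactly — the variant is a strict generalisation,
not a separate model. Time and space are dimensionless steps and cells; no
mapping to stages, µm, or any particular species is attempted.

## Synthetic traces

The trace module exists so that boundary quantification is testable end to
end with known ground truth; it emulates the *shape and processing
conventions* of AP intensity traces, not optics or nuclear texture, and
makes no claims about any real imaging dataset. Positions are % egg length
from the anterior pole. A domain is a plateau with logistic edges —
`baseline + amplitude · σ((x−a)/w) · σ((p−x)/w)` — so the half-maximum of
each edge sits exactly at the edge parameter, which is what makes parameter
recovery well-posed. Gaussian noise (SD in intensity units) is added per
sample and the result floored at 0; the generator takes a mandatory seed
with a fixed default.

Processing follows the figure conventions: traces are windowed to
67.5–97.5% AP (inclusive) and then min–max normalised per gene
(window-then-normalise, matching per-panel normalisation of windowed
traces; the two orders agree only when the extrema lie inside the window,
and a test documents the non-commutativity). A constant series normalises
to all-zero and is flagged degenerate rather than dividing by zero.
Boundaries are threshold crossings of the normalised series (default 0.5,
the half-maximum convention; the threshold is a parameter since the
operationalization is not standardised), positioned by linear interpolation
between adjacent samples, each labelled rising or falling. Boundary shifts
between a test and a reference trace are signed (negative = anterior);
multiple crossings in the requested direction require an explicit index.

At the default sampling (301 points over 0–100%, ≈0.33% spacing) and noise
at 5% of amplitude, ≥95 of 100 seeded runs recover both edges of a
tail-like domain within 0.5% egg length; the mean absolute error is
≈0.15–0.2% egg length (the residual comes from noise times the inverse
edge slope, amplitude/4w).

## Problem sizes and numerical choices

The terminal model is 4 regions × 4 timepoints × 7 ordinal variables and
all nine genotypes simulate in milliseconds; the default variant run is 21
final cells × 20 steps; the trace experiment uses 100 seeded runs of 301
samples. Levels are small integers throughout (stored as int8 tensors);
there are no tolerances in the logical model itself. Trace comparisons use
exact float arithmetic except where tests allow for sampling resolution
(±0.1% egg length on noise-free boundary positions).

## Known limitations

* No representation of region size, domain geometry, or continuous
  gradients: fate-map shifts and within-region shifting dynamics are out of
  scope by construction.
* Dorsoventral inputs and the *D* neuroectodermal domain are not modelled.
* The Fkh/Wg onset timing in *hkb⁻* is non-normative (see above).
* The variant's rule modifications are reconstructions; alternative
  wirings that produce the same phase sequence are not excluded.
* Passing the trace-recovery tests says the *quantification* is correct on
  generator-shaped data; real confocal traces have structured noise,
  nuclear periodicity and background gradients the generator does not
  emulate.
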