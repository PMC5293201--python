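# Methods

## Model

The bundled model (`ferronet.iron.build_iron_model`) has 24 ternary
species in a fixed order (LIP, TfR1, Fpn, Ft, IRP1, IRP2, Hep, Mfrn,
LIPmt, Ftmt, ALAS1, heme, HO1, ROS, Keap1, Nrf2, AE, EGFR, SOS, GAPs,
Ras, ERK, cMyc, IL6), grouped into four pathways: iron homeostasis,
iron utilization, oxidative stress response, and oncogenic signaling.
The state space has 3^24 = 282,429,536,481 states. Updates are
synchronous and deterministic.

### Gate algebra

Levels are {0, 1, 2} = low/normal/high. Rules are trees of:

- `Max(a, b, …)` — independent activation (any sufficient input);
- `Min(a, b, …)` — joint requirement;
- `NOT` literal transform — inhibition, level map (2, 1, 0);
- adjusted-regulation transforms for saturating regulators:
  `STAR_IRP1_ACT` = (0, 1, 1) (IRP1's RNA-binding activity activates but
  cannot push beyond normal), `STAR_IRP1_INH` = (2, 1, 1) (its
  inhibitory action likewise bottoms out at normal), and
  `STAR_NRF2` = (1, 1, 2) (Nrf2 only matters when high).

Transforms apply to a single literal before it enters a gate. Custom
transforms can be declared in the text DSL
(`transform: NAME 0->a 1->b 2->c`).

### Continuity

Biological species change concentration gradually. For a species with
raw rule output `f` and current level `x`, the applied update is

    h(x, f) = x + sign(f − x)            (move one level toward f)

unless the species is continuity-exempt, in which case the update is
`f` directly. Exempt species are the metabolite pools: **LIP, LIPmt,
heme, ROS**. Pools are aggregates of fast fluxes, so a one-step jump
(e.g. heme 0 → 2 when ALAS1 is high and HO-1 absent) is the intended
semantics.

Treating the mitochondrial labile iron pool (LIPmt) as a pool alongside
LIP, heme and ROS is a deliberate design choice of this package: all
four are metabolite concentrations rather than gene products, and the
basin structure of the Ras-overexpression landscape (26.4% point /
73.6% cycle) is only obtained with LIPmt exempt. With LIPmt subject to
continuity the model remains bistable but the point basin inflates to
≈36%. See the perturbation panel in `ferronet.perturb.SCENARIO_PRESETS`
for the scenarios this choice was validated against.

### Perturbations

- **Knockout**: the species' rule is replaced by the constant 0 and the
  species is exempted from continuity, so the clamp takes effect in one
  step and holds.
- **Overexpression**: likewise with constant 2.
- **Rule substitution**: a single literal inside one host rule is
  replaced by a constant, leaving the species itself free. Used for
  "low catalase bioactivity": the antioxidant-enzyme literal inside the
  ROS rule is fixed at its level-0 image, so ROS is no longer buffered,
  while AE's own dynamics are untouched.

## GF(3) polynomial encoding

Every rule has an exact polynomial form over the field GF(3), with
exponents reduced by x³ = x so each variable appears with exponent ≤ 2;
the reduced form is unique and is the canonical representation
(`ferronet.gf3.GF3Polynomial`). Polynomials are obtained two ways, which
the test suite proves equivalent on every rule:

1. **Interpolation** of the rule's truth table:
   g(x) = Σ_c f(c) · Π_j (1 − (x_j − c_j)²).
2. **Composition** of gate polynomials:
   NOT(x) = 2 + 2x,
   Max(x, y) = x²y² + x²y + xy² + 2xy + x + y,
   Min(x, y) = 2x²y² + 2x²y + 2xy² + xy,
   with literal transforms interpolated as univariate polynomials.

The continuity operator is itself a function of (current level, raw
output), so `apply_continuity` tabulates h over the rule's inputs plus
the target variable and re-interpolates, giving the applied update
polynomial f_i. Example (ferritin, x4; IRP1 = x5, IRP2 = x6):

    raw:  x5²x6² + 2x5² + 2x6 + 2
    f4:   x4²x5²x6² + 2x4²x5² + 2x4²x6 + 2x4x6² + x4² + x4x6 + x6² + 2x6 + 1

## Attractor analysis

States are encoded as base-3 integers (species 1 = most significant
digit). The engine compiles each rule to a per-species lookup table over
its inputs (continuity folded in), then steps batches of states with
vectorized numpy gathers.

- **Seeded sampling** (`sample_attractors`): draw n initial states
  uniformly with replacement (`numpy.random.default_rng(seed)`), run a
  vectorized Floyd tortoise-hare until every trajectory's cycle is
  found, canonicalize each cycle by rotating to its minimal state code,
  and tally basin counts. Basin fractions carry a binomial standard
  error √(p(1−p)/n); at n = 100,000 this is ≈0.14 percentage points for
  p ≈ 0.26. 100,000 samples of the 24-species model take ~1 s on one
  CPU.
- **Exhaustive enumeration** (`exhaustive_attractors`): iterate a code
  range, following each trajectory with memoization so every state is
  resolved once; results from disjoint ranges merge exactly
  (`merge_attractor_sets`), which is the contract for sharding the full
  3^24 enumeration across machines. The full run is cluster-scale
  (~10^11 states) and is not attempted here; the merge contract is
  verified exhaustively on models up to 3^8 states.

Sampling can miss attractors with basins smaller than ~1/n of the state
space; exact basin fractions for the 24-species model would require the
full enumeration. These are the two known limitations. All reported
numbers are otherwise exact-arithmetic (integer/GF(3)) or carry the
stated sampling error.

## Phenotype scoring

The cancer iron phenotype CP-IHP is the target vector
(Fpn, Ft, Hep, TfR1, IRP2, IRP1, LIP) = (0, 0, 2, 2, 2, 2, 2).
`score_phenotype` compares an attractor against it per species; a
species in a cyclic attractor matches only if it is constant at the
target level over the whole cycle. The triple perturbation
(Ras o/e + low-CAT + Mfrn k/o) reaches a single fixed point matching
6/7 components (5/6 excluding LIP); only IRP1 misses, because its
stability is controlled post-translationally in a way the logic rule
does not capture.
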