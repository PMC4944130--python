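# Model and methods

`bmusim` is a discrete hybrid cellular automaton (HCA) of a single bone
multicellular unit (BMU) — the transient anatomical unit of coupled bone
resorption and formation — invaded by bone-metastatic prostate cancer and
exposed to a TGFβ-neutralizing inhibitor at constant efficacy. Lattice
agents (five stromal cell types, four cancer clones) follow stochastic
rules driven by three continuous fields (TGFβ, RANKL, bone-derived
nutrients) solved on the same grid.

## Domain and discretization

The BMU is a 1000 μm × 1500 μm rectangle at 10 μm per lattice site (one
cell diameter), i.e. a 100 × 150 grid with a mineralized bone slab filling
the lower 30 % and marrow above. Agents occupy at most one site; bone
sites carry no agents. The time step is 1 h, which resolves the fastest
cellular process (the 36 h osteoblast-precursor division time) with wide
margin. Movement and daughter placement use the Moore (8-connected)
neighborhood; bone-surface adjacency uses the von Neumann (4-connected)
neighborhood. Cell and field boundaries are closed (no flux).

## Fields

Each field obeys ∂C/∂t = D∇²C − λC + S, advanced by one explicit
forward-Euler step per simulation step (5-point Laplacian, reflecting
boundaries). Stability (D·dt/dx² ≤ 0.25) is enforced at configuration
load. Defaults (all calibrated, see below):

| field | D (μm²/h) | λ (1/h) | sources |
|---|---|---|---|
| TGFβ (ng/ml) | 20 | 0.05 | ambient turnover (0.10 ng/ml/h, uniform); osteoblast lineage (0.01/cell/h); ligand-producing cancer clones TRP/TP (0.06/cell/h); actively resorbing osteoclasts (10/h at the resorption site); a 10 ng/ml quantum per resorbed bone site |
| RANKL (a.u.) | 20 | 0.10 | MSC/pOB secretion (0.02/cell/h), amplified 1 + 1.5·(local cancer density) by nearby cancer; direct cancer expression (0.04/cell/h) |
| BDN (normalized) | 5 | 0.025 | released from resorbed matrix only (55 per site); consumed by cancer cells |

TGFβ is normalized against its 10 ng/ml saturation level before any rule
reads it: T = clamp(raw/10, 0.01, 1). The measured biological response
window, 0.1–10 ng/ml, spans exactly two decades, so the logarithmic
response laws

    response_direct(T)  = clamp(1 + log10 T, 0, 1)
    response_inverse(T) = clamp(  − log10 T, 0, 1)

map it onto [0, 1]: the direct response is 100 % at saturation and zero at
the 0.1 ng/ml floor, and vice versa for the inverse response. The
inhibitor acts instantaneously and uniformly on bioavailability (no
pharmacokinetics): every rule reads T·(1 − efficacy), efficacy constant in
[0, 0.99] from the arm's start day (day 1 for pre-treatment, day 80 for
post-treatment).

## Stromal rules

* **MSC** (60, static): asymmetric division (MSC → MSC + pOB) every 8
  days on average, throttled by a marrow-niche ceiling of 120 pOBs.
* **pOB**: divides at `(1/36 h) · response_inverse(T)`; homes toward the
  bone surface; differentiates to aOB at 1/48 h when bone-adjacent and
  T < 0.30; dies after 6 days undifferentiated.
* **aOB**: deposits one adjacent bone site per 96 h, preferring concave
  (pit) sites so resorption lacunae refill before new apposition; retires
  after 6 days.
* **pOC**: recruited from marrow at a rate proportional to total RANKL
  (0.010/h per unit), placed by RANKL-weighted sampling; homes to the
  surface, then patrols along it drifting up the RANKL gradient; settles
  beside or mounds onto surface-bound peers; lives 8 days unfused.
* **Fusion**: a cluster of ≥ 5 mutually adjacent pOCs with a bone-adjacent
  anchor fuses into one multinucleated aOC with probability
  `1 − exp(−(1/6 h)·response_inverse(T)·dt)` per 5-precursor chunk per
  step — active resorption (high local TGFβ) therefore limits further
  osteoclastogenesis. A new aOC's resorption clock starts expired, so it
  cuts its first lacuna immediately; without this the fusion condition
  (low TGFβ) and the survival condition (high TGFβ) would deadlock.
* **aOC**: resorbs one adjacent bone site per 24 h, releasing the matrix
  quanta and advancing into the cavity; survives each 1 h step with
  probability `response_direct(T_bioavailable)` read from the live field
  (so the TGFβ it just liberated counts); dies at a 10-day lifespan cap or
  after 48 h without bone contact. Untreated, a resorbing aOC keeps its
  own site at saturation and lives out its cap (~10 lacunae); under any
  appreciable inhibition it survives hours, so each fusion yields ~1
  lacuna — inhibition converts resorption from a per-cell bulk process
  into a fusion-rate-limited trickle.

## Cancer clones

Four heritable, immutable phenotypes defined by TGFβ ligand/receptor use,
with measured division times and starvation lifespans (days):

| clone | baseline | fully inhibited | starvation lifespan | ligand | receptor |
|---|---|---|---|---|---|
| TRP | 1.5 | 2.0 | 14 | yes | yes |
| TR | 1.75 | 2.0 | 10 | no | yes |
| TP | 1.75 | 1.75 | 10 | yes | no |
| TN | 2.0 | 2.0 | 12 | no | no |

Division probability per step is `1 − exp(−rate·dt)` with
`rate = (1/effective_time) · response_direct(clamp(BDN, 0.01, 1))`; zero
without nutrients, maximal at nutrient saturation. The inhibitor's effect
on division time is linearly interpolated in efficacy between the baseline
and fully-inhibited endpoints (the endpoints are the measured quantities;
intermediate efficacies are simulated, making a continuous interpolation
the minimal assumption); receptor-less clones are unaffected by
construction. A cell's starvation clock resets whenever local BDN ≥ 0.02
and kills it past the clone's lifespan. Cancer cells are sessile;
daughters occupy a uniformly chosen empty Moore neighbor (contact
inhibition otherwise), consume BDN at 0.02/h, and ligand producers secrete
TGFβ locally.

Tumors are seeded on day 1 as a connected emboli abutting the bone
surface, placed beside the surface site with the most osteoclast
precursors nearby — disseminated tumor cells home to active remodeling
niches. This placement is what makes ignition of the vicious cycle
reliable for the untreated 9-cell reference emboli: the neighboring
precursor cluster soon fuses, and an untreated osteoclast's ~10-lacuna
feed bridges the lesion to self-sustained (mass-action RANKL-driven)
resorption, whereas under even 20 % inhibition the same fusion yields a
single lacuna and the lesion usually starves through a famine gap.

## Treatment arms and readouts

Arms: untreated control; pre-treatment (constant efficacy from day 1);
post-treatment (from day 80, when the vicious cycle is established). The
vicious cycle is *operationally* defined as established when the cancer
count reaches 10× the seeded count without declining across a trailing
25-day window; the source narrative asserts but does not define the
criterion, so this artifact definition is stated here once and used
everywhere (experiment early-stopping, the emboli-threshold scan).

Readouts per replicate and day: bone area (bone-site count × 100 μm²),
per-phenotype counts, clonal fractions, cumulative event counts (division,
differentiation, fusion, resorption, formation, apoptosis by lineage).
Arm comparisons report percent change of means, SEM, and a two-sided
Welch t-test (the original analyses name only the software used, not the
test; Welch is the conservative default for unequal variances). Tumor
burden is the total cancer-cell count across clones.

## Calibration and what passing tests show

All constants not fixed by measurement (field transport, secretion and
release magnitudes, stromal recruitment kinetics, lattice/niche
parameters) were calibrated in one pass against four qualitative anchors,
then frozen: (i) the tumor-free BMU holds its bone area within ±10 % over
75 days while remodeling at ~5–6 sites/day; (ii) 80 % inhibition of the
tumor-free BMU yields a high-single-digit percent bone gain over 75 days
(osteoclast suppression with maintained formation); (iii) an untreated
9-cell TRP emboli reliably ignites sustained growth; (iv) 20 % inhibition
applied before seeding durably suppresses it. The calibrated defaults are
marked `calibrated` in `bmusim.params.PARAM_INFO`.

Known limitation, stated plainly: with these response laws the osteoclast
survival penalty saturates at low efficacy (bioavailable TGFβ falls below
the response floor already at ~20 % inhibition at typical resorption-site
concentrations). Established lesions therefore lose more of their
nutrient supply under late high-efficacy inhibition than the near-futility
reported for the original model, whose unpublished kinetic table
presumably placed the operating point differently (e.g. resorption-site
TGFβ far above saturation, or survival evaluated on a per-day cadence —
either alternative, tested here, destroys the pre-treatment result, which
is the harder bound). The post-treatment reduction computed here
therefore overshoots the upper edge of the published band, while the
directionality is reproduced: post-treatment is far less effective than
pre-treatment, and 80 % vs 99 % post-treatment differ little from each
other.

## Problem sizes

Replicate defaults follow the original campaigns (24–29 per arm);
acceptance recomputation and the test suite run 6–10 replicates per arm
and scan the emboli ladder coarsely (sizes 9 and 5, 20 replicates each,
150-day horizon with early stopping at establishment/extinction) — the
package's own desk-scale choice; all stochastic checks use interval bands
rather than point equality.

## Numerical/implementation notes

* Rates convert to per-step probabilities as `p = 1 − exp(−rate·dt)`
  (exact for exponential waiting).
* Within each lineage, stochastic decisions are drawn synchronously
  against the start-of-sweep state; resulting events and moves are
  committed in random order (batched with one winner per contested site),
  removing systematic sweep bias.
* Step order: fields → osteoclast lineage → osteoblast lineage → cancer.
* One `numpy` Generator per replicate; identical inputs and seed give
  bitwise-identical outputs.
* Negative field values (possible only through explicit sinks) are
  clipped at zero; the TGFβ normalization floor keeps response-law inputs
  strictly positive.

## Not modeled

Osteocytes, immune cells, vasculature and mechanics; additional cytokines
(PTHrP, BMPs); cancer-cell motility beyond daughter placement; inhibitor
pharmacokinetics; 3-D geometry. Synthetic dynamics emulate a single
trabecular surface — real marrow geometry, systemic endocrine feedback and
inter-patient kinetic variation are outside the generator, so passing
tests certify internal consistency with the stated laws and calibration
anchors, not quantitative prediction for real bone.
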