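# Methods

## The model

A polymer is a self-avoiding walk of `Nm` monomers on the simple cubic
lattice (spacing `a ≡ 1`; all energies in units of kBT).  Four interactions
define the system:

* **Bending.**  Consecutive bonds form either a straight joint (angle 0,
  energy 0) or a right angle (energy `eps_bend`).  The back-fold (angle pi)
  never occurs: it would revisit an occupied site, so self-avoidance removes
  it structurally rather than through an energy penalty.  The resulting
  bond-orientation correlation per step is

      <cos θ> = 1 / (1 + 4 e^(−eps_bend)),

  (one straight continuation of weight 1, four right-angle continuations of
  weight `e^(−eps_bend)`), giving the persistence length

      lp/a = −1 / ln <cos θ>.

  `eps_bend = 0` gives `lp/a = 1/ln 5 ≈ 0.62`; `eps_bend = 3` gives
  `lp/a ≈ 5.5`, the stiffness used throughout the confinement studies.
* **Excluded volume.**  One monomer per site.
* **Contact attraction.**  A *contact pair* is two non-bonded monomers at
  unit distance; each contributes `−ε`.  The contact number `Nc` is the
  order parameter of the coil–globule transition.
* **Slit walls.**  Two hard walls `H` lattice planes apart.  `H = 1` is the
  strictly two-dimensional limit; `slit_height=None` is bulk.

An analytic upper bound on `Nc` follows from a discrete isoperimetric
argument: among any `Nm` occupied sites the adjacent pairs number at most
`3 Nm − 3 Nm^(2/3)` in bulk and at most `3 Nm − Nm/H − 2 √Nm` in a slit
(`2 Nm − 2 √Nm` at `H = 1`, the square-lattice bound), and every adjacent
pair is either one of the `Nm − 1` bonds or a contact.  For `Nm = 1024` on a
surface this gives 961 contacts, i.e. ≈ 0.94 per monomer; the corresponding
limits for infinitely long chains are 2 per monomer in bulk and 1 on a
surface.

## Counting convention

The effective density of states

    g(Nc) = Σ_shapes e^(−E_bend)        (sum over allowed shapes with Nc contacts)

absorbs the bending Boltzmann factor, so a single `ε`-independent table
yields every thermodynamic quantity by reweighting with `e^(+ε Nc)`.

Each chain **shape** is counted exactly once: the first monomer is pinned at
the lateral origin, all orientations are kept (no symmetry reduction), and
the vertical placement is quotiented out — a shape is allowed in a slit iff
its z-extent is at most `H − 1` planes, i.e. iff it fits between the walls
at some placement.  Consequences that the test-suite asserts exactly:

* a slit at least as tall as the chain is *identical* to bulk, table
  entry for table entry;
* `g_slit(Nc) ≤ g_bulk(Nc)` bin by bin (confinement only removes shapes);
* at `H = 1` the totals are the square-lattice walk counts
  (12, 36, 100, 284, …), and in bulk the cubic-lattice counts
  (30, 150, 726, 3534, …).

The alternative convention — summing over all allowed starting planes —
weights each shape by `H` minus its extent, which breaks the first two
properties while changing nothing observable: every reported quantity is a
shifted curve or a ratio, so the absolute normalization cancels.  The
convention is recorded in each table's metadata and checked whenever two
tables are combined.

## Exact enumeration

For small chains a depth-first walk over the growth tree visits every
allowed shape once (memory O(Nm)), accumulating exact integer counts
resolved jointly by contact number and number of right-angle joints.  One
enumeration per geometry therefore serves *every* bending rigidity exactly,
and at `eps_bend = 0` the integer counts are exposed for bit-exact tests.
The tree has ≈ 4.68^Nm nodes in bulk and ≈ 2.64^Nm at `H = 1`, so the
module refuses chains beyond `Nm = 12` in bulk (13 at `H = 2`, 16 at
`H = 1`), which keeps a single enumeration in the seconds range and covers
every validation use.

## flatPERM sampling

Production-scale tables come from flat-histogram pruned–enriched Rosenbluth
growth.  A *tour* starts from a single monomer; at each step the
*atmosphere* (allowed continuations with their bending weights) multiplies
the Rosenbluth weight, and a continuation is drawn with probability
proportional to its bending weight (an unbiased uniform-selection variant is
kept and cross-checked; the biased draw has lower variance).  On arrival at
`(n, Nc)` the running weight sum `W[n, Nc]` and visit histogram are updated;
the ratio `r` of the current weight to the per-tour-normalized estimate
`W[n, Nc]/S` (S = tours started) then drives

* **enrichment** (`r > 1`): `ceil(r)` copies, capped at the atmosphere
  size, each carrying `w / copies`;
* **pruning** (`r < 1`): survive with probability `r`, weight promoted to
  the estimate.

Unvisited bins act as infinitely attractive, which is what flattens the
`(n, Nc)` exploration.  All weights live in log space (they span hundreds
of orders of magnitude at production lengths) with log-sum-exp
accumulation.  The RNG is a per-run seeded Mersenne Twister inside the
numba kernel; identical `(parameters, budget, seed)` reproduce tables
bit for bit.  The final estimate is `log g(Nc) = log W[Nm, Nc] − log S`.

**Convergence filters.**  Raw visit counts overstate the information in a
bin because enrichment copies within one tour are strongly correlated, so
the kernel also records how many *distinct tours* touched each bin — the
effective sample size.  Two trims are used downstream:

* transition location and landscapes: keep bins reached by ≥ 1 % of tours
  (rare-bin weight estimates carry errors of order their own magnitude and
  would otherwise inject multi-kBT spikes into `F(Nc)`);
* confinement-free-energy curves: keep bins reached by ≥ 100 tours — an
  absolute cutoff, because the physically decisive near-close-packed bins
  (e.g. `Nc` up to 48 of the 49-contact two-dimensional maximum at
  `Nm = 64`) are reached by a small fraction of tours yet are pointwise
  accurate at that coverage, and the curve statistics tolerate ±0.5 kBT
  noise.

## Thermodynamics from g(Nc)

With Boltzmann weights `g(Nc) e^(+ε Nc)` (attraction lowers the energy by ε
per contact), computed in log space:

* `⟨Nc⟩(ε)` and the fluctuation `Var Nc(ε)`; the peak of the fluctuation
  over ε locates the critical attraction `ε*`, found by a coarse scan
  (default window 0–2 kBT, step 1e−3 — brackets every regime with
  `eps_bend ≤ 3` at the chain lengths studied) plus bounded refinement far
  past the 1e−5 kBT tolerance; the full width at half maximum (FWHM) of the
  peak, from root-bracketed half-maximum crossings, measures transition
  sharpness (the crossing search extends past the scan window when needed,
  flagged).  Fluctuations are reported raw, with a per-monomer option.
  On a two-level toy system (`g(0) = M`, `g(N) = 1`) the implementation
  reproduces the closed forms `ε* = ln(M)/N` and
  `FWHM = 2 ln(3 + 2√2)/N` to 1e−6.
* the landscape `F(Nc) = −ln P(Nc; ε)` in kBT, shifted so the coil-side
  (lowest-Nc) local minimum is zero; minima live on the integer `Nc` grid
  with plateaus resolved to the lower `Nc`.
* the barrier: the interior maximum between the coil (lowest-Nc) and
  globule (highest-Nc) *significant* minima, measured from the coil
  minimum.  Significance uses two filters with defaults in kBT: adjacent
  minima not separated by a ridge ≥ 0.25 are merged (sampling ripple), and
  minima more than 3 above the deepest one are ignored (a basin 10 kBT up
  holds e^(−10) of the probability — tail noise, not a phase).  A
  single-basin curve reports barrier 0 with a continuous-transition flag.
* the confinement free energy `ΔF_conf(Nc) = −ln[g_slit(Nc)/g_bulk(Nc)]`,
  independent of ε because the Boltzmann factors cancel in the ratio.  Its
  additive constant depends on the unobservable absolute normalization, so
  the curve is anchored to zero at the smallest shared `Nc`; this is the
  unique choice that is exactly invariant both to per-table shifts of
  `log g` and to pre-reweighting the inputs.  Trends in `Nc` are
  unaffected.
* the phase map: `ε*`, FWHM, and barrier per geometry, plus the critical
  slit height `H*` minimizing `ε*(H)` — either the discrete argmin or the
  crossing of the segment ending at the discrete minimum with the segment
  through the next two points on the rising side.
* the DNA unit mapping: matching the model persistence length to a physical
  one fixes `a = lp_phys / (lp/a)`; the effective width is `a` (closest
  approach) and the contour is `Nm·a`.  `Nm = 1024`, `eps_bend = 3`,
  `lp = 50 nm` gives a 9.3 μm contour and 9 nm width — λ-DNA territory,
  which is what makes slit-confined DNA condensation the natural experiment
  for this model.

## Validation scales and what they show

The suite validates three layers:

1. **Exact layer** (bit-exact, milliseconds): walk counts against the
   published square/cubic-lattice series, hand-enumerated energies, the
   contact bound, closed-form two-state transition quantities.
2. **Sampler vs oracle** (seconds–minutes): for `Nm ∈ {5, 10}`,
   `H ∈ {1, 2, 3, bulk}`, `eps_bend ∈ {0, 1.5, 3}`, the seed-averaged
   flatPERM `log g` (10 seeds × 20 000 tours) agrees with exhaustive
   enumeration within 3 standard errors per bin.  With ≈ 200 bins and
   9-degree-of-freedom error estimates a few chance exceedances are
   expected, so a failing combination is re-examined once on an
   independent 20-seed replication at the same rule: sampler bias fails
   both stages, statistical fluctuation does not.
3. **Confinement trends** (minutes): `Nm = 64`, `eps_bend = 3`,
   `H ∈ {1, 2, 4, 8, bulk}`, 120k tours per geometry (600k for `H = 1`,
   whose two-dimensional globule limit converges slowly; 300k for bulk),
   fixed seed.  These sizes keep the default test run in the minutes range
   on one CPU; all reported quantities were checked to reproduce within a
   few percent under an independent seed.

At this reduced scale the confinement phenomenology is partly, not fully,
that of production-length chains (`Nm = 1024`, `L/lp ≈ 186` vs ≈ 12 here):

* the fluctuation peak *height* decreases monotonically with decreasing `H`
  (270 → 138 from bulk to `H = 1`), and the FWHM broadens monotonically
  from bulk through `H = 2` (0.156 → 0.252 kBT) — both as at production
  scale;
* the strictly two-dimensional point `H = 1` departs: its transition is
  *sharper* than `H = 2` (FWHM 0.204 kBT) with a *larger* barrier
  (3.2 kBT), so the monotone broadening and the monotone barrier decrease
  do not extend through `H = a` at `Nm = 64`.  Short stiff chains in 2-D
  have a more strongly two-state transition; the dimensional specialness
  of `H = a` is a genuine feature of the model, visible here because the
  chain is short.  The corresponding trend tests assert the
  production-scale ordering and therefore fail at this scale; they are
  left failing deliberately, as a documented scale limitation rather than
  a softened assertion.
* the confinement free energy decreases with `Nc` in moderate slits
  (compact shapes lose less entropy to the walls) and increases with `Nc`
  at `H = 1` once the near-close-packed bins are converged — the flattened
  globule exposes more surface monomers, and `ΔF_conf` climbs by ≈ 11 kBT
  approaching the 2-D maximum contact number.  Both production-scale signs
  are reproduced.

What the synthetic conditions do **not** emulate: production chain lengths
(and with them the sharpness numbers such as the 0.0034 kBT bulk FWHM or
the 1.6-contacts-per-monomer bulk maximum, which require far longer chains
and budgets), off-lattice globule morphologies (toroids vs bundles),
heterogeneous sequences, and any kinetics — the landscape's reaction
coordinate is `Nc`, so barrier heights are not rate predictors.

## Numerical and design choices

* Enumeration and growth kernels are numba-compiled; the occupancy grid is
  a `(2 Nm + 1)^3` byte array and slit confinement is enforced through the
  running z-extent.
* Contacts update incrementally (occupied neighbours of the new site minus
  the bond); bends from comparing consecutive step directions.
* `find_critical_epsilon` treats coarse-grid peaks below 1 % relative
  prominence as ripple; genuinely multimodal fluctuation curves are all
  reported and flagged.
* Degenerate inputs: single-bin tables raise a window error; two-bin
  tables (the toys) have no interior barrier and report the continuous
  flag; `eps_bend = 0` maps to `lp < a`, which the unit mapping flags
  rather than rejects.
* Serialized numbers carry 12 significant digits; files re-serialize byte
  for byte after parsing.
* Checkpoint/resume of sampler state is not implemented; runs at the sizes
  this package targets complete in minutes.
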