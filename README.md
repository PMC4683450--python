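# slitperm

Coil–globule transition of a single semiflexible polymer confined in a slit,
on the cubic lattice: a **flatPERM** (flat-histogram pruned–enriched
Rosenbluth) chain-growth sampler for the effective density of states, an
**exact enumeration** oracle for small chains, and a **density-of-states
thermodynamics** layer that locates the critical attraction, quantifies
transition sharpness, and computes free-energy landscapes, barriers, and
confinement free energies.  The intended users are polymer/DNA-condensation
modellers who want slit-confinement phase behaviour without rerunning
production Monte Carlo for every attraction strength.

## The model and the central quantity

A chain of `Nm` monomers on the cubic lattice (spacing `a`, energies in
kBT) with bending energy `eps_bend` per right-angle joint, hard excluded
volume, a contact attraction `−ε` per non-bonded nearest-neighbour pair
(`Nc` = number of contact pairs), and two hard walls `H` planes apart
(`H = 1` is strictly 2-D, `H = None` is bulk).  The bending rigidity sets
the persistence length via `lp/a = −1/ln<cos θ>` with
`<cos θ> = 1/(1 + 4 e^(−eps_bend))`.

Everything thermodynamic flows from the **effective density of states**

    g(Nc) = Σ_{shapes with Nc contacts} e^(−E_bend),

which is independent of ε.  With Boltzmann weights `g(Nc) e^(+ε Nc)` one
table gives, at any attraction strength: `⟨Nc⟩`, the fluctuation
`Var Nc` (whose peak over ε is the critical attraction `ε*` and whose FWHM
is the transition sharpness), the landscape `F(Nc) = −ln P(Nc; ε)` with its
coil/globule basins and barrier, and — comparing slit to bulk — the
ε-independent confinement free energy
`ΔF_conf(Nc) = −ln[g_slit(Nc)/g_bulk(Nc)]`.

`g` is exact (integer-resolved) from enumeration up to `Nm = 12`, and
estimated without bias by flatPERM beyond that; the test suite checks the
sampler against the enumeration oracle across geometries and rigidities.

## Worked example

Exact table for a short stiff chain in a two-plane slit, then a sampled
`Nm = 48` chain analysed against its bulk reference:

```
$ slitperm enumerate --nm 10 --eps-bend 3 --slit-height 2 --out dos_nm10_H2.tsv
wrote dos_nm10_H2.tsv (7 contact bins)

$ head -9 dos_nm10_H2.tsv
# schema=slitperm-dos/1
# n_monomers=10
# eps_bend=3
# slit_height=2
# provenance=enumeration
# shift=raw
# convention=shape-once
Nc	log_g
0	2.36308514394

$ slitperm sample --nm 48 --eps-bend 3 --slit-height 2    --tours 30000 --seed 7 --min-tours 300 --out dos_nm48_H2.tsv
wrote dos_nm48_H2.tsv (44 contact bins, seed 7)
$ slitperm sample --nm 48 --eps-bend 3 --slit-height bulk --tours 30000 --seed 7 --min-tours 300 --out dos_nm48_bulk.tsv
wrote dos_nm48_bulk.tsv (42 contact bins, seed 7)

$ slitperm analyze dos_nm48_H2.tsv --bulk dos_nm48_bulk.tsv --out-dir analysis
dos_nm48_H2: eps*=0.4621 kBT, FWHM=0.4294 kBT, barrier=2.019 kBT
```

Reading the numbers: for the stiff chain (`lp ≈ 5.5 a`) squeezed into two
lattice planes, the coil–globule transition sits at an attraction of
0.46 kBT per contact; the fluctuation peak is 0.43 kBT wide (a soft, finite-
size-rounded transition at this short length); and at `ε*` the landscape
has coil and globule basins (minima at `Nc = 0` and `Nc = 43` in
`analysis/dos_nm48_H2_summary.json`) separated by a 2.0 kBT barrier, i.e. a
discontinuous, two-state transition.  `analysis/` also holds the
fluctuation curve, the landscape, and the slit-minus-bulk confinement
free-energy curve as TSV, each stamped with the checksum of its input
table.

The same objects are available as a library:

```python
from slitperm import ModelParams, run, enumerate_dos, transition_summary

table, state = run(ModelParams(48, 3.0, 2), budget=30_000, seed=7)
print(transition_summary(state.to_table(min_tours=300)).eps_star)
```

Other CLI verbs: `phase-map` aggregates `ε*`/FWHM/barrier across a set of
tables and reports the critical slit height minimizing `ε*(H)`;
`fixtures` writes the deterministic exact-table/toy-table set used by the
test suite.

## Layout

| module | contents |
| --- | --- |
| `slitperm.model` | lattice chain, energies, contact counting, persistence length, contact bound |
| `slitperm.dos` | the `DoSTable` artifact + TSV dialect, analytic two-state toys |
| `slitperm.enumeration` | exhaustive oracle, exact integer counts, size guard |
| `slitperm.flatperm` | flatPERM engine (numba kernel), convergence diagnostics |
| `slitperm.thermo` | reweighting, `ε*`/FWHM, landscapes, barriers, confinement free energy, phase map, unit mapping |
| `slitperm.cli` | `slitperm enumerate / sample / analyze / phase-map / fixtures` |

`docs/methods.md` documents the model, the counting convention, the
sampler's update rules and convergence filters, the numerical choices, and
what the reduced-scale validation does and does not show.
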