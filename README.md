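# connectomatrix

A toolkit for representing macroscale **human structural brain connectivity**
as an explicit, evidence-backed matrix over gyral parcellation units, in the
spirit of the original Harvard-Oxford Atlas cortical parcellation framework.
It is aimed at neuroanatomists and neuroimaging researchers who curate
connectional knowledge from the literature — classical postmortem sources and
diffusion-tractography studies alike — and want that knowledge queryable,
validated, and exportable to standard graph tooling.

## The model

The cerebrum is partitioned into parcellation units (PUs): 48 gyral cortical
regions (AG, F1, F2, …), 7 thalamic units (A, M, La, Lp, P, LGN, MGN) and
aggregate subcortical targets (striatum, pons, hippocampus, amygdala).
Connectional knowledge is the matrix **C** whose element C<sub>i,j</sub> is a
1×4 logical column vector over four **distance types**:

| type | name | rule |
| --- | --- | --- |
| 1 | short-range (intragyral/juxtagyral) | the units are adjacent gyri — within one lobe (*intralobar*) or across a lobe border (*juxtalobar*, the U-fiber case) |
| 2 | medium-range (intralobar) | non-adjacent units of the same lobe |
| 3 | long-range (interlobar) | non-adjacent units of different lobes, mediated by named association fascicles (SLF, ILF, cingulum, …) |
| 4 | projection | any cortical–subcortical pair |

Classification is purely relational — a function of the declared gyral
adjacency graph and lobe map (the insula counts as its own lobe) — and
exclusive: type 1/2 connections for a pair cannot coexist with type 3, so
every pair admits exactly one distance type. For example

```
C_F2,AG = [0 0 3 0]ᵀ
```

middle frontal gyrus ↔ angular gyrus: long-range only, via the superior
longitudinal fascicle (SLF). Homotopic callosal (commissural) connections are
generated by rule — every cortical unit links to its contralateral mirror
region — and heterotopic callosal connections are excluded.

Each curated entry is an assertion *"Region A is connected to Region B by
Pathway C"* backed by publication evidence (page/table/figure/tracer/species),
and each matrix is era-tagged: `pre_dti` for classical postmortem knowledge,
`dti` for the conservative tractography-era matrix validated against
nonhuman-primate tracing (which carries only type-3 and commissural entries).

## Worked example

```bash
$ connectomatrix classify F2 AG
F2 -- AG: type 3 (long_range, interlobar)

$ connectomatrix fixtures build --era pre_dti --out pre.json
wrote pre.json (50 entries)
$ connectomatrix fixtures build --era dti --out dti.json
wrote dti.json (9 entries)

$ connectomatrix diff --region AG --a pre.json --b dti.json
type 1: only in A: OLs SGp | only in B: -
type 2: only in A: PCN POG | only in B: -
type 3: only in A: CO F3o PHa SMC | only in B: -
type 4: only in A: Lp P PON STR | only in B: -
```

The type-3 line is the era comparison for the angular gyrus: the classical
matrix connects AG with F3o, CO, SMC and PHa, none of which survive into the
conservative tractography-era matrix. A lesion analysis over multiple PUs
reports the cumulative set of remote regions disconnected through each fiber
type (type 4 optionally restricted to thalamic partners):

```bash
$ connectomatrix lesion --units F2,AG --matrix pre.json --thalamic-only --style csv
type,partner,via
1,F1,F2
...
3,CGp,AG;F2
3,CO,AG;F2
...
4,A,F2
4,La,F2
4,Lp,AG
4,P,AG
```

The same operations are available as library functions
(`classify_pair`, `connectivity_map`, `era_diff`, `lesion_disconnection`,
`build_pre_dti_fixture`, `random_matrix`, …); matrices export to canonical
JSON, long CSV and GraphML.

## Layout

- `src/connectomatrix/registry.py` — parcellation units, lobe map, adjacency
- `src/connectomatrix/typology.py` — distance-type classifier and validator
- `src/connectomatrix/matrix.py` — the era-tagged connection matrix C
- `src/connectomatrix/evidence.py` — curation layer (CSV + sidecar, sqlite)
- `src/connectomatrix/analysis.py` — maps, era diffs, lesion disconnection
- `src/connectomatrix/fixtures.py` — packaged matrices and random generator
- `docs/methods.md` — modelling assumptions and design notes
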