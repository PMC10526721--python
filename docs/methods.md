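# Methods

## The connectional model

The package encodes macroscale structural connectivity of the human cerebrum
as a symmetric matrix over gyral parcellation units (PUs). An element is a
1×4 logical vector whose slots record presence/absence of the four distance
types, ordered 1→4 top to bottom. Two storage conventions exist in the
literature for the occupied slot — a bare presence bit and the type number
printed in place — so vectors store booleans and both renderings are offered
at output (`render("binary")` → `0010`, `render("typed")` → `0030`).

The distance typology is a total function of two declared relations:

* **adjacency** — an irreflexive, symmetric graph over cortical PU codes;
* **lobe membership** — a partition of cortical PUs into frontal, parietal,
  temporal, occipital, insula (a lobe in its own right) and limbic.

Adjacent pairs are type 1 (intralobar or juxtalobar by lobe agreement);
non-adjacent same-lobe pairs type 2; non-adjacent cross-lobe pairs type 3;
any cortical–subcortical pair type 4. No millimetre threshold enters the
rule — classification is relational, so it is exactly reproducible from the
registry config alone. Because the rule is a function, the "allowed slots"
of a pair form a singleton, which is what makes the coexistence constraint
(types 1/2 exclude type 3 for a pair) checkable mechanically: an asserted
type is valid iff it equals the classified type.

The matrix is **undirected**. Classical sources delineate pathway stems, not
origins and terminations, so directionality cannot be supported by the
evidence; where a source states origin/termination information it belongs in
the evidence record's notes, not in the matrix structure.

**Commissural connections** are modelled by rule, not curation: every
cortical PU is linked to its homotopic contralateral region, and heterotopic
callosal links are never created. Commissural entries live in their own
class beside the four slots — they are not a fifth distance type, and the
ipsilateral matrix stays hemisphere-agnostic (48×48, not 96×96); hemisphere
tags (`F2_L`/`F2_R`) appear only in commissural output rows.

**Eras.** A matrix carries exactly one era tag. The classical (`pre_dti`)
matrix collates postmortem human observations; the tractography-era (`dti`)
matrix is deliberately conservative — association type-3 entries validated
against nonhuman-primate tracing, plus rule-generated commissural links, and
no type-1/2/4 entries, because those are unvalidated in that era's sources.

## The packaged registry

* **48 cortical units.** The source framework declares 49 cortical regions
  but prints 48 unit codes; the registry packages exactly the printed units
  and records both counts in metadata rather than inventing a 49th.
* **7 thalamic units** (A, M, La, Lp, P, LGN, MGN), exactly.
* **Aggregate subcortical targets.** STR (striatum), PON, HIP, AMY give the
  projection systems (internal capsule, corticopontine, corticostriatal,
  amygdalofugal) endpoints without enumerating striatal sub-units, which the
  printed framework does not do.
* **Lobe map and adjacency are editable defaults**, not printed facts. They
  were assigned once from standard gyral anatomy and are fully overridable
  in the registry config; every classification is explicitly relative to the
  loaded config, and the matrix records a registry checksum so results are
  never silently reinterpreted against a different frame. Two assignments
  deserve note: cingulate/paracingulate/subcallosal/parahippocampal units
  default to a "limbic" lobe (a modelling convention, not an anatomical
  claim), and the central opercular cortex (CO) is grouped with the
  insular/opercular lobe — CO participates in printed long-range
  (interlobar) connections with both frontal (F2) and parietal (AG) units,
  so it can belong to neither of those lobes under the typology.

## Fixtures and provenance discipline

Fixture curation rows carry a provenance note. Rows restating printed facts
are tagged `in-paper: …` (the worked example C(F2,AG); the AG and F2
era-difference partner lists); rows that merely flesh out the exemplar maps
and populate the ten named pathway systems are tagged
`figure-level, unverified`, since the full region maps exist only pictorially
in the source. Tests assert that every `in-paper` fact is present in the
built matrix, and only those facts are treated as ground truth; the complete
published matrix (supplementary tables) can be merged at build time as
optional CSV input through the same validator/quarantine path.

## The random generator

`random_matrix(GeneratorConfig(seed, per_type_density))` fills, for every
pair, the pair's single allowed slot with probability given by that type's
density, so output is typology-valid by construction for any seed and
reproducible from the seed (`numpy.random.default_rng`). Default densities —
type 1: 0.9, type 2: 0.5, type 3: 0.15, type 4: 0.3 — reflect that adjacent
gyri are nearly always interconnected by U-fibers, that intralobar
connectivity is common, and that any given long-range fascicle touches a
minority of cross-lobe pairs. The generator emulates the *structure* of a
curated matrix (slot legality, symmetry, era tag), not its content: it draws
slots independently, with no spatial autocorrelation, no hub structure and
no evidence records, so tests that pass on generated matrices demonstrate
the rule system and serialization machinery, not anatomical fidelity.

## Numerical and procedural choices

* **Determinism.** All orderings are sorted (pair keys, query groupings,
  rendered tables), evidence identifiers are assigned in row order
  (`E0001…`), and ingest of the same file always yields the same object
  graph, byte for byte through serialization.
* **Validation is data, not control flow**, at the curation boundary:
  ingest quarantines offending rows with per-row diagnostics and returns the
  valid remainder. Programmatic APIs (`set_connection`) raise instead, so a
  matrix object can never hold an invalid element.
* **Degenerate inputs.** Self-pairs are undefined (error), the empty lesion
  yields an empty report (not an error), an empty curation file yields empty
  tables and a clean report.
* **Lesion semantics are first-order by default** (direct partners of the
  lesioned units, cumulative union over a multi-unit lesion, lesioned units
  excluded from their own affected sets); multi-hop propagation exists only
  behind an explicit `depth` parameter, and commissural disconnection is
  reported as a separate class.
* **Problem sizes.** The default test/validation sweeps use the packaged
  48-unit registry: exhaustive checks over all 1 128 cortical pairs, 100
  random multi-unit lesions against a brute-force union oracle, and 200
  generator seeds through the full validator; the whole suite runs in a few
  seconds.

## Known limitations

* No quantitative weights (fiber counts, FA, cross-sectional area) and no
  laminar origin/termination coding — the matrix is qualitative presence
  data with evidence pointers.
* No voxelwise/volumetric atlas: mapping an imaging lesion mask onto PU
  codes is out of scope; lesions enter as sets of codes.
* Heterotopic callosal connectivity is deliberately unmodelled.
* The typology is only as good as the declared adjacency and lobe maps;
  alternative parcellations or adjacency conventions change type
  assignments, which is why both are explicit, checksummed inputs.
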