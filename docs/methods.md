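# Methods

## The modelling problem

`pepdock` predicts how a short peptide (3–15 residues) binds a protein
receptor when some contact information — often a single receptor/peptide
residue pair known to touch — is available from experiment or prediction.
The protocol is: (i) coarse-grained replica-exchange Monte Carlo docking of
a fully flexible peptide around a near-rigid receptor, with an optional
soft distance restraint pulling the named side chains together; (ii)
filtering of the sampled pool, first by the contact criterion and then by
receptor–peptide interaction energy; (iii) k-medoids clustering and density
scoring, whose cluster representatives are the final models; (iv)
RMSD-based quality assessment against a reference complex when one exists.

## Coarse-grained representation

Each residue is reduced to four pseudo-atoms: CA; CB; SC, the unweighted
center of mass of the side-chain heavy atoms (CB included; SC := CA for
glycine, SC := CB for alanine); and CP, the peptide-bond center (midpoint
of carbonyl C and the next amide N, falling back to the CA midpoint when
either atom is missing). Coordinates are continuous (no lattice). When
converting all-atom PDB input, the highest-occupancy altloc conformer is
kept (ties go to file order), hydrogens are ignored, HETATM records are
skipped except selenomethionine (read as methionine), and a missing CA is a
hard error.

Peptides built from sequence are self-avoiding CA random walks with 3.8 Å
virtual bonds and pseudo-bond angles in [75°, 150°]; CB and SC are placed
along the local backbone-bisector direction at a fixed per-residue-type
distance (0 for Gly, 1.53 Å for Ala, up to 4.1 Å for Arg). Conformers whose
own CA or SC pairs fall inside the clash radii are rejected and regrown, so
a freshly built peptide always has zero excluded-volume energy.

## Energy model

All energies are dimensionless simulation units with k_B = 1; the Monte
Carlo temperatures are in the same units. The total is a sum of four
independent components:

**Contact restraint.** For restrained side chains at SC–SC distance *d*:
E(d) = 0 for d ≤ D0 and s·(d − D0) beyond, with defaults D0 = 5.0 Å and
s = 1.0 per Å. The flat bottom means a satisfied restraint exerts no force
at all, so the peptide stays fully flexible inside the binding site; the
gentle linear (not harmonic) tail tolerates approximate or partly wrong
contact information. An *ambiguous* restraint names only a receptor residue
and is evaluated at the minimum distance over all peptide residues, with
D0 = peptide length + 12 Å — wide enough that any pose draping the peptide
over that residue satisfies it.

**Receptor–peptide interaction.** A residue-type-dependent square well on
SC–SC distances: pairs inside [4.0, 6.5] Å contribute e(a,b) from a 20×20
symmetric table. The shipped default table is a hydrophobicity-derived
scale, e(a,b) = −(0.2 + h_a·h_b) with h the min–max-normalised
Kyte–Doolittle hydropathy, giving well depths between −0.2 and −1.2 so that
hydrophobic burial is rewarded most. The table is a plain-text matrix and
can be swapped wholesale; every paper-level behaviour of the protocol
(restraint effect, filtering, clustering) is agnostic to the specific
scale. Receptor–receptor interactions are omitted: the receptor only
jitters near its input coordinates, so its internal energy would be a
near-constant offset.

**Intra-peptide terms.** Harmonic CA–CA bond energy (target 3.8 Å,
k = 5 /Å²) and a flat-bottom quadratic penalty outside the [75°, 150°]
pseudo-angle window (k = 10 /rad²). If a secondary-structure string is
supplied, flat-bottom windows on pseudo-angles (H: 80–105°, E: 110–145°)
and pseudo-dihedrals (H: 35–70°, E: 150–210°) are added with weight 0.5 —
a bias, deliberately weaker than the bonded terms.

**Excluded volume.** Soft-core repulsion k·(r_clash − d)² for CA–CA pairs
under 3.5 Å and SC–SC pairs under 3.0 Å (k = 10 /Å²), over all inter-chain
pairs and intra-chain pairs more than one residue apart.

None of these constants is prescribed by the protocol being reproduced;
they are package defaults chosen to give physically sensible toy systems
and 30–60 % move acceptance on them, and all live in one `ForceFieldParams`
block overridable from a YAML file.

## Sampling

Ten replicas (default) run at a geometric temperature ladder from 1.0 to
3.0. One sweep is: N_pep local peptide moves (a single-residue displacement
of up to 0.7 Å or a two-residue crankshaft rotation of up to 45°, chosen at
random), one rigid-body peptide move (translation ≤ 2 Å or rotation ≤ 30°),
and ⌈N_rec/10⌉ receptor CA jitter moves (≤ 0.3 Å) tethered to the input
coordinates by a harmonic positional restraint (k = 1 /Å²) — small
receptor fluctuations, no large-scale rearrangements. Side pseudo-atoms are
re-derived from the CA trace after every peptide move, so SC positions are
a deterministic function of the backbone. Acceptance is standard
Metropolis on the total energy (restraint term included throughout — it is
never ramped or switched off); neighbouring replicas attempt swaps every 10
sweeps with min(1, exp((1/T_i − 1/T_j)(E_i − E_j))).

Each replica independently builds a random peptide conformation and places
it, clash-free and uniformly oriented, on a sphere 10 Å outside the
receptor's bounding radius. Snapshots are collected from **all** replicas
at fixed sweep intervals until the requested pool size (default 10 000) is
reached; each snapshot stores the full energy breakdown and the current
SC–SC distance of every restraint. Runs are bit-reproducible for a fixed
seed.

## Filtering, clustering, scoring

The contact filter drops models whose recorded restraint distance exceeds
D0 — exactly the zero-energy region of the restraint term. With several
restraints the default requires all of them ("any" is a config option).
The contact filter runs **before** the energy filter, so the low-energy
pool is drawn from poses already at the site. The energy filter keeps the
1000 models (default) with the lowest interaction energy, ties broken by
model index. If the contact filter empties the pool, the pipeline keeps
the least-violating models instead and warns loudly rather than failing —
hard targets may never strictly satisfy a contact.

Clustering is k-medoids (k = 10) on the pairwise peptide-RMSD matrix,
computed after superposing every model's receptor CAs onto the first
model's receptor. Small instances are solved exactly by enumerating medoid
subsets; larger ones use deterministic central/farthest-point seeding
followed by PAM-style swaps, so results are reproducible without
randomness. Clusters are scored by density = size / mean intra-cluster
pairwise RMSD (density = size for singletons or zero-spread clusters), and
the medoids ordered by density are the final models. Density scoring is
this package's documented stand-in for the original protocol's unspecified
cluster ranking.

## Quality assessment

*peptide-RMSD*: RMSD over peptide CA atoms after least-squares (Kabsch)
superposition of the model receptor onto the reference receptor — the
peptide is not refitted. Categories: high < 3 Å, medium 3–5.5 Å
(boundaries inclusive), low > 5.5 Å. *i-RMSD* follows the CAPRI
convention: interface residues are reference receptor residues with any
pseudo-atom within 10 Å of any reference peptide pseudo-atom, plus the
peptide; the RMSD is over their CA atoms after superposition on those same
atoms. Categories: sub-Ångström ≤ 1 Å, near-native 1–2 Å, not acceptable
> 2 Å. Peptide residues are paired by sequence position, receptor residues
by (chain, author number); all matched receptor CAs are used for the
superposition.

## Toy systems and what they do (not) show

The fixture generator builds a sheet-like receptor: straight antiparallel
CA strands 4.8 Å apart joined by single-residue turns, with the two strands
flanking the central one raised by 3 Å to form a shallow groove. The
central strand's side chains point into the groove; a peptide laid along it
has a chosen number of side chains reaching down to exactly 4.2 Å from
their target SC (a native contact) while the rest point away (> 5 Å from
everything). The generator verifies the planted contact set, bond-length
range and clash-freedom after construction and refuses to return anything
that deviates. An "unbound" receptor is produced by jittering all
pseudo-atoms to an exact CA RMSD (default 1.0 Å). A synthetic-trajectory
generator mixes near-native poses (per-residue Gaussian noise, σ = 0.5 Å)
with far random decoys and draws synthetic interaction energies whose
near-native population sits 3 units lower on average, emulating what a
docking force field's energy funnel does for the filtering stages.

These caricatures have controlled geometry but no real secondary-structure
packing, no sequence diversity, no partial or conflicting experimental
restraints, and an energy model far smoother than a knowledge-based
potential. Passing tests therefore demonstrate the *mechanics* of the
protocol — restraint algebra, filter semantics, clustering optimality,
metric correctness, sampler validity, and the qualitative direction of the
restraint's benefit — not predictive accuracy on real protein–peptide
complexes.

## Problem sizes

The package's own studies are desk-scale: the docking comparisons use
60-residue receptors, 6-residue peptides, 2 replicas and 200-model runs
(100 burn-in sweeps, snapshots every 2 sweeps) over 12–20 independent
cases, and the pipeline demonstration uses the full default pool of 10 000
synthetic models. At these sizes a docking run samples the approach to the
binding site and the restraint's steering effect clearly (restrained runs
roughly halve the best-of-run peptide-RMSD, Mann–Whitney p ≈ 10⁻³), but
rarely settles into sub-3-Å poses — converged docking needs the default
10 000-model runs.

## Known limitations

- The statistical contact potential of the original CABS engine is not
  reproduced; the shipped hydrophobicity table is a documented,
  swappable substitute.
- No all-atom reconstruction of final models; the coarse-grained models
  are the terminal artifact.
- No large-scale receptor rearrangements, no solvent, no electrostatics.
- Interaction-energy evaluation is a Python double loop over in-well
  pairs; adequate at toy scale, the bottleneck for production-size runs.
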