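# Methods

## Ring geometry

Ring centres and face normals are purely constructive. For Phe/Tyr the
centre is the unweighted mean of the six ring atoms CG, CD1, CD2, CE1,
CE2, CZ; for Trp it is the midpoint of CD2 and CE2, treating the fused
bicyclic system as a single ring. The face normal is the normalized cross
product of the centre→CG and centre→CD1 vectors (Phe/Tyr) or centre→CD1
and centre→CD2 (Trp). Planarity is never enforced, and the normal's sign
is an artefact of atom order: every consumer folds angles so that flipping
any normal changes nothing (tested property).

Histidine is excluded — the definitions cover only Phe/Tyr/Trp; an
extension would need its own centre/normal convention and is deliberately
not smuggled in. Residues missing a defining atom, and degenerate rings
whose cross product magnitude falls below 1e-6 Å² (collinear atoms), are
skipped with a logged warning rather than failing the run: truncated side
chains are routine in deposited coordinates. Unit-norm is asserted to
1e-9. These tolerances are implementation choices with no physical
content; results are insensitive to them for any real ring.

## Stacking detection

A pair stacks face to face when the centroid distance is **strictly**
below 6.0 Å and the folded normal angle min(θ, 180°−θ) is **at most**
20.0°. The strict/inclusive split mirrors the wording of the rule the
thresholds come from ("less than 6 Å"; "0 ± 20° or 180 ± 20°"); boundary
behaviour is pinned by tests and recovered by bisection to 0.01 in the
acceptance script. `find_pairs` evaluates every unordered pair with
vectorized numpy — no spatial index — so equality with a brute-force
oracle holds by construction and is still verified on random
configurations.

A *stack* is a connected component of the pair graph (networkx). Nothing
finer-grained (e.g. requiring a path of mutually parallel rings, or
geometric linearity) is imposed: components are the minimal reading of
"an interaction involving n rings". A stack is inter-chain iff its rings
span ≥ 2 chain IDs; on a connected component this is equivalent to "some
pair crosses chains". Reports keep stacks of ≥ `min_rings_report` rings;
the two presets are 6 (curation of survey hits) and 4 (the inter-chain
analysis). Manual curation of hits is out of scope — the survey reports
candidates.

## Structure IO

gemmi parses PDB v3.3 and mmCIF; writing is PDB only (coordinates to
1e-3 Å, the format's precision). Multi-model files expose model 1 only.
Altloc groups collapse to the highest-occupancy conformer, ties broken by
lexicographically first altloc — deterministic and standard. Chain
identity is the author chain ID (auth_asym_id for mmCIF), matching what a
deposited-coordinate survey sees. No symmetry or assembly expansion is
performed: deposited coordinates only. Hydrogens are read and kept but
every downstream step selects heavy atoms by name. Non-standard residues
are ignored by ring extraction unless named PHE/TYR/TRP.

## Helical geometry

Conventions: fibril axis = z through the origin; layer k = rotation by
k·twist about +z (right-hand rule) followed by translation k·rise along
+z; **negative twist ⇒ left-handed**. The convention is self-consistent:
mirroring a built helix through the xz-plane flips the measured twist
sign (tested). Aligning an arbitrary subunit to this frame is the
caller's job; `fit_axis` offers a least-squares (principal-component)
helper as plumbing. C2 symmetry adds a 180°-rotated copy of every layer.
Chain IDs are remapped per subunit copy from a 62-character pool; the
copy layout is recorded in `model.meta["copies"]`. The rival pseudo-2₁
screw hypothesis (rise/2, twist/2 + 180°, C1) is available via
`two_start_screw_equivalent`, and builds under the two hypotheses place
subunits at measurably different coordinates.

Closed forms: crossover = rise·180°/|twist| (half the pitch), undefined
at twist 0; mass-per-length = subunits-per-layer · subunit-mass /
(rise/10) in kDa/nm. For the two-protofilament β₂-microglobulin fibril
geometry (11.731 kDa monomer, 2 per layer, rise 4.83 Å) the formula gives
≈ 48.6 kDa/nm, whereas ~53.3 kDa/nm has been quoted for these fibrils
from scanning-TEM calibration; the basis of that figure is not derivable
from the monomer mass and geometry alone, so the package reports the
formula value and does not force agreement.

## NMR contacts

Classes partition |i−j|: 0 intra, 1 sequential, 2–4 medium, ≥ 5 long.
The boundary case |i−j| = 5 is not covered by the usual "2–4" / "> 5"
phrasing; it is assigned to long-range so the classes partition all
separations (flagged prominently here because other conventions exist).
Tallies count records as given — duplicate residue pairs stand for
distinct atom-pair cross-peaks.

Model checking takes a fibril with ≥ 3 stacked layers. For each contact
the evaluated distance is the minimum over (a) the residue pair within a
middle reference subunit and (b) the same pair measured against every
subunit copy in the axially adjacent layers — cross-peaks in a parallel
in-register fibril cannot distinguish these arrangements, so the check
must not either. Distances are minimum heavy-atom–heavy-atom unless both
atom names are given (then that atom pair; missing named atoms make the
contact unmappable, as do residues absent from the ordered core). The
default satisfaction cutoff is 8 Å, a typical upper bound for ¹³C–¹³C
recoupling transfers; it is configurable and never applied silently.
Satisfaction counts are monotone in the cutoff, and a table synthesized
from a model's own distances at cutoff c is 100% satisfied at any cutoff
≥ c (both tested).

Built fibrils carry copy metadata; for fibrils re-read from disk the copy
layout is inferred by rounding each chain's mean z against the rise. The
inference assumes one chain per subunit copy, which holds for everything
this package writes.

## Synthetic fixtures

`make_ring_residue` places the six ring atoms as a regular hexagon of
C–C bond length 1.39 Å (circumradius = bond length) perpendicular to a
given normal, with vertex order following the ring bond path so the
constructed normal is recovered exactly by the production extractor —
fixtures are written as standard PHE/TYR and travel through the real
reader, never a bypass.

`make_fibril_fixture` emulates the aromatic geometry of a cross-β
fibril: ladders at a configurable rise (default 4.8 Å, the cross-β
repeat), optional per-layer twist, an optional C2-related second chain at
a configurable interface gap (default 7.6 Å — just outside the 6 Å rule,
as at the tyrosine-ladder protofilament interface that motivated the
detector), a global ring tilt, and seeded Gaussian coordinate jitter.
Ground truths (expected pair set and component sizes) are computed
analytically from the recipe *before* jitter with inline arithmetic and a
local union-find — not by calling the detector. At zero jitter detection
must match the ground truth exactly; under jitter, disagreements can only
arise for pairs within ~3σ of a threshold boundary.

What the fixtures do **not** emulate: full side chains and backbones,
ring deformation, thermal disorder correlated along the fibril, density
noise, or real packing environments. Passing tests therefore demonstrate
the correctness of the geometry and bookkeeping, not detector performance
on experimental coordinates.

## Survey

The batch survey scans a directory of PDB/mmCIF files, skipping
unreadable entries with a logged warning and reporting files scanned /
failed / stacks found. Output is sorted (structure_id, size descending,
residue labels) and hence independent of processing order; two scans of
the same directory are byte-identical. An optional per-entry wall-clock
cap (SIGALRM, POSIX-only, off by default) lets a desk-scale scan skip
ribosome-scale entries. Census counts from any historical whole-archive
scan are snapshot-dependent and explicitly not reproduced here.

## Problem sizes

Tests and the acceptance script run on synthetic structures of 2–60
rings, 100 random 50-ring configurations for oracle equivalence, and
contact tables of ~1200 records — sizes at which every oracle is exact
and the full suite completes in seconds.
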