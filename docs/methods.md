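# Methods

## The observables and the classification model

The analysis targets the DNA entry pore of an XPD-type 5′→3′ helicase,
formed by the FeS, Arch and ATPase-lobe-1 domains. All coordinates are in
Å and times in ns throughout the package; interfaces that quote μs values
convert at the boundary.

**Pore geometry.** Three raw internal distances are monitored per frame:
the pore width Cα(H135)–Cα(L220), the Arch/lobe-1 gap Cα(R380)–Cα(L220),
and the minimum heavy-atom distance between the R380 side chain and the
lobe-1 helix (residues 215–221). No superposition is involved since these
are internal to the complex. In the cryo-EM reference geometry the width
is 16.7 Å and the R380–{D219, L220} closest approach is 2.8 Å; an open
pore widens by ~3.6 Å (to ~20.3 Å).

**Displacement tracks.** Each frame is superposed onto the reference
frame by a least-squares rigid fit (Kabsch, proper rotation only) on the
pore Cα set (`PoreConfig.fit_selection`, default the Cα atoms of the FeS,
Arch and ATPase-1 domain ranges). After the fit, the tracked nucleotide
contributes (i) the displacement of its phosphate from its reference
position, (ii) the heavy-atom RMSD of the whole nucleotide (no second
fit — this is a displacement-style RMSD), and (iii) its base-centroid
path. Ensemble numbers are reported as mean ± per-frame SD (ddof = 0)
over a closed time window; block averaging is not used.

**Equilibration window.** Unless the caller supplies a window, the
equilibrated window starts at the earliest time after which every input
series (pore Cα RMSD plus the tracked nucleotides' heavy RMSD) has an
absolute linear slope below 0.1 Å per 100 ns in every sliding window of
10 % of the trajectory length; the window always ends at the final frame.
When no plateau exists the final 40 % of frames is used, with a warning.
An explicit window always overrides detection.

**Behavior classification.** The B-form adjacent phosphate spacing
d(P–P) = √((2·r·sin(Ω/2))² + h²) with twist Ω = 36° and rise h = 3.38 Å is
the one-nucleotide step yardstick; the default phosphate radius is
calibrated as r = √(7² − h²) / (2 sin(Ω/2)) = 9.9184 Å so the spacing is
exactly 7.00 Å. A replica is labelled

* `backbone_translocation` when its windowed mean phosphate displacement
  is ≥ 0.8 × 7.0 = 5.6 Å. Translocated replicas sit near 7 Å and
  non-translocated ones at or below ~3.6 Å, so any cut between those
  separates the classes; 0.8× is a midpoint-leaning-conservative choice
  and is configurable (`backbone_frac`).
* `base_translocation` when the backbone stays put but the base swung far
  (windowed mean heavy RMSD ≥ 5.0 Å, configurable) **and** the windowed
  mean base centroid lies inside the pore interior. Heavy RMSD alone
  cannot distinguish a base flip into the pore from a large excursion
  outside it (both span roughly 3–10 Å), hence the interior test.
* `blocked` otherwise (entrapment of the base by the FeS pocket —
  residues H135, A139, S140, Y141, Y158, F161, Y192, F193, H384 — or the
  lobe-1 helix 215–221).

The pore interior is modelled as the triangular prism spanned by the
three domain-anchor Cα centroids (FeS helix 128–138, the Arch helix
containing R380, the lobe-1 helix 215–221), extruded ±6 Å along its
normal. The anchor-triangle prism is the simplest geometry that makes
"inside the pore" testable; it is a design choice, not a measured
surface. Classification is invariant under a global rigid motion of every
frame (the pore fit removes it) and under order-preserving time
rescaling.

**Interaction detectors.** A hydrogen bond is a donor/acceptor heavy-atom
pair at D–A ≤ 3.5 Å whose D–H···A angle is ≥ 135° for some covalently
attached hydrogen. When the model carries no hydrogens the hydrogen is
inferred on the D→A axis, which makes the angle test trivially true, so
the criterion reduces to the distance. Donor/acceptor roles come from
residue templates covering the standard amino acids, standard
deoxynucleotides and the T64 lesion residue (both rings' O2/O4 as
acceptors, N3 as donor, addressed by 5T/3T atom-name prefixes); atoms
without a template are excluded with a warning, never guessed. Pair
occupancy is the satisfied-frame fraction over the window; pairs never
satisfied are omitted. "Total HB numbers" per residue–nucleotide–moiety
group are plain sums of member-pair occupancies and can exceed 1.
Cation-π (Arg CZ / Lys NZ) and methyl-π (any carbon) contacts require the
atom within 6.0 Å / 4.6 Å of the ring centroid and within 45° of the ring
normal; the ring plane is an SVD fit, so ≥ 5 non-collinear ring atoms are
needed. Van der Waals contacts are heavy-atom cross pairs within 4.5 Å;
an interaction counts as "abolished" when the windowed mean count drops
below 1. All cutoffs are conventional geometric trajectory-analysis
values and all are configurable; they are deliberately exposed because
different upstream H-bond conventions differ at the margins.

**Stage segmentation.** Stages are defined by which key
residue–nucleotide contacts exist, not by RMSD changepoints: per frame a
binary fingerprint over the caller's pair list (contact = any heavy-atom
cross distance ≤ 4.0 Å, or a satisfied hydrogen bond when the H-bond
cutoff exceeds 4.0 Å), median-filtered with a width of 5 % of the frames;
a boundary is emitted where the smoothed fingerprint changes and the new
fingerprint persists at least the minimum dwell (default 5 % of the
trajectory length). One-frame flickers therefore never create stages, and
the boundary count is non-increasing in the dwell.

**Representative frame.** The "most representative structure" of a window
is its medoid: the frame minimising the summed pairwise RMSD (after
mutual fit on the selection) over all window frames, ties broken to the
earliest time. Whether upstream practice used a clustering tool's
centroid or a medoid is not documented; the medoid is exactly
reproducible and is verified against brute force.

**Bend metric.** For three consecutive phosphates the cross-loop distance
is |P(i−1) − P(i+1)|; a retained backbone bend is called when its
windowed mean is ≤ 1.3 × the adjacent spacing (9.1 Å at the 7 Å default),
which separates the ~8 Å looped state from the ~13.5 Å straight B-form
two-step chord.

**Populations.** Replica labels aggregate into counts and integer-rounded
percentages in the fixed order backbone / base / blocked (e.g. 1/2/6 of
nine replicas → 11 % / 22 % / 67 %).

## The synthetic generator

`synthetic_data` builds a pseudo-atom scaffold: three rigid clusters
carrying the named pore residues with Cα, backbone N/O and minimal
side-chain pseudo-atoms (Arg NE/CZ/NH1/NH2, Lys NZ, His/Tyr/Phe rings,
carbonyl/carboxylate oxygens), positioned so the planted reference
geometry is exact by construction — width 16.7 Å, R380–L220 closest
approach 2.8 Å — plus a 4-nt ssDNA track (dA0–dT3, or dA0/T64/dT2/dT3 in
the lesion variant) on an ideal B-form helix with 7.0 Å P–P spacing. Only
the atoms the detectors consume are generated, keeping fixtures small and
the oracles analytic.

Scripted events interpolate linearly over 50 frames (configurable):
`hop` moves the tracked nucleotide's phosphate group exactly one B-form
spacing along the strand axis; `base_flip` translates the base ring to
the anchor-triangle centroid with the phosphate fixed; `pore_open`/
`pore_close` translate the lobe-1 cluster by ∓3.6 Å. Entrapment scenarios
schedule nothing. Events sharing atoms with overlapping transitions are a
schedule-conflict error. Default scenarios use 200 frames at 10 ns
spacing (a 2 μs replica at a desk-scale frame count) with σ = 0.5 Å
iid Gaussian coordinate noise.

Planted hydrogen-bond occupancies are realised per frame by a Bernoulli
draw: on satisfied frames the designated donor pseudo-atom is placed at
2.9 Å from the noise-perturbed acceptor, otherwise at 5.2 Å, so the
realised satisfied fraction is an exact binomial sample of the planted
probability even under noise (these donor atoms are positioned after the
noise is applied; everything else receives noise). Contact epochs work
the same way through per-residue `CM` marker atoms that move to 3.0 Å
from a nucleotide's phosphate during "on" intervals and rest on a perch
far from the DNA otherwise. Each residue–nucleotide toggle is a planted
fingerprint boundary.

What the generator does **not** emulate: physical dynamics (no force
field, no correlated motions, no solvent), realistic side-chain
chemistry, purine ring geometry (a single 6-ring stands in), or the
gradual conformational transitions of real trajectories (events are
linear ramps). Passing tests therefore demonstrate that the *detectors
and the classification logic* are correct against analytic ground truth
at realistic geometric scales and noise levels — not that real
trajectories are noise-plus-ramps.

## Numerical choices and degenerate inputs

* Kabsch fits require ≥ 3 non-collinear fit atoms (second singular value
  above 1e−8 of the first); the proper-rotation branch is always taken.
* Windows are closed intervals in time; statistics need ≥ 2 frames.
* The median (majority) filter width is forced odd; the dwell is at least
  one frame.
* Medoid ties break to the earliest frame; `numpy.argmin` guarantees the
  first minimum.
* An empty atom selection is an error naming the unmatched clause, never
  an empty result.
* Unknown-element atoms are treated as heavy, with a warning.
* A 5′-terminal nucleotide without a phosphate yields a heavy-atom-only
  track, with a warning.
* Report JSON holds only JSON-native types, so save/load round-trips are
  byte-identical and re-analysis of identical inputs is deterministic.

## Problem sizes

Default synthetic replicas are 200 frames × ~210 pseudo-atoms; the
occupancy studies use 2000-frame replicas; oracle-equivalence checks run
500 randomized frames; medoid brute-force checks cover windows up to 50
frames. These sizes make every planted effect resolvable above noise at
the default window lengths while keeping the full suite fast.

## Known limitations

* The H-bond and π-contact thresholds are conventional geometric
  defaults; reproducing numbers computed under a different convention may
  require adjusting `HBondCriterion` and the π cutoffs in config.
* Real-data inputs are assumed imaged (no periodic-boundary handling) and
  RMSDs are not mass-weighted.
* The equilibration detector assumes a monotone approach to a plateau;
  strongly non-monotone series fall back to the final 40 % of frames.
* PRMTOP reading covers atom/residue identity only (no force-field
  sections); deposited topologies whose residue numbering is offset from
  the structure's can be remapped via the domain-range configuration.
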