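# Methods

This note documents the models, parameter choices and numerical decisions
behind `xlms`, and what the synthetic-data tests do and do not establish
about real data.

## Distance-bound calculus (`linkerchem`)

A cross-link between residues a and b constrains the Cα–Cα distance to
`spacer + ℓ(a) + ℓ(b) + tolerance`. Three tolerance modes are exposed:

- `none` — pure geometry. BS²G (spacer 7.5 Å) between two lysines
  (ℓ = 6.3 Å) gives 20.1 Å.
- `base` — a fixed structural-flexibility allowance. For BS²G this is
  5.9 Å (→ 26 Å for Lys–Lys); for the photo-amino acids it is 13.0 Å,
  back-solved from the tolerance-extended photo bounds (23.4 Å for
  photo-Leu×Lys and 24.4 Å for photo-Leu×Arg) because the published
  photo bounds are the authoritative outputs and no separate allowance is
  printed for them.
- `md` — an allowance derived from molecular-dynamics studies of lysine
  side-chain mobility, stored as the residual that reproduces the
  published MD-adjusted bound: 13.9 Å for BS²G (→ 34 Å Lys–Lys),
  14.0 Å for DSS (→ 38 Å). For photo links no MD figure exists; the
  registry reuses the BS²G residual and marks it non-authoritative.

Side-chain lengths: Lys 6.3 Å and the back-solved photo-Leu 4.1 Å and
Arg 7.3 Å are authoritative; every other entry is an approximate
crystal-structure tip distance and flagged as such in the registry. The
protein N-terminus is a valid amine site with length 0 (the reactive
amine sits on the backbone). Photo-Met's length (5.3 Å) is a best-effort
value; its pairwise bounds are not pinned anywhere and should not be
treated as reference numbers.

Bridge masses come from elemental compositions via pyteomics (BS²G:
glutaryl C5H4O2, +96.02113 Da). Photo cross-links are carbene insertions
that expel N₂, a net change of −28.00615 Da rather than a bridge.

## Restraint mapping and scoring (`xlinkmap`, `structio`)

Structure residue numbers are taken verbatim from the coordinate file
(author numbering, insertion codes included); all user-facing positions
are construct numbering and pass through an explicit `SequenceMap`
(constant offset, or global alignment with match +1 / mismatch −1 /
gap −2 mapping only aligned identical positions and refusing below 50%
identity). This single mapping layer exists because real projects mix
construct, classical and UniProt numbering, and silent off-by-N errors
are the dominant failure mode.

The flat-harmonic restraint is parametrized as a pure upper bound:
center 0, penalty-free half-width equal to the allowed maximum distance,
sd = 1 Å, weight 1.0. Since distances are non-negative, the two-sided
flat harmonic is equivalent to a one-sided bound. Status classification
uses the bound ladder: `within` (≤ geometric bound), `tolerated`
(≤ MD bound), `violated` (beyond it); the penalty's default `tol` is the
base-tolerance bound (26 Å for BS²G Lys–Lys), because constraint setup
conventionally uses the fixed allowance while plausibility screening uses
the MD bound — the writer supports either, plus per-link overrides.

Ambiguous photo links (site lists rather than single sites) are scored at
the minimum-distance alternative — the most permissive reading consistent
with the data; the choice is visible in the assessment table.
Unresolvable sites yield `unmappable`, never an exception, and are
excluded from (but reported next to) the ensemble constraint score.

Deduplication is residue-pair-level: one constraint per unordered
(site, site, linker-class) triple, with evidence counts accumulated.
Peptide-level redundancy definitions would count chemically identical
pairs twice; residue-pair level matches what a distance restraint means
geometrically. Model selection intersects the top-n by total score with
the top-n by constraint score, ties broken by model id.

## Published link table and the synthetic stand-in

`data/crosslinks_g3_leb24.tsv` carries the 13 cross-links of the
nidogen-1 G3/laminin γ1 LEb2–4 interface together with their published
crystal-structure Cα–Cα distances. The experimental coordinate file is
not redistributable here, so end-to-end checks embed these residues into
a synthetic stand-in structure by least-squares distance geometry
(`gen_distance_embedding`): the 13 listed distances are realized to
numerical precision, every unconstrained coordinate is arbitrary. This
validates the mapping/assessment/writing pipeline against the printed
distances; it does not validate anything about unlisted geometry, and
runs on a real PDB file should use `analysis/02_map_published_links.py`
with the structure path and an appropriate `SequenceMap` (the
construct-vs-author numbering offset must be established with align
mode on real data).

## Domain contacts (`domaincontacts`)

Domain tables are user-supplied TSV inputs (shipped tables for nidogen-1
and laminin γ1 are best-effort approximations of UniProt-style ranges and
flagged as such in their headers — UniProt boundaries change across
releases, so pinning them as data keeps the code stable). Ranges are
inclusive; boundary positions belong to the domain; unannotated gaps are
labeled `ua1, ua2, …` in sequence order, with a trailing gap only when
the sequence length is provided. Intra-protein matrices count each link
once in its unordered cell and mirror for display, so the upper triangle
(diagonal included) sums to the link count.

## Precursor-level identification (`digestmatch`)

Digestion cleaves C-terminal to the union of the enzymes' cleavage
residues (trypsin K/R, chymotrypsin Y/W/F, GluC E). The missed-cleavage
allowance defaults to a shared budget of 2 internal sites per peptide
across the combined rule set; a per-enzyme budget mode (2 per enzyme) is
available because the published phrasing "per amino acid" admits both
readings. No cleavage before proline is on by default (standard
chemistry, toggleable). Photo codes `z`/`o` behave as Leu/Met for
cleavage and carry diazirine residue compositions (C5H7N3O / C6H9N3O)
for mass purposes.

Masses are monoisotopic: residues + water + fixed Cys carbamidomethyl
(+57.02146) + variable Met oxidation (+15.99491). Precursor matching is
boundary-inclusive at 3 ppm on neutral masses (`m/z·z − z·m_proton`).
Fragment ions: singly protonated b/y series, b1 excluded and y1 included
(common practice), link-containing fragments carry the partner peptide
plus bridge; −H₂O/−NH₃ variants are off by default. Spectrum-level
signal-to-noise filtering needs raw spectra and is represented by a
no-op hook (`snr_filter`).

## Ensemble tools (`ensembletools`)

Superposition is closed-form least squares (Kabsch, SVD with reflection
guard) over positions unmasked in both models, index-corresponded.
Loop masking excludes maximal loop runs longer than 5 residues from RMSD.
Clustering is greedy center-based at an explicit radius (the working
radii in the analyses are 1.5, 2 and 10 Å; automatic radius detection is
out of scope), ties broken by model id, followed by an optional merge
pass keyed on the models' source tag for clusters tracing back to the
same originating centroid model. The cross-homologue consensus rule is
existential per homologue ensemble and universal over ensembles; the
similarity test is masked RMSD ≤ threshold (default 5 Å over matched
Cα). This replaces sequence-independent structural-alignment Z-scores:
the consensus logic is the point being captured, and an index-matched
RMSD proxy has no analog for alignment-coverage criteria, which are
therefore not emulated.

## Binding kinetics (`bindingaffinity`)

The 1:1 Langmuir model `dR/dt = ka·C(t)(Rmax − R) − kd·R` is integrated
in closed form on the piecewise-constant concentration segments of a
single-cycle schedule. Defaults emulate nanomolar-affinity single-cycle
runs: five 1-min injections of a doubling 6.25–100 nM series, each
followed by a 40.6-min dissociation gap; truth parameters ka = 10⁶
M⁻¹s⁻¹, kd = 10⁻³ s⁻¹ (Kd = 1 nM), Rmax = 100 RU. Fitting is
least squares on log-parameters (positivity by construction); Kd is
reported as kd/ka exactly. Mass transport, drift and bulk jumps are not
modeled; instrument-artifact windows can be excluded from the residuals
and double referencing is blank subtraction. Saturation binding uses the
hyperbola `R = Bmax·C/(Kd + C)` over the 0.03–234 nM window, with the
fit flagged unreliable when the top concentration is below the fitted
Kd. Replicate combination offers inverse-variance weighting, flagged as
a package choice since instrument-software weighting schemes differ.

## Synthetic data (`synthetic_data`)

Generators are deterministic under (spec, seed). Chains: helix
(1.5 Å rise, 100°/residue, 2.3 Å radius — consecutive Cα ≈ 3.8 Å),
extended (3.8 Å spacing), and a compact self-avoiding walk (3.8 Å
steps, ≥ 4.0 Å non-bonded separation, 30% centroid-biased moves — this
yields globules whose diameter for ~150 residues is ≈ 40–50 Å, in the
range of real single-domain proteins, so that all three restraint
satisfaction bands are populated). Sequences are Lys/Leu/Met-rich so
both chemistries have abundant sites. Cross-link sets are sampled
directly in the three satisfaction bands with the sampled distance as
planted truth; ensembles plant clusters as large coordinate deformations
(plus rigid moves, invisible to RMSD) with small member jitter; precursor
sets inject uniform ppm errors inside (matchable) or outside
(non-matchable) the inclusive 3 ppm gate.

What passing synthetic tests show: the implementations agree with their
independent oracles and planted truth under controlled conditions. What
they do not show: robustness to real-data pathologies — missing density,
alternate conformers beyond highest-occupancy selection, mis-annotated
domains, correlated MS noise, isotope-envelope errors, or mass-transport
effects in sensorgrams.

## Problem sizes

The test battery and drivers run at desk scale by choice: 150-residue
chains, 26-pair link sets expanded to 47 observations, ensembles of
10–60 models (with one 25,296-row score-table ranking check), 100-seed
planted-truth sweeps, 20-seed noisy kinetic recoveries sampled at 0.2 Hz.
These sizes exercise every code path while keeping the default suite
fast; all of them scale up by changing generator arguments.
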