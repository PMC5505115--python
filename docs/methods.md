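# Methods

This note documents the models, parameter choices and known limitations of
the package.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Mass bookkeeping

All masses are monoisotopic: proton 1.007276 Da, water 18.010565 Da, residue
masses from the standard table with cysteine carrying the fixed
carbamidomethyl modification (+57.02146 Da; samples are assumed reduced and
alkylated with iodoacetamide before digestion).  No variable modifications
are modelled.  Neutral precursor mass is `precursor_mz · z − z · proton`; the
total residue mass M of a precursor is that minus water.  Fragment ions are
treated as singly protonated throughout — a deliberate simplification
(2–3+ precursors mostly yield 1+ fragments in this mass range) and a known
limitation for long, highly charged peptides.

Ion-series neutral offsets relative to the summed residue mass of the
fragment: b 0.0, a −27.99491, y +18.010565, c +17.02655, z• +1.99184 Da.

## Synthetic experimental design

The generator emulates the experiment the pipeline is built for:

- **Proteome**: n proteins (default 10), lengths uniform on 60–200 residues,
  residues i.i.d. uniform over the 20-letter alphabet.  Uniform frequencies
  are a neutral default; real venom toxins are cysteine-rich and biased, so
  the simulated sequence-collision rate between proteins is, if anything,
  conservative for homology mapping.
- **Fractionation**: partition at a 10 kDa molecular-weight proxy (residue
  mass sum + water); the two fractions are processed independently and merged
  only at the parsimony step.
- **Digests**: trypsin 4 h (partial), trypsin 18 h, chymotrypsin 18 h,
  pepsin 18 h.  Rules: trypsin after K/R not before P; chymotrypsin after
  F/W/Y not before P; pepsin (pH-2 style) after F/L/W/Y.  Digestion
  completeness is the only difference between the two trypsin conditions:
  stochastic mode cuts each susceptible site with p=0.5 (4 h) vs 0.9 (18 h);
  deterministic mode instead enumerates products with ≤2 vs ≤1 missed
  cleavages.  Products are kept at 4–30 residues.  These completeness values
  are stand-ins — the study design states only the incubation times.
- **Acquisition**: precursors outside m/z 350–1,800 at charges 2 and 3 are
  dropped (charge 2 preferred).  Default mode acquires one CID/HCD/ETD triple
  per eligible peptide; DDA mode simulates Gaussian elution over a gradient,
  top-3 selection per ~5 s cycle and a 60 s dynamic-exclusion list.
- **Fragmentation model**: per mode, ion series with detection probability
  and mean relative intensity (CID b 1.0/y 0.7; HCD b 1.0/y 0.7/a 0.3;
  ETD c 1.0/z• 0.8), m/z jitter s.d. 0.2 Da for ion-trap CID/ETD readout and
  0.01 Da for Orbitrap HCD, log-normal intensity noise, and Poisson(20)
  uniform noise peaks.  The `noiseless()` preset (detection 1, jitter 0, no
  noise) produces exactly the theoretical ladders and defines the reference
  study used by the acceptance checks.

Every emitted triple is recorded with its peptide, source accession, 0-based
start, digest, and charge, so downstream stages can be scored exactly.

What the generator does **not** model: isotope envelopes, fragment charge
states >1, neutral losses, co-isolation/chimeric spectra, retention-time
structure beyond a Gaussian, semi-specific or non-specific cleavage, and
post-translational modifications.  Passing tests therefore demonstrate the
correctness of the pipeline's combinatorial machinery under the stated noise
model, not instrument-grade performance on real files.

## PRM scoring

The likelihood models of the original software are not published, so the
scoring model here is a declared default, not a reconstruction: intensity
ranks are binned into tiers (top 10 / top 25 / top 50 / rest) with likelihood
ratios 8/4/2/1, multiplied by a per-series prior (CID b=y=0.4; HCD b=y=0.35,
a=0.1; ETD c=z•=0.45) and divided by a noise likelihood of 0.05;
`score = log(tier · prior / noise)`.  The noise likelihood is the probability
mass assigned to a peak being noise; 0.05 keeps every default log-odds
positive, which gives the model a clean separation property (below).  Within
one spectrum, candidate masses closer than the fragment tolerance (0.4 Da
CID/ETD, 0.02 Da HCD) are alternatives for the same peak set and collapse to
the best-scoring one; across the triple, matching masses corroborate each
other and scores add (merge tolerance 0.3 Da).  Both the N- and C-terminal
reading of every series are always generated; the mirror ambiguity is
resolved by cross-mode corroboration, not per spectrum.

Under this default model on noiseless data the attainable scores stratify:
a single spurious interpretation scores at most log(8·0.45/0.05) ≈ 4.28; the
b/y mirror of a true mass is corroborated by CID and HCD but can never
receive ETD support (c/z mirrors land 15.03 Da away), capping two-mode
clusters near 8.4; a true prefix mass collects one contribution from each of
the three modes and scores at least ≈ 10.4.  Coincidences on the residue-mass
lattice can push a two-mode cluster's *score* above a weak true peak, so the
robust separator is **mode corroboration, not score**: the assembly stage
keeps only peaks supported by all three modes (`min_modes = 3`) and with
summed log-odds ≥ 9 (`peak_score_floor`, the boundary between the two-mode
maximum and the three-mode minimum).  For noisy data, where a mode can miss a
cut entirely, `min_modes = 2` is the natural relaxation; both are config
keys.

## Spectral network

Candidate shifts are all pairwise mass differences, with the boundary masses
0 and M included virtually (they anchor shifts but never count as matches).
Per candidate, the optimal monotone matching is computed by weighted-LIS
dynamic programming — a greedy scan is not guaranteed to equal the exhaustive
search that the oracle tests require.  Three edge criteria control the
false-edge rate of the all-versus-all search:

- `min_matches = 7` for network construction (a single pairwise comparison
  uses 5).  PRM masses live on the residue-mass lattice, so two unrelated
  proteins sharing a 4-residue substring already produce 5 coincident
  ladder masses; 7 requires a shared run of ≥6 residues, which is rare at
  this proteome size and is the level at which synthetic runs stop producing
  cross-protein bridge edges.
- window consistency (`min_window_frac = 0.8`): a genuine overlap alignment
  matches essentially every ladder mass inside the overlap window; spurious
  shifts match scattered subsets.
- shift coherence (0.2 Da): matched pairs must agree on the shift; the value
  accommodates the ~0.06 Da consensus-mass wobble of noisy merged spectra.

The score threshold defaults to twice the mean score of shuffled-mass decoy
alignments (usually 0 at these match counts).  Alignments with one internal
offset change (`allow_offset`) support spotting an unanticipated modification
between two peptides; such edges are annotated only and never used by
assembly.

## Assembly and consensus

Union-find gluing refuses any union that would put two peaks of one spectrum
into one vertex or whose frame-propagated masses disagree by more than
`frame_tol = 0.35 Da`; redundant (non-spanning-tree) edges that disagree with
the propagated frames simply have their pairs dropped and logged.  The anchor
is the highest-total-score spectrum and frames propagate along the
maximum-score spanning tree — a stability choice.  Unmatched peaks stay as
singleton vertices because they may carry true ladder masses at the contig
ends.  The heaviest path maximises summed vertex score with a penalty of 10
log-odds units on any step whose mass difference is not a single residue mass
(±0.03 Da): a weakly supported vertex sitting between two ladder masses costs
two penalised steps, so the path detours through it only when its own
evidence outweighs ~20 units, while a genuine coverage gap costs one penalty
and is taken.  Contigs need ≥2 member spectra to be reported as meta-contigs.

## De novo notation

Residue calls use `call_tol = 0.02 Da` at consensus level — score-weighted
averaging across modes and member spectra justifies a tolerance much tighter
than the ion-trap readout, and it separates K (128.09496) from Q (128.05858).
At looser tolerances ambiguous differences become gaps, which is the honest
output.  I/L are isobaric and reported as I; the homology mapper treats them
as equivalent.  Gap masses print to 3 decimals with trailing zeros trimmed;
the parser accepts 1–6 decimals and formatting a parsed sequence reproduces
the printed digits verbatim.  `gap_compositions` enumerates all residue
multisets (≤6 residues) compatible with a gap mass, for interpreting gaps.

## Homology mapping and parsimony

The placement DP allows no substitutions, insertions or deletions: a residue
element must match (I≡L) and a gap element must consume 1–6 protein residues
whose mass sum is within `gap_tol = 0.05 Da` of the gap.  Score = number of
matched residue elements, `min_matched = 6`.  These are declared defaults; no
scoring scheme is published for the original mapping step.  Protein inference
is greedy minimum set cover (ties: more total matches, then lexicographic),
after removing matches to a bundled contaminant list (the three
sample-preparation proteases, keratins, BSA).

## Reference study and problem sizes

The acceptance checks run the noiseless study at 10 proteins × 4 digests
(≈ 900–1,100 triples, ≈ 500k pairwise alignments after filtering), which
completes in well under a minute; oracle suites use 200 random instances of
≤12 peaks/vertices and 100 gap masses, sizes at which exhaustive enumeration
is exact and fast.  The printed counts of the real venom study derive from
~78,000 measured triples across 88 raw files and are not reproducible from
synthetic data; the summary report intentionally emits the same count
categories so real and synthetic runs read alike.

## Known limitations

- Fragment charge fixed at 1+; no isotope envelopes or neutral losses.
- The noisy regime trades residue calls for gaps (as real ion-trap data
  does); recovering calls there requires looser `call_tol`/`gap_tol` and
  `min_modes = 2`, at some cost in precision.
- Paralogous isoforms sharing long identical stretches will co-assemble; no
  repeat resolution is attempted — such regions surface as one contig.
- All-versus-all alignment is quadratic in the number of triples; no
  locality hashing is implemented, so runs beyond ~10⁴ triples become slow.
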