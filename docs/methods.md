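# Methods

## Scientific setting

Native electrospray of an oligomerizing peptide such as amyloid-beta 1–40
produces a forest of co-populated n-mer/charge-state ions.  Gas-phase
hydrogen/deuterium exchange (HDX) with ND₃ inside the instrument, on
sub-millisecond timescales, labels only heteroatom-bound side-chain and
terminus hydrogens — backbone amide NH exchanges far too slowly in vacuum
to register.  The measured deuterium uptake of each ion therefore probes
how many side-chain protons are free versus engaged in intra- or
intermolecular hydrogen bonds and salt bridges.  Combined with ion-mobility
(IM) drift-time separation, the method resolves *which* oligomeric species,
at *which* charge, in *which* conformational state exchanges how much.

This package implements the complete data-analysis chain for such
experiments, plus a forward simulator that generates ground-truthed
synthetic spectra with the same statistical structure, so that every stage
is testable without instrument data.

## Exchangeable-proton accounting

Per-residue counts of exchangeable hydrogens of the *neutral* side-chain
forms (`DEFAULT_EXCHANGE_TABLE`):

| residue | D | E | S | T | Y | H | Q | N | K | R | W | C | others |
|---------|---|---|---|---|---|---|---|---|---|---|---|---|--------|
| H count | 1 | 1 | 1 | 1 | 1 | 1 | 2 | 2 | 2 | 4 | 1 | 1 | 0 |

plus 2 for a free N-terminal amine and 1 for a free C-terminal acid.  This
is the unique simple neutral-form assignment consistent with the wild-type
amyloid-beta 1–40 inventory: 27 exchangeable protons overall, 19 in
residues 1–16 and 8 in residues 17–40.  In positive mode the z charging
protons are themselves exchangeable, so an (n-mer, z+) ion carries
`n·27 + z` exchangeable sites (e.g. 32 for the 5+ monomer).  The table is a
plain data object, serializable to YAML and overridable.

Known simplification: some side-chain hydrogens exchange more slowly than
others; no per-site kinetics is modelled (the gas-phase model has no
Bai–Englander-style rate constants), and all counted sites are treated
identically.

## Isotope envelopes

Elemental compositions come from summing residue compositions (pyteomics
tables) plus one water for the termini.  Natural isotope envelopes are
computed by exact per-element convolution aggregated on the nominal-mass
lattice: each integer-offset bin carries its total probability and the
probability-weighted mean mass of its fine structure.  This is exact for
the zeroth and first moments (the envelope centroid equals the average
mass) and adequate at the peak widths of interest; sub-bin fine structure
is not resolved.  Envelopes are pruned at relative probability 1e-6 and
renormalized.

## The equal-probability single-state model

A single conformational state is modelled as exchanging every one of its
`n` sites independently with the same probability `f`; its deuteration
count is Binomial(n, f) and each deuteron adds Δm_D = 1.006277 Da.  The key
inequality is that for *any* heterogeneous per-site probabilities p_i with
the same mean, the Poisson-binomial variance Σ p_i(1−p_i) is at most
n·p̄(1−p̄): the equal-probability envelope is the widest a single state can
produce.  Decomposing an observed envelope against a family of such maximal
single-state envelopes therefore yields a *lower bound* on the number of
co-populated states — the count can only be an undercount, never an
overcount.  This bound is exercised directly in the tests (heterogeneous
simulated single states are never split).

The theoretical family spans uptake fractions 0…1 inclusive in 200 steps
(step 1/199; whether the endpoints are included was an open choice — the
undeuterated member is needed as the zero reference, so both ends are in).
The binomial pmf is evaluated exactly (no normal approximation); peptide
ions here never exceed ~150 sites.

## Preprocessing

Savitzky–Golay smoothing with polynomial order 3 over a 5-point window,
one pass, is the default, mirroring the "(3, 5)" convention of vendor
software; because that shorthand is ambiguous both parameters are exposed.
Negative filter undershoot is floored at zero.  Centroiding takes local
maxima, splits supports at the valleys between neighbouring maxima,
restricts each support to points at least 1% of its apex, and reports
intensity-weighted mean positions with summed-intensity areas.  Uptake per
monomer (HDX/M) is the centroid difference between deuterated and control
ions converted to deuterons and divided by the oligomer order:
`(m/z_D − m/z_H)·z / (Δm_D·n)`.

## Deconvolution

Both the control envelope and the deuterated envelope are converted to the
mass domain of one monomeric unit (`(m/z·z − z·m_p)/n`), where
equal-charge-density isobars coincide.  The control centroids serve as the
empirical natural envelope; convolving them with the binomial model at 200
fractions gives the family, each member rendered as a 500-element vector by
Gaussian-kernel convolution on a uniform mass grid.  Defaults:

- mass range: control envelope extremes padded by 5 deuteron-widths below
  and `n_sites·Δm_D/n + 5 Δm_D` above;
- kernel sigma: 1.5× the monomer-domain isotope spacing (1.00235/n Da) —
  wide enough to make the linear system smooth, narrow enough to keep
  neighbouring family members distinguishable (recovery turned out to be
  insensitive to halving it);
- peaks below 1% of the strongest peak in either input are treated as noise
  pickup and dropped.

The non-negative system y = A w is solved with the boosted Gold algorithm:
multiplicative updates `w_i ← w_i·(Aᵀy)_i/(AᵀA w)_i` from a strictly
positive uniform start, organised as 100 boosting cycles of 10000 updates
each, with the boosting step `w ← w^1.2` (followed by renormalization)
applied at the end of every cycle.  The per-cycle iteration count follows
the convention of the boosted-deconvolution literature, where the iteration
number names the inner relaxation length of each boosting repetition.  The
cycle structure is essential, not cosmetic: the plain multiplicative update
separates overlapping components only after ~10⁵ updates, and a boost
applied before the update has relaxed commits the solution to a wrong
support that later updates cannot leave (multiplicative updates never
revive a crushed weight).  With the long relaxation the solver matches a
non-negative least-squares oracle on small systems, which is how the tests
pin it down.

Solution elements below 1% of the total are zeroed; each remaining run of
*adjacent* non-zero family members is reported as one component at the
weight-weighted interpolated uptake.  Component uptakes are reported per
monomer.  If everything falls below threshold a single low-confidence
component at the overall centroid is returned rather than nothing.

Resolution limits, measured on synthetic data at signal-to-noise 50:
components separated by ≥ 3 deuterons with weights ≳ 0.1 are mostly
recovered with the correct count; a weak state (weight ≈ 0.1) closer than
about 4 deuterons to a dominant neighbour may be absorbed into it, by the
Gold solver and by non-negative least squares alike — it is a conditioning
limit of the family, not a solver artefact.

## Oligomer, charge and conformer assignment

Charge density CpM = z/n determines envelope position: all ions of one
peptide with equal CpM are exact isobars (for amyloid-beta the printed
2164–2169 m/z window holds the 2+, 4+, 6+, 8+ ladder of monomer to
tetramer).  `isobar_family` enumerates the ladder; `infer_charge_from_spacing`
reads z off the isotope comb via the median adjacent-peak gap
(z = round(1.00235/gap); relative gap dispersion above 20% is declared
unassignable; a strongly periodic area pattern across the comb flags an
overlapped mixed comb).  The spacing constant 1.00235 Da is the average
peptide isotope gap, deliberately not the pure ¹³C−¹²C difference;
it is configurable.

Drift handling stays in milliseconds; no collisional-cross-section
calibration is attempted.  A drift profile is the map summed over an m/z
window; populations are local maxima with prominence ≥ 10% of the profile
maximum (the numeric split criterion is a documented choice — the
phenomenon itself has no printed threshold), with shares from
valley-to-valley integration after subtracting a flat baseline estimated
as the mean of the lowest quartile of bins (noise clipped at zero leaves a
positive offset that would otherwise bias shares toward ½).  The
shortest-drift apex is labelled compact, the longest extended.  Slicing the
map at an apex yields that conformer's own envelope for
conformer-specific deconvolution.

## Synthetic data

The generator is the forward version of the analysis assumptions: each
species is a mixture of conformers, each conformer a single equal-probability
state at its own uptake fraction; envelopes sit at proton-adduct m/z with
Gaussian peak shapes (sigma 0.02 m/z, resolving isotopes to z ≈ 8);
drift-time populations are separable Gaussians; noise is additive Gaussian
(sd relative to the signal maximum; optional Poisson).  HDX reagent flow
labels 20/30/40/50 mL/min map to multiplicative fraction scalings
0.4/0.6/0.8/1.0 — purely phenomenological, not a model of the ND₃
chemistry.  All randomness flows through one seeded generator recorded in
the ground truth, so identical configs reproduce outputs bit for bit.

Canonical scenarios mirror the wild-type system: monomer (2+) states at
4/10/18/28 D per monomer, dimer (4+) at 4/9/14 D, a compact/extended
trimer (6+) drift split (compact exchanging less), a fully-scrambled-like
single-population trimer, and a small unstructured-peptide control
(Leu-enkephalin-like, unimodal).  Scrambled-variant sequences are synthetic
stand-in permutations of the wild type (composition-preserving, fixed
seed); every quantity computed from them is permutation-invariant.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: chemical noise and baseline drift, detector
saturation, adduct and salt-cluster signals, charge-dependent transmission,
peak-shape asymmetry, and any real kinetics of the ND₃ collision complex.

## I/O formats

Plain two-column text (whitespace or comma), minimal mzML (MS1 spectra,
32/64-bit float arrays, plain or zlib-compressed binary; both reader and
writer live in `spectra.py`), three-column text for IM-MS maps, TSV for
centroid lists and reports, JSON for ground-truth manifests and run
reports.  Run reports embed the resolved configuration and package version
for provenance.

## Numerical choices and degenerate inputs

- Division guards at machine epsilon in the Gold update; all-zero spectra,
  empty windows, empty drift slabs and out-of-range regions raise
  `ValueError` with context.
- Near-coincident masses (< 1 nDa apart) are merged during binomial
  convolution to keep mass axes strictly increasing.
- Deconvolution problem sizes: 500 grid points × 200 family members;
  one envelope takes ~10 s of multiplicative updates; the end-to-end test
  suite sizes its simulations accordingly (monomer-scale systems, 20-trial
  recovery studies).
- `uptake` flags negative values beyond 0.5 D with a warning but returns
  them, so systematic control/deuterated mispairing is visible rather than
  silently clipped.

## Known limitations

- The component count is a lower bound by construction; states closer than
  the family's resolution limit merge.
- Charge assignment needs ≥ 3 resolved isotope peaks; heavily overlapped
  combs of more than two charges are flagged mixed at best.
- No lock-mass recalibration, no deisotoping, no CCS calibration, no
  negative-ion mode.
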