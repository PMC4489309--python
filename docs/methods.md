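# Methods

## Problem and scope

`ionforest` predicts the intensities of the four most common peptide
fragment ions — b+, y+, b++ and y++ — observed in MS² spectra of tryptic
peptides at precursor charges 2+ and 3+, separately for CID and HCD
fragmentation. The package covers the full loop: peptide grammar, PTM
registry, theoretical fragment masses, spectrum annotation, feature
encoding, random-forest regression, MGF/CSV output, and per-PSM Pearson-R
evaluation. Upstream identification (database search, FDR control) is out
of scope: evaluation trusts its input PSMs to be confidently identified.

## Peptide grammar and masses

Peptides are written `H-P-OH`: capital 1-letter residues, each optionally
preceded by a lowercase PTM symbol that binds to the *next* capital
(`H-SAoxMPLE-OH` puts `ox` on the M at 1-based position 3); the leading
and trailing dash-delimited tokens are the terminal groups (`ace-P-OH`
for N-terminal acetylation). One symbol per residue; stacked symbols are
rejected as unregistered rather than guessed at, since the grammar gives
no way to split a lowercase run unambiguously. Only the 20 standard
residues are accepted — the training alphabet — and no upper length limit
exists anywhere in the pipeline (the parser requires length ≥ 2 so that
at least one cleavage site exists).

Masses are monoisotopic throughout (high-resolution, de-isotoped data are
the intended regime). Neutral peptide mass = Σ residues + water + Σ PTM
shifts; b_i = prefix residues (+ N-terminal and in-range shifts); y_i =
suffix residues + water (+ C-terminal and in-range shifts); m/z =
(neutral + z·m_proton)/z with the proton mass, not the hydrogen atom.
Terminal modifications are additive on top of the default H-/-OH groups,
matching how PTM databases state terminal mass shifts. The b/y identity
neutral(b_i) + neutral(y_{L−i}) = M holds exactly and is tested to 1e-9 Da.

The PTM registry is a local CSV table (symbol, name, monoisotopic shift,
residue scope); no network database is queried. At most 8 distinct
symbols per run, overridable, mirroring a server-style resource cap
rather than a method limit. The bundled table carries common artefactual
PTMs (oxidation +15.994915 on M, carbamidomethyl +57.021464 on C,
N-terminal acetyl +42.010565, deamidation, phospho, C-terminal amidation).

## Annotation transform

A theoretical ion takes the intensity of the most intense observed peak
within ±`tol` of its m/z. `tol` defaults to 0.02 Da (absolute, not ppm),
appropriate for de-isotoped Orbitrap-resolution peak lists; it is
configurable everywhere it appears. One observed peak may serve several
near-isobaric ions — exclusive assignment would add a tie-breaking policy
whose effect only shows for close isobars, so the simpler deterministic
rule is used.

Matched raw intensities are divided by the spectrum's total ion current
and mapped through x → log2(x + ε), with ε = 0.001 × the median nonzero
normalized intensity of that spectrum (fallback 1e-9 for empty spectra).
Unmatched ions get the baseline log2(ε): absence is trained as "lowest
intensity", not dropped, so every PSM contributes exactly 4·(L−1)
examples. The transform is strictly monotone, so intensity rank order
survives annotation. The transform identifier (`tic-log2-v1`) is stored
in model metadata; predictions invert it (2^t − ε, floored at 0, using
the median training ε) before writing MGF/CSV.

## Feature schema (v1-146)

Each example encodes (peptide, precursor charge, cleavage site) as 146
features: length; relative site position; charge indicators; means of
four bundled property scales (gas-phase basicity, Kyte–Doolittle
hydrophobicity, Chou–Fasman helix propensity, isoelectric point) over the
full peptide, prefix and suffix; one-hot residue identities at positions
site−1…site+2 (padded at the edges with an explicit null symbol — the
±2 window captures the proline/glycine local effects that dominate CID
cleavage); per-residue composition counts of prefix and suffix; and
modification features: total PTM mass in prefix/suffix, counts of
modified residues, and modified-at-site indicators. The schema encodes
"modified + how heavy", deliberately never PTM identity; two PTMs of
different mass at the same position differ only in the mass features
(tested). Vector length is independent of peptide length, which is what
removes any length restriction from the models. The schema version is
embedded in every saved model and checked at load and predict time.

## Models

One model per (fragmentation method × precursor charge), bundling four
independent `RandomForestRegressor`s, one per ion series — per-series
regressors keep the targets homoscedastic and mirror the per-series
evaluation. Defaults: 50 trees, unlimited depth, `max_features="sqrt"`,
fixed seed, single-threaded. These defaults keep training on ~65k
examples per series in the low minutes on one CPU while leaving held-out
accuracy on the synthetic recovery task at the ceiling; they are recorded
in model metadata along with method, charge, seed, tolerance and
normalization id, and stored as a single joblib bundle. `load_model`
refuses a bundle whose schema version differs from the running encoder.
An optional documented deduplication filter (keep the highest-TIC
spectrum per (peptide, charge)) is *not* applied by default.

## Synthetic study conditions

The generator emulates the qualitative drivers of peptide fragmentation
without claiming physical accuracy. Ground-truth intensity for ion
(series, z) at site i is

    base[series,z] · exp(−decay·|x−0.5|) · proline · supp^n_basic_comp ·
    exp(−ptm_coef·m_frag) · mobility · boost,

where x is the relative site position, `proline` multiplies y (divides
b) by `proline_factor` when the residue C-terminal to the cleavage is P,
`supp^n` suppresses a series per basic residue (R/K/H) retained by the
*complementary* fragment, `m_frag` is the modification mass carried by
the fragment, `mobility` penalizes spectra whose precursor charge does
not exceed the count of basic residues (no mobile proton), and `boost`
raises ++ fragments for 3+ precursors. Intensities are normalized to
unit TIC. Every driver is a function of the v1 feature schema, so the
recovery ceiling of a trained forest is near 1 by construction: model
tests measure the learner, not encoder blind spots.

Two presets emulate the CID/HCD contrast: `method_a` (CID-like — strong
proline effect 4.0, centre-weighted cleavage decay 2.0, substantial b+
base level) and `method_b` (HCD-like — weak proline effect 1.4,
edge-weighted profile −1.2, y-dominated, weaker basic suppression). On
identical peptides the presets disagree on the intensity rank of ~96% of
ions, which is what makes cross-method transfer degrade.

The observation layer adds, in order: multiplicative log-normal noise
(σ = 0.2 by default, log scale); detection-limit dropout — each peak is
lost with probability `dropout·2·(1−q)` where q is its intensity rank
quantile, so the weakest peaks are lost preferentially, emulating
censoring at the noise floor; mean rate 1% by default — and Poisson
decoy peaks (0.3 per true ion) at uniform m/z with intensities below the
median true peak. With these defaults the truth-vs-observed annotation
ceiling is ≈0.97 median R, so σ is the dominant distortion and held-out
R degrades monotonically in σ. Peptide lengths default to 15–16
residues, matching a synthesized proteotypic evaluation set; residues
are uniform, with PTMs placed at rate 0.1 within registry scope.

What the generator does **not** emulate: real cleavage chemistry beyond
the rule above, neutral losses, a/c/x/z ions, isotope envelopes,
retention behaviour, intensity correlations between series beyond shared
features, or realistic decoy structure. Passing the synthetic tests
therefore demonstrates that the pipeline is correct and the learner can
recover a feature-expressible fragmentation rule at the stated noise —
not that predictions on real instrument data reach these correlations.

## Evaluation

Each PSM is scored by one Pearson R between predicted and observed
intensities with all four series concatenated (a single R per PSM, as in
boxplot summaries of prediction accuracy; per-series R is available
behind a flag). Correlations are computed on the normalized-log2 target
scale — the scale the models are trained on; Pearson is invariant to the
affine part of any remaining per-spectrum offset. Zero-variance vectors
make Pearson undefined: such PSMs are flagged degenerate, excluded from
summaries, and counted. Summaries report n, mean, quartiles by linear
interpolation, and Tukey whiskers (most extreme datum within 1.5×IQR of
the box) — the conventional boxplot definition, adopted over a literal
"1.5 × Q1/Q3" reading, which is not a consistent whisker rule. PTM
partitioning buckets peptides as `no_ptm`, `mox` (only oxidized M),
`cmm` (only carbamidomethyl C) or `other`.

## Problem sizes and numerical choices

The shipped end-to-end checks use 5000 noiseless PSMs (4500 train / 500
held out) for parameter recovery with a label-permutation control at
identical protocol, 800 train / 150 eval PSMs per preset for the
matched-vs-cross comparison, and 1000 random peptides (lengths 2–30,
PTM rate 0.15) for mass-oracle equivalence at 1e-9 Da — sizes chosen to
make each check decisive at single-CPU desk scale. Ties in peak matching
resolve to the most intense candidate; equal-intensity ties to the
lower-m/z peak (stable sort). Degenerate inputs (empty spectra, empty
peak lists, all-unmatched annotations) are handled without error and
produce baseline targets.

## Known limitations

- The feature list of the original intensity-prediction work is not
  public in detail; schema v1 is this package's own explicit stand-in,
  versioned so models and encoders can never silently disagree.
- Absolute predicted intensities are on the normalized relative scale of
  the training transform; only relative/rank structure is meaningful.
- Real-data performance is not established by the synthetic suite (see
  above); training on real annotated PSM corpora is supported through
  the same MGF path but not exercised here.
- q-value filtering, de-isotoping and charge deconvolution are upstream.
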